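# Methods

## Study design and the quantity of interest

The package analyses a 2 x 2 x 2 repeated-measures design: stimulation
group (PMN-targeted vs prefrontal control; between subjects), stimulation
condition (stim vs sham; within subject), and cognitive task
(autobiographical retrieval vs rest; within subject), with one scan per
within-subject cell. All connectivity is expressed as Fisher z = arctanh(r)
of Pearson correlations, which is approximately variance-stabilising and
makes additive models sensible. The scientific target is the three-way
interaction: a stimulation effect on connectivity that is larger during
memory retrieval than at rest, and selectively so for network-targeted
stimulation.

## Preprocessing

Operating on series already in a common space, the fixed stage order is
trim -> motion-parameter regression -> bandpass -> smooth -> mask. Choices
and conventions:

- **Framewise displacement** uses the Power convention: the sum of absolute
  backward differences of the six rigid-body parameters, rotations
  converted to arc length on a 50 mm sphere; the first frame is 0. The
  rotation unit of motion files on disk is site-dependent, so the reader
  takes a `rotation_units` dialect option ('rad'/'deg') and never guesses.
- **Exclusion** is strict-greater: a scan is excluded when more than 5% of
  frames exceed FD 0.3 mm (included scans have at most the boundary
  fraction). Censored frames are flagged for QC only; retained scans enter
  connectivity computation unscrubbed. The pipeline drops every scan of an
  excluded subject to keep the within-subject design complete.
- **Bandpass** (default 0.01-0.1 Hz) is an ideal frequency-domain
  projection: DFT bins inside the band are kept, all others (including DC)
  zeroed. Projection makes the filter exactly idempotent, which a test
  asserts.
- **Smoothing** uses sigma = FWHM / (2 sqrt(2 ln 2)) per axis in voxel
  units, handling anisotropic voxels per-axis.
- **tSNR** (mean over in-mask voxels of temporal mean / temporal SD) is
  computed after motion regression but before bandpass — the bandpass
  removes the mean, after which the ratio is undefined. Zero-SD voxels are
  excluded with a warning.
- The first five frames of a loaded NIfTI are dropped by the reader
  (intensity stabilisation), configurable.

## Mixed-effects inference

The core model is a linear mixed model with a subject random intercept,
fitted by REML (statsmodels MixedLM):

    z ~ condition * task * group + tSNR_c + (1 | subject)

- **Coding**: all factors use +/- 1/2 sum-to-zero contrasts, so the
  three-way beta is exactly the difference between the two groups'
  (stim - sham, retrieval) - (stim - sham, rest) contrasts on the z scale,
  and a delta planted in the single (PMN, stim, retrieval) cell appears in
  the beta at its planted magnitude.
- **Hierarchy**: the full model includes all two-way interactions beneath
  the three-way term (testing a three-way term without its lower-order
  terms confounds it); a mains-plus-three-way structure is selectable.
- **Denominator df** use a Satterthwaite approximation implemented from the
  closed-form REML likelihood of the random-intercept model: per
  coefficient, df = 2 f^2 / Var(f) where f is the coefficient's sampling
  variance and Var(f) comes from the delta method with the inverse REML
  observed information (finite differences in the two variance parameters).
  A test verifies agreement with R's lmerTest to ~1e-3 on t and ~0.1 on df.
  When the information matrix is not positive definite the fit falls back
  to residual df and says so in the result. At the boundary (random
  intercept variance ~ 0) the GLS fit reduces to OLS and is reported as
  such.
- **Degenerate columns** (e.g. a constant tSNR covariate, collinear with
  the intercept after centring) are dropped with a log entry; the fit then
  reproduces the no-covariate fit exactly.
- **Edge tests**: each within-network pair's z series is fitted with the
  same model; interaction p-values are Benjamini-Hochberg corrected across
  the pairs of one network (each network is its own FDR family, matching
  per-network reporting). Non-convergent edges are flagged and excluded
  from the family.

## Global connectedness and cluster-extent inference

Global connectedness of voxel i is arctanh of the mean correlation of i
with every other in-mask voxel. It is computed from standardised series
sums in O(voxels x time) and is algebraically identical to the brute-force
pairwise loop (a test enforces 1e-8 agreement). Clamping (|r| <= 1 - 1e-7)
applies to the *mean* correlation before arctanh. Zero-variance voxels are
removed from the mask with a warning.

Voxelwise inference offers two engines: the exact per-voxel MixedLM fit,
and a fast engine that absorbs subject intercepts as fixed effects
(within-subject centring of data and design) and runs vectorised OLS. For
the within-subject contrasts they share the same point estimates; the
permutation loop uses the fast engine for both the observed and permuted
statistics, so observed and null maps are always computed identically.
The between-subject group main effect is not identifiable after centring
and is dropped (it is not a tested term).

Cluster-extent control follows the max-statistic permutation logic:

1. Per permutation, factor labels are randomly flipped: each subject's
   stim/sham labels swap with probability 1/2; each subject-condition
   pair's retrieval/rest labels swap with probability 1/2; group labels are
   permuted across subjects. tSNR stays attached to its scan. This respects
   within-subject exchangeability of the two within-subject factors and
   between-subject exchangeability of group under the null; the scheme is
   configurable because the historical "random flipping of factor labels"
   phrasing does not pin down one scheme.
2. The voxelwise model is refit, thresholded two-tailed at p < 0.05 (signs
   pooled; sign-split clustering available), components labelled with
   face adjacency by default (6-connectivity; 18/26 selectable), and the
   maximum cluster size recorded (0 if none).
3. The cutoff is the smallest size whose null exceedance probability is
   <= alpha; "that size or larger" survives (>=). With several effects
   tested, the largest cutoff applies to all.

Calibration: over 100 independent null studies (16^3 grid with eight
4^3-voxel signal communities, 8 subjects per group, 60 timepoints, 200
permutations each) the procedure admits at least one surviving cluster in
5% of studies — measured by `scripts/acceptance.py` and asserted (within
binomial error, +/-5 points) by the acceptance test.

## Drivers, allegiance, chi-square

Surviving clusters seed whole-brain Fisher-z correlation maps (cluster-mean
series vs every in-mask voxel). Driver inference reuses the voxelwise model
at p < 0.001 two-tailed with a fixed 20-voxel extent (no second permutation
stage). Allegiance: a cluster overlapping >= 1 voxel (configurable) of any
a-priori PMN/ATN sphere takes that network's label — a-priori spheres take
precedence over the 14-network reference volume; larger overlap wins, exact
ties go to PMN and are logged; otherwise the reference label with maximal
overlap; otherwise unassigned. The group x network count table is tested
with the Yates-corrected chi-square, each cell's correction floored so
(|O - E| - 1/2) never goes negative; the statistic matches
scipy.stats.chi2_contingency with continuity correction, and on the count
table 31/5 vs 12/13 it evaluates to 8.55.

## Behavior and the brain-behavior link

Item recognition = (hits + correct rejections) / trials. Context
recollection is conditional: correct context choices (one of six) among
high-confidence hits only; with zero high-confidence hits it is undefined
(NaN, flagged) and the subject is dropped pairwise from contrasts. Paired
t-tests are one-tailed in the improvement direction for post-stim vs
post-sham. The per-subject interaction effect is
(stim - sham | retrieval) - (stim - sham | rest) of cluster-mean
connectedness. The robust regression uses Huber M-estimation (tuning
constant 1.345, IRLS to 1e-8); with all standardised residuals inside the
threshold it coincides with OLS. The "robust F" is a Wald-type test of the
connectivity coefficient on the robust covariance with df (1, n - k) —
no claim of small-sample equivalence to any particular published robust-F
variant is made. r^2 is reported as the squared correlation between fitted
and observed values, labelled as such because no unique robust r^2 exists.

## Synthetic data: what it emulates, and what it does not

ROI series are draws from a multivariate Gaussian whose population
correlation between same-network regions is tanh(baseline_z + subject
intercept + planted increments), zero across networks — precisely the
structure the Pearson + Fisher-z mixed model assumes, so parameter-recovery
results are interpretable as estimator properties. The subject random
effect is additive on the z scale and shared across a subject's scans,
mirroring the downstream random intercept. Per-edge Gaussian jitter
(noise_sd) adds scan-level edge noise; tSNR heterogeneity is a log-normal
per-scan noise-scale multiplier, recorded as the covariate. Voxel phantoms
give each labelled community a shared latent signal with mixing chosen so
the within-community correlation equals tanh of the same z terms;
background voxels are independent noise. Behavioral context recollection is
binomial around a probability whose stim-sham change is
behavior_slope x interaction effect + Gaussian noise, truncated to [0, 1].

Defaults (package choices — the source study reports no Fisher-z effect
sizes): baseline_z 0.3 (a typical within-network coupling), delta_3way
0.25, subject_sd 0.1, noise_sd 0.05, community mixing 0.5, behavior slope
0.5 per unit z with SD 0.1, tSNR 60 with 0.2 log-SD, 42 old + 42 new test
trials with 6 context options per assessment.

Deliberately not modelled: hemodynamic response, physiological noise,
autocorrelated BOLD spectra, anatomy, registration error. Passing tests
therefore demonstrate correctness of the estimators and calibration of the
inference under the assumed generative structure, not robustness to
violations of it (e.g. temporal autocorrelation would make nominal df
optimistic on real data).

## Numerical conventions and degenerate inputs

- Correlation clamp |r| <= 1 - 1e-7 before arctanh everywhere.
- Sphere membership by voxel-centre distance, inclusive boundary;
  coordinates are mm in the dataset's common space via the NIfTI affine;
  voxel indices are 0-based.
- Stimulation-target selection breaks ties by distance to an anatomical
  anchor, then lexicographic voxel index.
- Identical maps across scans give t = 0, p = 1 (not NaN) in the fast
  voxelwise engine.
- All generators are deterministic under a fixed seed; the pipeline derives
  per-stage substreams from one global seed, so reruns are byte-identical
  and changing one stage's parameters leaves upstream outputs untouched.

## Problem sizes

Replicate-study summaries default to: 100 null studies for family-wise
error (16^3 grid, 8 subjects/group, 60 timepoints, 200 permutations); 200
studies for estimator bias and type-I error (16 subjects/group, 300
timepoints, 12-region atlas); 20 runs for direction checks. These sizes
keep Monte-Carlo error within the tolerances the tests assert (binomial SE
~2% at 100-200 replicates) on a single CPU.

## Known limitations

- The permutation engine's OLS refit treats subject intercepts as fixed
  effects; variance components are not re-estimated per permutation. This
  is exact for the within-subject contrasts' point estimates and calibrates
  correctly in the family-wise error simulation, but the permuted t values
  are not REML t values.
- Whether historical network means averaged r before transforming or
  transformed each edge first is ambiguous; this package transforms each
  edge then averages, stated here as an interpretation.
- The 14-network reference atlas is an input label volume; none is bundled.
- No scrubbing/censoring of retained frames, no partial correlation, no
  sliding-window connectivity, no TFCE or random-field cluster inference.
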