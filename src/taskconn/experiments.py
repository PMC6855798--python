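"""Replicate-study simulation drivers.

These functions run the full method on many independently generated synthetic
studies to measure its operating characteristics: family-wise error of the
permutation cluster-extent procedure, bias of the planted three-way
interaction estimate, type-I error of the mixed-model and robust
brain-behavior tests, and qualitative direction checks. They are the engines
behind the analysis scripts and the acceptance checks.

Problem sizes default to a desk scale chosen to keep Monte-Carlo error small
while the full suite stays re-runnable on one CPU: 16^3 voxel grids with
cubic signal communities, 8-16 subjects per group, and 100-200 replicate
studies per estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .behavior import robust_brain_behavior
from .connectedness import (apply_cutoff, global_connectedness,
                            permutation_cluster_cutoff, threshold_and_label,
                            voxelwise_lme)
from .drivers import classify_allegiance
from .lme import THREEWAY_TERM, TWOWAY_TERM, fit_lme
from .roi import ROIAtlas, connectivity_matrix, scan_connectivity_table
from .synthetic import (EffectSpec, block_community_map, make_design,
                        simulate_behavior, simulate_roi_timeseries,
                        simulate_voxel_dataset)

__all__ = [
    "default_atlas",
    "atlas_from_communities",
    "null_fwer_simulation",
    "threeway_recovery_simulation",
    "robust_behavior_simulation",
    "task_direction_check",
    "allegiance_chain_study",
]

#: Null generating conditions: no planted interaction or task effect, but
#: realistic baseline coupling, subject heterogeneity, and tSNR variation.
NULL_EFFECTS = EffectSpec(delta_3way=0.0, delta_task=0.0)


def _study_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def default_atlas() -> ROIAtlas:
    """A-priori PMN/ATN sphere atlas (6 regions per network, 6 mm radius).

    Coordinates are representative peak locations in a common mm space; for
    ROI-level simulation only the name/network structure matters.
    """
    rows = [
        ("precuneus", "PMN", -6, -62, 32), ("retrosplenial", "PMN", -8, -52, 10),
        ("parahippocampal", "PMN", -26, -36, -14), ("angular", "PMN", -44, -66, 28),
        ("post_cingulate", "PMN", -2, -40, 30), ("med_prefrontal", "PMN", -4, 52, 8),
        ("perirhinal", "ATN", -28, -8, -30), ("ant_temporal", "ATN", -46, 2, -32),
        ("amygdala", "ATN", -22, -4, -18), ("lat_orbitofrontal", "ATN", -32, 34, -12),
        ("ant_fusiform", "ATN", -34, -18, -28), ("temporopolar", "ATN", -40, 14, -28),
    ]
    return ROIAtlas(pd.DataFrame(rows, columns=["name", "network", "x_mm",
                                                "y_mm", "z_mm"]))


def atlas_from_communities(community_map: np.ndarray, networks: dict,
                           affine=None, radius_mm: float = 3.0) -> ROIAtlas:
    """Sphere atlas centred on community centroids of a synthetic phantom.

    ``networks`` maps community label -> network name ('PMN'/'ATN').
    """
    if affine is None:
        affine = np.eye(4)
    affine = np.asarray(affine, dtype=float)
    rows = []
    for label, network in networks.items():
        vox = np.argwhere(community_map == label)
        if vox.size == 0:
            raise ValueError(f"community {label} empty")
        centroid = vox.mean(axis=0)
        mm = affine[:3, :3] @ centroid + affine[:3, 3]
        rows.append({"name": f"community_{label}", "network": network,
                     "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
                     "radius_mm": radius_mm})
    return ROIAtlas(pd.DataFrame(rows))


@dataclass
class FWERResult:
    any_survivor: np.ndarray     # per-study bool
    cutoffs: np.ndarray          # per-study permutation cutoff (voxels)
    n_studies: int

    @property
    def rate(self) -> float:
        return float(self.any_survivor.mean())


def _null_study_survives(study_seed: int, n_per_group: int, grid_shape,
                         community_map, effects: EffectSpec,
                         n_timepoints: int, n_permutations: int, alpha: float,
                         p_two_tailed: float):
    design = make_design(n_per_group, seed=study_seed)
    volumes, mask, scans = simulate_voxel_dataset(
        design, grid_shape, community_map, effects, n_timepoints,
        seed=study_seed + 1)
    maps = []
    eff_mask = mask
    for vol in volumes:
        vol_map, eff_mask = global_connectedness(vol, eff_mask)
        maps.append(vol_map)
    null = permutation_cluster_cutoff(
        maps, scans, eff_mask, terms=(THREEWAY_TERM,),
        n_permutations=n_permutations, alpha=alpha,
        p_two_tailed=p_two_tailed, seed=study_seed + 2,
        min_permutations=min(100, n_permutations))
    statmap = voxelwise_lme(maps, scans, eff_mask, term=THREEWAY_TERM)
    clusters = threshold_and_label(statmap, p_two_tailed=p_two_tailed)
    surviving = apply_cutoff(clusters, null.cutoff)
    return surviving.n_clusters > 0, null.cutoff


def null_fwer_simulation(n_studies: int = 100, seed: int = 0,
                         n_per_group: int = 8, grid_shape=(16, 16, 16),
                         n_timepoints: int = 60, n_permutations: int = 200,
                         alpha: float = 0.05, p_two_tailed: float = 0.05,
                         effects: EffectSpec = NULL_EFFECTS,
                         n_communities: int = 8) -> FWERResult:
    """Family-wise error of the permutation cluster-extent procedure.

    Generates ``n_studies`` null synthetic studies, derives each study's
    cluster-size cutoff from its own label-flipping permutation null, and
    records whether any observed cluster survives. Under the null the
    surviving fraction should match ``alpha`` within binomial error.
    """
    community_map = block_community_map(grid_shape, n_communities)
    flags, cutoffs = [], []
    for study_seed in _study_seeds(seed, n_studies):
        survived, cutoff = _null_study_survives(
            study_seed, n_per_group, grid_shape, community_map, effects,
            n_timepoints, n_permutations, alpha, p_two_tailed)
        flags.append(survived)
        cutoffs.append(cutoff)
    return FWERResult(any_survivor=np.asarray(flags),
                      cutoffs=np.asarray(cutoffs), n_studies=n_studies)


@dataclass
class RecoveryResult:
    betas: np.ndarray
    pvalues: np.ndarray
    delta: float

    @property
    def mean_beta(self) -> float:
        return float(self.betas.mean())

    @property
    def bias(self) -> float:
        return self.mean_beta - self.delta

    @property
    def rejection_rate(self) -> float:
        return float((self.pvalues < 0.05).mean())


def threeway_recovery_simulation(n_studies: int = 200, seed: int = 0,
                                 delta: float = 0.25, n_per_group: int = 16,
                                 n_timepoints: int = 300,
                                 effects: EffectSpec | None = None,
                                 network: str = "PMN") -> RecoveryResult:
    """Estimate the three-way interaction across replicate ROI-level studies.

    With ``delta=0`` this measures the type-I error of the three-way test;
    with a planted delta it measures bias and power of the REML estimate.
    """
    atlas = default_atlas()
    base = effects or EffectSpec()
    spec = replace(base, delta_3way=delta)
    betas, pvals = [], []
    for study_seed in _study_seeds(seed, n_studies):
        design = make_design(n_per_group, seed=study_seed)
        series_list, scans = simulate_roi_timeseries(
            design, atlas, spec, n_timepoints, seed=study_seed + 1)
        matrices = [connectivity_matrix(s, atlas.names) for s in series_list]
        table = scan_connectivity_table(matrices, scans, atlas,
                                        networks=(network,))
        res = fit_lme(table, model="threeway")
        row = res.term(THREEWAY_TERM)
        betas.append(row["beta"])
        pvals.append(row["p"])
    return RecoveryResult(betas=np.asarray(betas), pvalues=np.asarray(pvals),
                          delta=delta)


@dataclass
class RobustSimResult:
    slopes: np.ndarray
    pvalues: np.ndarray
    slope: float

    @property
    def mean_slope(self) -> float:
        return float(self.slopes.mean())

    @property
    def rejection_rate(self) -> float:
        return float((self.pvalues < 0.05).mean())


def robust_behavior_simulation(n_studies: int = 200, seed: int = 0,
                               slope: float = 0.0, n_subjects: int = 32,
                               effect_sd: float = 0.3,
                               effects: EffectSpec | None = None) -> RobustSimResult:
    """Robust brain-behavior regression over replicate behavioural studies.

    Per study, per-subject connectivity interaction effects are drawn
    N(0, effect_sd^2), trial-level memory data are generated with the given
    coupling slope, and the Huber regression slope/p for the connectivity
    term are recorded. ``slope=0`` measures type-I error; a positive slope
    measures recovery.
    """
    base = effects or EffectSpec()
    spec = replace(base, behavior_slope=slope)
    design_template = make_design(max(1, n_subjects // 2), seed=0)
    slopes, pvals = [], []
    for study_seed in _study_seeds(seed, n_studies):
        rng = np.random.default_rng(study_seed)
        subjects = design_template["subject"].unique()
        ie = pd.Series(rng.normal(0.0, effect_sd, size=subjects.size),
                       index=subjects)
        _, scores = simulate_behavior(design_template, ie, spec,
                                      seed=study_seed + 1)
        wide = scores.pivot(index="subject", columns="assessment",
                            values="context_recollection")
        change = (wide["post_stim"] - wide["post_sham"]).reindex(subjects)
        fit = robust_brain_behavior(ie.to_numpy(), change.to_numpy())
        slopes.append(fit.slope)
        pvals.append(fit.p)
    return RobustSimResult(slopes=np.asarray(slopes),
                           pvalues=np.asarray(pvals), slope=slope)


def task_direction_check(n_runs: int = 20, seed: int = 0,
                         delta_task: float = 0.3, n_per_group: int = 4,
                         grid_shape=(12, 12, 12), n_timepoints: int = 80,
                         n_communities: int = 4) -> float:
    """Fraction of runs where the task main effect is positive in communities.

    Plants higher within-community coupling during retrieval than rest and
    checks that the voxelwise task main effect (retrieval minus rest) has a
    positive mean t inside community voxels.
    """
    community_map = block_community_map(grid_shape, n_communities)
    effects = replace(NULL_EFFECTS, delta_task=delta_task)
    hits = 0
    for study_seed in _study_seeds(seed, n_runs):
        design = make_design(n_per_group, seed=study_seed)
        volumes, mask, scans = simulate_voxel_dataset(
            design, grid_shape, community_map, effects, n_timepoints,
            seed=study_seed + 1)
        maps = []
        eff_mask = mask
        for vol in volumes:
            vol_map, eff_mask = global_connectedness(vol, eff_mask)
            maps.append(vol_map)
        statmap = voxelwise_lme(maps, scans, eff_mask, term="task")
        in_comm = (community_map > 0) & eff_mask
        if np.nanmean(statmap.tstat[in_comm]) > 0:
            hits += 1
    return hits / n_runs


def allegiance_chain_study(seed: int = 0, n_per_group: int = 8,
                           grid_shape=(16, 16, 16), n_timepoints: int = 100,
                           delta: float = 0.5, n_communities: int = 8,
                           p_two_tailed: float = 0.05, min_extent: int = 4):
    """Full connectedness -> clusters -> allegiance chain on one phantom.

    The first half of the communities are PMN, the second half ATN (sphere
    atlas at community centroids); the condition x task effect is planted
    only in PMN communities and only materialises for the PMN-targeted
    group's stim-retrieval scans. Per group, a two-way (condition x task)
    model is fit and surviving clusters are classified, yielding a group x
    network count table.
    """
    community_map = block_community_map(grid_shape, n_communities)
    labels = sorted(int(c) for c in np.unique(community_map) if c)
    half = len(labels) // 2
    networks = {c: ("PMN" if i < half else "ATN")
                for i, c in enumerate(labels)}
    atlas = atlas_from_communities(community_map, networks)
    effects = replace(NULL_EFFECTS, delta_3way=delta)
    design = make_design(n_per_group, seed=seed)
    planted = [c for c, net in networks.items() if net == "PMN"]
    volumes, mask, scans = simulate_voxel_dataset(
        design, grid_shape, community_map, effects, n_timepoints,
        seed=seed + 1, planted_communities=planted)
    maps = []
    eff_mask = mask
    for vol in volumes:
        vol_map, eff_mask = global_connectedness(vol, eff_mask)
        maps.append(vol_map)
    reference = np.zeros(grid_shape, dtype=int)  # no extra reference atlas
    counts = {}
    for group in ("PMN", "PFC"):
        rows = scans["group"] == group
        group_maps = [m for m, keep in zip(maps, rows) if keep]
        statmap = voxelwise_lme(group_maps, scans.loc[rows], eff_mask,
                                term=TWOWAY_TERM, model="twoway")
        clusters = apply_cutoff(
            threshold_and_label(statmap, p_two_tailed=p_two_tailed),
            min_extent)
        if clusters.n_clusters:
            alle = classify_allegiance(clusters, atlas, reference)
            counts[group] = {
                "PMN": int((alle["label"] == "PMN").sum()),
                "ATN": int((alle["label"] == "ATN").sum()),
            }
        else:
            counts[group] = {"PMN": 0, "ATN": 0}
    table = np.array([[counts["PMN"]["PMN"], counts["PMN"]["ATN"]],
                      [counts["PFC"]["PMN"], counts["PFC"]["ATN"]]])
    return table, counts
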