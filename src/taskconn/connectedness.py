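"""Whole-brain global connectedness and permutation cluster-extent inference.

Global connectedness stores, at each in-mask voxel, the Fisher-z of its mean
Pearson correlation with every other in-mask voxel. Voxelwise condition
contrasts use the same subject-random-intercept model as the ROI analysis;
cluster-extent false positives are controlled by a label-flipping permutation
null: the model is refit under random exchanges of the within-subject
condition/task labels and of the between-subject group labels, and the
cluster-size cutoff is the smallest size whose null exceedance probability is
at most alpha. When several effects are tested, the most stringent (largest)
cutoff is applied to all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .lme import THREEWAY_TERM, design_matrix, fit_lme
from .roi import fisher_z
from .volume import VolumeSeries

__all__ = [
    "StatMap",
    "ClusterSet",
    "PermutationNull",
    "global_connectedness",
    "voxelwise_lme",
    "threshold_and_label",
    "permutation_cluster_cutoff",
    "apply_cutoff",
    "permute_design",
]


def _series_data(series) -> np.ndarray:
    return series.data if isinstance(series, VolumeSeries) else np.asarray(series, dtype=float)


def global_connectedness(series, mask: np.ndarray):
    """Fisher-z of each in-mask voxel's mean correlation with all others.

    Computed via standardized-data sums (O(voxels x time)) and therefore
    algebraically identical to the brute-force double loop over voxel pairs.
    Zero-variance voxels are removed from the mask with a warning. Returns
    ``(volume, effective_mask)`` with NaN outside the effective mask.
    """
    data = _series_data(series)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[0] < 3:
        raise ValueError("need >= 3 frames")
    if mask.shape != data.shape[1:]:
        raise ValueError("mask shape does not match volume grid")
    flat = data.reshape(data.shape[0], -1)[:, mask.ravel()]
    sd = flat.std(axis=0)
    good = sd > 0
    if (~good).any():
        warnings.warn(f"{(~good).sum()} zero-variance voxels removed from "
                      "connectedness mask", RuntimeWarning, stacklevel=2)
    eff_mask = mask.copy()
    eff_idx = np.flatnonzero(mask.ravel())[good]
    eff_mask.ravel()[np.flatnonzero(mask.ravel())[~good]] = False
    n_vox = int(good.sum())
    if n_vox < 2:
        raise ValueError("need >= 2 usable in-mask voxels")
    X = flat[:, good]
    Xc = X - X.mean(axis=0)
    Z = Xc / np.linalg.norm(Xc, axis=0)  # columns: unit-norm centred series
    s = Z.sum(axis=1)
    # sum_j r(i, j) = z_i . s ; subtract the self term r(i, i) = 1
    mean_r = (Z.T @ s - 1.0) / (n_vox - 1)
    values = fisher_z(mean_r)
    out = np.full(mask.shape, np.nan)
    out.ravel()[eff_idx] = values
    return out, eff_mask


@dataclass
class StatMap:
    """Voxelwise beta / t / p volumes for one fixed-effect term."""

    beta: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    term: str
    model: str = "threeway"
    n_failed: int = 0


@dataclass
class ClusterSet:
    """Connected-component labelling of suprathreshold voxels.

    ``labels`` is an integer volume (0 = background); ``table`` has one row
    per cluster: id, size, peak |t| coordinate, peak t, sign summary, and
    mean effect.
    """

    labels: np.ndarray
    table: pd.DataFrame
    p_threshold: float
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    @property
    def sizes(self) -> np.ndarray:
        return self.table["size"].to_numpy() if len(self.table) else np.array([], int)

    def voxels(self, cluster_id: int) -> np.ndarray:
        return np.argwhere(self.labels == cluster_id)


@dataclass
class PermutationNull:
    """Max-cluster-size null distribution(s) and the derived cutoff."""

    max_sizes: dict  # term -> (n_permutations,) array
    cutoffs: dict    # term -> int
    cutoff: int      # most stringent (largest) cutoff across terms
    alpha: float
    p_two_tailed: float
    n_permutations: int
    seed: int
    scheme: str = "flip_condition_task_permute_group"


# ---- fast within-subject OLS refits ---------------------------------------

_ALWAYS_WITHIN_DROPPED = {"intercept", "group"}


def _center_within_subject(A: np.ndarray, subject_codes: np.ndarray) -> np.ndarray:
    out = A.astype(float).copy()
    for s in np.unique(subject_codes):
        rows = subject_codes == s
        out[rows] -= out[rows].mean(axis=0)
    return out


def _fast_term_stats(Y_centered: np.ndarray, scans: pd.DataFrame,
                     subject_codes: np.ndarray, terms, model: str,
                     n_subjects: int):
    """Per-voxel OLS t/beta for the requested terms with subject fixed
    effects absorbed by within-subject centering."""
    X, names = design_matrix(scans, model=model, hierarchy="full")
    Xc = _center_within_subject(X, subject_codes)
    norms = np.linalg.norm(Xc, axis=0)
    keep = norms > 1e-10
    Xc, kept_names = Xc[:, keep], [n for n, k in zip(names, keep) if k]
    missing = [t for t in terms if t not in kept_names]
    if missing:
        raise ValueError(f"terms {missing} not identifiable after "
                         "within-subject centering")
    n, p = Xc.shape
    dof = n - n_subjects - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom for the fast refit")
    G = np.linalg.inv(Xc.T @ Xc)
    beta = G @ (Xc.T @ Y_centered)
    resid = Y_centered - Xc @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    out = {}
    for term in terms:
        j = kept_names.index(term)
        se = np.sqrt(sigma2 * G[j, j])
        b = beta[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / se
        t = np.where(se > 1e-12, t, np.where(np.abs(b) <= 1e-12, 0.0,
                                             np.sign(b) * np.inf))
        pvals = 2 * stats.t.sf(np.abs(t), dof)
        out[term] = (b, t, pvals, dof)
    return out


def _stack_maps(maps, mask: np.ndarray) -> np.ndarray:
    mask_flat = np.asarray(mask, dtype=bool).ravel()
    rows = []
    for m in maps:
        arr = np.asarray(m, dtype=float).ravel()[mask_flat]
        if np.any(np.isnan(arr)):
            raise ValueError("NaN map values inside the analysis mask")
        rows.append(arr)
    return np.asarray(rows)


def voxelwise_lme(maps, scans: pd.DataFrame, mask: np.ndarray,
                  term: str = THREEWAY_TERM, model: str = "threeway",
                  backend: str = "ols_within") -> StatMap:
    """Fit the condition-contrast model at every in-mask voxel.

    ``backend="mixedlm"`` runs the full REML random-intercept fit per voxel
    (slow; exact); ``backend="ols_within"`` absorbs the subject intercepts as
    fixed effects and runs a vectorised OLS refit, which shares the same
    fixed-effect point estimates and is the engine used inside the
    permutation loop.
    """
    mask = np.asarray(mask, dtype=bool)
    Y = _stack_maps(maps, mask)
    if Y.shape[0] != len(scans):
        raise ValueError("one map per scan row required")
    shape = mask.shape
    beta_v = np.full(shape, np.nan)
    t_v = np.full(shape, np.nan)
    p_v = np.full(shape, np.nan)
    idx = np.flatnonzero(mask.ravel())
    n_failed = 0
    if backend == "ols_within":
        subj = pd.factorize(scans["subject"])[0]
        Yc = _center_within_subject(Y, subj)
        res = _fast_term_stats(Yc, scans, subj, [term], model,
                               n_subjects=len(np.unique(subj)))
        b, t, p, _ = res[term]
        beta_v.ravel()[idx] = b
        t_v.ravel()[idx] = t
        p_v.ravel()[idx] = p
    elif backend == "mixedlm":
        for col, flat_i in enumerate(idx):
            table = scans.copy()
            table["value"] = Y[:, col]
            try:
                row = fit_lme(table, model=model).term(term)
            except Exception:
                n_failed += 1
                continue
            beta_v.ravel()[flat_i] = row["beta"]
            t_v.ravel()[flat_i] = row["t"]
            p_v.ravel()[flat_i] = row["p"]
        if n_failed:
            warnings.warn(f"{n_failed} voxels failed to fit and were masked "
                          "out", RuntimeWarning, stacklevel=2)
    else:
        raise ValueError("backend must be 'ols_within' or 'mixedlm'")
    return StatMap(beta=beta_v, tstat=t_v, p=p_v, mask=mask, term=term,
                   model=model, n_failed=n_failed)


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def threshold_and_label(statmap: StatMap, p_two_tailed: float = 0.05,
                        connectivity: int = 6,
                        sign_split: bool = False) -> ClusterSet:
    """Label connected suprathreshold components (p < threshold, two signs
    pooled by default; ``sign_split`` clusters positive and negative voxels
    separately)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18, or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    supra = (statmap.p < p_two_tailed) & statmap.mask & np.isfinite(statmap.p)
    if sign_split:
        lab_pos, n_pos = ndimage.label(supra & (statmap.tstat > 0), structure)
        lab_neg, n_neg = ndimage.label(supra & (statmap.tstat < 0), structure)
        labels = lab_pos + np.where(lab_neg > 0, lab_neg + n_pos, 0)
        n_clusters = n_pos + n_neg
    else:
        labels, n_clusters = ndimage.label(supra, structure)
    rows = []
    for cid in range(1, n_clusters + 1):
        vox = np.argwhere(labels == cid)
        tvals = statmap.tstat[tuple(vox.T)]
        bvals = statmap.beta[tuple(vox.T)]
        peak = vox[np.argmax(np.abs(tvals))]
        if np.all(tvals > 0):
            sign = "pos"
        elif np.all(tvals < 0):
            sign = "neg"
        else:
            sign = "mixed"
        rows.append({"id": cid, "size": len(vox),
                     "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                     "peak_z": int(peak[2]),
                     "peak_t": float(tvals[np.argmax(np.abs(tvals))]),
                     "sign": sign, "mean_beta": float(bvals.mean())})
    table = pd.DataFrame(rows, columns=["id", "size", "peak_x", "peak_y",
                                        "peak_z", "peak_t", "sign",
                                        "mean_beta"])
    return ClusterSet(labels=labels, table=table, p_threshold=p_two_tailed,
                      connectivity=connectivity)


def permute_design(scans: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One random flip of the factor labels.

    Independently per subject, swap that subject's stim/sham labels with
    probability 1/2; independently per subject-condition pair, swap its
    retrieval/rest labels with probability 1/2; and randomly permute the
    group labels across subjects. tSNR stays attached to its scan.
    """
    out = scans.reset_index(drop=True).copy()
    subj_codes = pd.factorize(out["subject"])[0]
    n_subjects = subj_codes.max() + 1
    is_stim = (out["condition"] == "stim").to_numpy()
    is_retrieval = (out["task"] == "retrieval").to_numpy()
    flip_cond = rng.random(n_subjects) < 0.5
    new_stim = is_stim ^ flip_cond[subj_codes]
    # subject-condition cells are the same scan pairs before/after the
    # condition flip, so the original condition indexes them
    cell = subj_codes * 2 + is_stim.astype(int)
    flip_task = rng.random(2 * n_subjects) < 0.5
    new_retrieval = is_retrieval ^ flip_task[cell]
    first_row = np.unique(subj_codes, return_index=True)[1]
    permuted_groups = rng.permutation(out["group"].to_numpy()[first_row])
    out["condition"] = np.where(new_stim, "stim", "sham")
    out["task"] = np.where(new_retrieval, "retrieval", "rest")
    out["group"] = permuted_groups[subj_codes]
    return out


def _max_cluster_size(p_flat: np.ndarray, mask: np.ndarray,
                      p_two_tailed: float, structure) -> int:
    supra = np.zeros(mask.shape, dtype=bool)
    supra.ravel()[np.flatnonzero(mask.ravel())] = p_flat < p_two_tailed
    labels, n = ndimage.label(supra, structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_cutoff_from_sizes(max_sizes: np.ndarray, alpha: float) -> int:
    """Smallest size k whose null exceedance P(max >= k) is <= alpha."""
    sizes = np.asarray(max_sizes)
    for k in range(1, int(sizes.max()) + 2):
        if np.mean(sizes >= k) <= alpha:
            return k
    raise AssertionError("unreachable")


def permutation_cluster_cutoff(maps, scans: pd.DataFrame, mask: np.ndarray,
                               terms=(THREEWAY_TERM,), model: str = "threeway",
                               n_permutations: int = 1000, alpha: float = 0.05,
                               p_two_tailed: float = 0.05,
                               connectivity: int = 6, seed: int = 0,
                               min_permutations: int = 100) -> PermutationNull:
    """Label-flipping permutation null of the maximum cluster size.

    Per permutation the factor labels are randomly flipped
    (:func:`permute_design`), the voxelwise model is refit with the fast
    within-subject OLS engine, the map is thresholded at ``p_two_tailed``,
    and the maximum suprathreshold cluster size is recorded (0 when nothing
    survives). The cutoff per term is the smallest size with exceedance
    probability <= alpha; the overall cutoff is the largest across terms.
    """
    if n_permutations < min_permutations:
        raise ValueError(f"need >= {min_permutations} permutations for a "
                         "reportable cutoff")
    mask = np.asarray(mask, dtype=bool)
    terms = list(terms)
    Y = _stack_maps(maps, mask)
    if Y.shape[0] != len(scans):
        raise ValueError("one map per scan row required")
    subj = pd.factorize(scans["subject"])[0]
    n_subjects = len(np.unique(subj))
    Yc = _center_within_subject(Y, subj)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    rng = np.random.default_rng(seed)
    max_sizes = {t: np.zeros(n_permutations, dtype=int) for t in terms}
    for b in range(n_permutations):
        permuted = permute_design(scans, rng)
        res = _fast_term_stats(Yc, permuted, subj, terms, model, n_subjects)
        for term in terms:
            _, _, pvals, _ = res[term]
            max_sizes[term][b] = _max_cluster_size(pvals, mask, p_two_tailed,
                                                   structure)
    cutoffs = {t: cluster_cutoff_from_sizes(max_sizes[t], alpha) for t in terms}
    return PermutationNull(max_sizes=max_sizes, cutoffs=cutoffs,
                           cutoff=max(cutoffs.values()), alpha=alpha,
                           p_two_tailed=p_two_tailed,
                           n_permutations=n_permutations, seed=seed)


def apply_cutoff(clusters: ClusterSet, cutoff: int) -> ClusterSet:
    """Retain clusters whose size is >= cutoff ("that size or larger")."""
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    keep = clusters.table[clusters.table["size"] >= cutoff]
    labels = np.where(np.isin(clusters.labels, keep["id"].to_numpy()),
                      clusters.labels, 0)
    return ClusterSet(labels=labels, table=keep.reset_index(drop=True),
                      p_threshold=clusters.p_threshold,
                      connectivity=clusters.connectivity)
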