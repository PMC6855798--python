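"""Seed-based driver maps, network-allegiance classification, and the
Yates-corrected chi-square on allegiance counts.

Clusters surviving the whole-brain interaction analysis are used as seeds:
each cluster's spatially averaged series is correlated with every in-mask
voxel (Fisher z). Driver inference applies the same voxelwise model at a
stricter voxel threshold (p < 0.001 two-tailed) with a fixed 20-voxel extent.
Surviving clusters are assigned to the posterior-medial (PMN) or
anterior-temporal (ATN) network when they overlap an a-priori network sphere,
falling back to a reference label volume of resting-state networks, and the
PMN/ATN distribution across stimulation targets is compared by a
Yates-corrected chi-square.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .connectedness import (ClusterSet, apply_cutoff, threshold_and_label,
                            voxelwise_lme)
from .lme import THREEWAY_TERM
from .roi import ROIAtlas, fisher_z, sphere_voxels
from .volume import VolumeSeries

__all__ = [
    "seed_driver_map",
    "driver_inference",
    "classify_allegiance",
    "overlap_fraction",
    "yates_chi2",
]


def seed_driver_map(series, cluster_voxels: np.ndarray, mask: np.ndarray):
    """Fisher-z correlation of a cluster's mean series with every in-mask voxel."""
    data = series.data if isinstance(series, VolumeSeries) else np.asarray(series, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vox = np.asarray(cluster_voxels, dtype=int)
    if vox.size == 0:
        raise ValueError("empty seed cluster")
    seed = data[:, vox[:, 0], vox[:, 1], vox[:, 2]].mean(axis=1)
    seed = seed - seed.mean()
    norm = np.linalg.norm(seed)
    if norm == 0:
        raise ValueError("zero-variance seed series")
    seed /= norm
    flat = data.reshape(data.shape[0], -1)[:, mask.ravel()]
    flat = flat - flat.mean(axis=0)
    norms = np.linalg.norm(flat, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (seed @ flat) / norms
    r[norms == 0] = 0.0
    out = np.full(mask.shape, np.nan)
    out.ravel()[np.flatnonzero(mask.ravel())] = fisher_z(r)
    return out


def driver_inference(maps, scans: pd.DataFrame, mask: np.ndarray,
                     term: str = THREEWAY_TERM, model: str = "threeway",
                     p_two_tailed: float = 0.001, min_extent: int = 20,
                     connectivity: int = 6,
                     backend: str = "ols_within") -> ClusterSet:
    """Voxelwise model on seed maps at the stricter driver threshold.

    Thresholds at ``p_two_tailed`` (default 0.001) and keeps clusters of at
    least ``min_extent`` contiguous voxels (fixed extent; no permutation
    stage here).
    """
    statmap = voxelwise_lme(maps, scans, mask, term=term, model=model,
                            backend=backend)
    clusters = threshold_and_label(statmap, p_two_tailed=p_two_tailed,
                                   connectivity=connectivity)
    return apply_cutoff(clusters, min_extent)


def _sphere_mask(atlas: ROIAtlas, network: str, shape, affine, mask):
    out = np.zeros(shape, dtype=bool)
    for name in atlas.members(network):
        row = atlas.regions.set_index("name").loc[name]
        try:
            vox = sphere_voxels(atlas.center_mm(name), row["radius_mm"],
                                shape, affine=affine, mask=mask, name=name)
        except ValueError:
            continue  # sphere entirely off-grid: contributes no overlap
        out[tuple(vox.T)] = True
    return out


def classify_allegiance(clusters: ClusterSet, atlas: ROIAtlas,
                        reference_networks: np.ndarray,
                        reference_legend: dict | None = None,
                        affine=None, min_overlap: int = 1) -> pd.DataFrame:
    """Assign each cluster a network label.

    A cluster overlapping at least ``min_overlap`` voxels of any a-priori PMN
    or ATN sphere is assigned to that network (larger overlap wins; exact
    ties go to PMN and are logged). Otherwise it takes the reference-atlas
    label with maximal overlap, or 'unassigned' when it overlaps nothing.
    """
    reference_networks = np.asarray(reference_networks)
    if reference_networks.shape != clusters.labels.shape:
        raise ValueError("reference atlas not in the cluster volume's space")
    shape = clusters.labels.shape
    sphere_masks = {net: _sphere_mask(atlas, net, shape, affine, None)
                    for net in ("PMN", "ATN") if net in atlas.networks}
    legend = reference_legend or {}
    rows = []
    for cid in clusters.table["id"]:
        cluster_mask = clusters.labels == cid
        counts = {net: int((cluster_mask & m).sum())
                  for net, m in sphere_masks.items()}
        pmn, atn = counts.get("PMN", 0), counts.get("ATN", 0)
        tie = False
        if max(pmn, atn) >= min_overlap:
            if pmn == atn:
                tie = True
                label = "PMN"
            else:
                label = "PMN" if pmn > atn else "ATN"
        else:
            ref_labels = reference_networks[cluster_mask]
            ref_labels = ref_labels[ref_labels != 0]
            if ref_labels.size == 0:
                label = "unassigned"
            else:
                vals, n = np.unique(ref_labels, return_counts=True)
                best = int(vals[np.argmax(n)])
                label = str(legend.get(best, f"reference_{best}"))
        if tie:
            warnings.warn(f"cluster {cid}: PMN/ATN overlap tie ({pmn} voxels); "
                          "assigned PMN", RuntimeWarning, stacklevel=2)
        rows.append({"id": int(cid), "label": label, "pmn_overlap": pmn,
                     "atn_overlap": atn, "tie": tie})
    return pd.DataFrame(rows, columns=["id", "label", "pmn_overlap",
                                       "atn_overlap", "tie"])


def overlap_fraction(clusters: ClusterSet, reference: np.ndarray):
    """Fraction of clusters sharing >= 1 voxel with a reference mask.

    Undefined (None, with a warning) for an empty cluster set.
    """
    reference = np.asarray(reference, dtype=bool)
    if reference.shape != clusters.labels.shape:
        raise ValueError("reference mask not in the cluster volume's space")
    if clusters.n_clusters == 0:
        warnings.warn("no clusters: overlap fraction undefined",
                      RuntimeWarning, stacklevel=2)
        return None
    hits = sum(bool((clusters.labels == cid)[reference].any())
               for cid in clusters.table["id"])
    return hits / clusters.n_clusters


def yates_chi2(table) -> tuple[float, int, float]:
    """Yates continuity-corrected chi-square for a 2x2 contingency table.

    statistic = sum over cells of (max(|O - E| - 0.5, 0))^2 / E with E from
    the row/column marginals; p from the chi-square distribution with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal: chi-square undefined")
    expected = np.outer(row, col) / total
    corrected = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float((corrected ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, 1))
    return statistic, 1, p
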