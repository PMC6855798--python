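"""ROI-sphere extraction, Fisher-z connectivity, and network summaries.

Network regions are spheres (default radius 6 mm) around a-priori peak
coordinates, grouped into the posterior-medial network (PMN) and the
anterior-temporal network (ATN). Pairwise region connectivity is the Pearson
correlation of spatially averaged ROI time series, Fisher z-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import VolumeSeries

__all__ = [
    "ROIAtlas",
    "ConnectivityMatrix",
    "sphere_voxels",
    "extract_mean_timeseries",
    "connectivity_matrix",
    "network_interconnectivity",
    "region_mean_connectivity",
    "select_stimulation_target",
    "scan_connectivity_table",
    "CLAMP",
]

#: Correlations are clamped to |r| <= 1 - CLAMP before arctanh so that
#: identical series map to a large finite Fisher z instead of infinity.
CLAMP = 1e-7

ATLAS_COLUMNS = ["name", "network", "x_mm", "y_mm", "z_mm", "radius_mm"]


@dataclass
class ROIAtlas:
    """Spherical ROI atlas: one row per region (name, network, centre, radius)."""

    regions: pd.DataFrame

    def __post_init__(self):
        df = self.regions.copy()
        if "radius_mm" not in df.columns:
            df["radius_mm"] = 6.0
        df["radius_mm"] = df["radius_mm"].fillna(6.0)
        missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"atlas missing columns {missing}")
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate region names: {dup}")
        if (df["radius_mm"] <= 0).any():
            raise ValueError("all radii must be positive")
        self.regions = df.reset_index(drop=True)

    @property
    def names(self) -> list[str]:
        return self.regions["name"].tolist()

    def members(self, network: str) -> list[str]:
        return self.regions.loc[self.regions["network"] == network, "name"].tolist()

    @property
    def networks(self) -> list[str]:
        return sorted(self.regions["network"].unique())

    def center_mm(self, name: str) -> np.ndarray:
        row = self.regions.set_index("name").loc[name]
        return np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)

    @classmethod
    def from_csv(cls, path) -> "ROIAtlas":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.regions[ATLAS_COLUMNS].to_csv(path, index=False)


def _voxel_centers_mm(shape, affine) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-centre coordinates in mm."""
    idx = np.indices(shape).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    mm = (np.asarray(affine) @ homog)[:3]
    return mm.T.reshape(*shape, 3)


def sphere_voxels(center_mm, radius_mm, shape, affine=None,
                  mask: np.ndarray | None = None,
                  name: str | None = None) -> np.ndarray:
    """Voxels whose centre lies within ``radius_mm`` (inclusive) of a point.

    Returns an (n, 3) integer index array, intersected with ``mask`` when one
    is provided. An empty result (sphere entirely off-mask) is an error that
    names the offending region.
    """
    center = np.asarray(center_mm, dtype=float).reshape(3)
    if affine is None:
        affine = np.eye(4)
    centers = _voxel_centers_mm(tuple(shape), affine)
    dist2 = ((centers - center) ** 2).sum(axis=-1)
    inside = dist2 <= float(radius_mm) ** 2 + 1e-12
    if mask is not None:
        inside &= np.asarray(mask, dtype=bool)
    voxels = np.argwhere(inside)
    if voxels.size == 0:
        label = name or f"sphere at {center.tolist()}"
        raise ValueError(f"ROI {label!r}: no in-mask voxels within "
                         f"{radius_mm} mm")
    return voxels


def extract_mean_timeseries(series: VolumeSeries | np.ndarray,
                            voxels: np.ndarray) -> np.ndarray:
    """Unweighted mean time series over a voxel index set."""
    data = series.data if isinstance(series, VolumeSeries) else np.asarray(series)
    voxels = np.asarray(voxels, dtype=int)
    if voxels.size == 0:
        raise ValueError("empty voxel set")
    return data[:, voxels[:, 0], voxels[:, 1], voxels[:, 2]].mean(axis=1)


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region Fisher-z connectivity for one scan.

    The diagonal carries the clamped maximum (a region is perfectly
    correlated with itself) and is excluded from every summary.
    """

    values: np.ndarray
    region_names: list[str]
    scan: dict | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=0):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite connectivity values")
        self.values = v

    def index(self, name: str) -> int:
        return self.region_names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_names,
                            columns=self.region_names)


def fisher_z(r: np.ndarray, clamp: float = CLAMP) -> np.ndarray:
    """arctanh with |r| clamped to 1 - clamp (variance-stabilising transform)."""
    return np.arctanh(np.clip(r, -1.0 + clamp, 1.0 - clamp))


def connectivity_matrix(region_series: np.ndarray,
                        region_names: list[str] | None = None,
                        scan: dict | None = None) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of region series, Fisher z-transformed."""
    X = np.asarray(region_series, dtype=float)
    if X.ndim != 2:
        raise ValueError("region_series must be (n_regions, n_timepoints)")
    n_regions, n_time = X.shape
    if n_time < 3:
        raise ValueError("need >= 3 timepoints")
    names = region_names or [f"r{i}" for i in range(n_regions)]
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    r = np.corrcoef(X)
    z = fisher_z(r)
    z = (z + z.T) / 2.0  # exact symmetry against rounding
    return ConnectivityMatrix(values=z, region_names=list(names), scan=scan)


def _member_indices(matrix: ConnectivityMatrix, members) -> np.ndarray:
    return np.array([matrix.index(m) for m in members], dtype=int)


def network_interconnectivity(matrix: ConnectivityMatrix, members) -> float:
    """Mean Fisher z over all distinct pairs of ``members`` (diagonal excluded)."""
    idx = _member_indices(matrix, members)
    if idx.size < 2:
        raise ValueError("need >= 2 member regions")
    block = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(block[iu].mean())


def region_mean_connectivity(matrix: ConnectivityMatrix, region: str,
                             members) -> float:
    """Mean Fisher z between one region and the other network members."""
    if region not in members:
        raise ValueError(f"{region!r} not among members")
    idx = _member_indices(matrix, members)
    if idx.size < 2:
        raise ValueError("need >= 2 member regions")
    i = matrix.index(region)
    others = idx[idx != i]
    return float(matrix.values[i, others].mean())


def select_stimulation_target(value_map: np.ndarray, mask: np.ndarray,
                              anchor_mm, affine=None):
    """Pick the in-mask voxel with the maximal map value.

    Ties are broken by smaller Euclidean distance to ``anchor_mm``, then by
    lexicographic voxel index. Returns (voxel_index, peak_value, distance_mm).
    """
    value_map = np.asarray(value_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty candidate mask")
    if affine is None:
        affine = np.eye(4)
    vals = np.where(mask, value_map, -np.inf)
    peak = np.nanmax(vals[mask])
    cand = np.argwhere(vals == peak)
    centers = _voxel_centers_mm(value_map.shape, affine)
    anchor = np.asarray(anchor_mm, dtype=float).reshape(3)
    dists = np.linalg.norm(centers[tuple(cand.T)] - anchor, axis=1)
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], dists))
    best = cand[order[0]]
    return tuple(int(i) for i in best), float(peak), float(dists[order[0]])


def scan_connectivity_table(matrices, scans: pd.DataFrame,
                            atlas: ROIAtlas,
                            networks=("PMN", "ATN")) -> pd.DataFrame:
    """Long-format per-scan network interconnectivity table.

    One row per scan per network with columns (subject, group, condition,
    task, order, network, value, tsnr) — the contract consumed by the
    mixed-model stage.
    """
    if len(matrices) != len(scans):
        raise ValueError("one connectivity matrix per scan row required")
    rows = []
    for matrix, (_, scan) in zip(matrices, scans.iterrows()):
        for network in networks:
            members = atlas.members(network)
            rows.append({
                "subject": scan["subject"], "group": scan["group"],
                "condition": scan["condition"], "task": scan["task"],
                "order": scan.get("order", ""), "network": network,
                "value": network_interconnectivity(matrix, members),
                "tsnr": scan.get("tsnr", np.nan),
            })
    return pd.DataFrame(rows)
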