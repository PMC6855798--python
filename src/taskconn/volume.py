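"""4D volume container and NIfTI-1 / motion-table I/O.

Inputs are assumed to live in one common stereotactic space; the NIfTI affine
defines the voxel-to-mm mapping and voxel indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeSeries",
    "load_volume_series",
    "save_volume_series",
    "load_motion",
    "default_affine",
]

#: Number of initial frames discarded at load time (intensity stabilisation).
DROP_INITIAL_FRAMES = 5


def default_affine(voxel_size_mm) -> np.ndarray:
    """Axis-aligned affine with the given voxel size and origin at voxel 0."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = np.asarray(voxel_size_mm, dtype=float)
    return aff


@dataclass
class VolumeSeries:
    """A 4D functional time series stored time-first: ``data[t, x, y, z]``.

    Parameters
    ----------
    data
        Real array of shape ``(n_frames, nx, ny, nz)``; must be finite.
    voxel_size_mm
        Physical voxel size along x, y, z in millimetres.
    repetition_time_s
        Sampling interval (TR) in seconds.
    affine
        Optional 4x4 voxel-to-mm affine; defaults to a scaled identity.
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray
    repetition_time_s: float
    affine: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (t, x, y, z) data, got {self.data.ndim}D")
        if self.data.shape[0] < 2:
            raise ValueError("time dimension must be >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in volume data")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float).reshape(3)
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")
        if self.repetition_time_s <= 0:
            raise ValueError("repetition time must be positive")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        else:
            self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def copy_with(self, data: np.ndarray) -> "VolumeSeries":
        return VolumeSeries(
            data=data,
            voxel_size_mm=self.voxel_size_mm.copy(),
            repetition_time_s=self.repetition_time_s,
            affine=self.affine.copy(),
        )


def save_volume_series(series: VolumeSeries, path) -> None:
    """Write a :class:`VolumeSeries` as NIfTI-1 (spatial-first on disk)."""
    img = nib.Nifti1Image(np.moveaxis(series.data, 0, -1), series.affine)
    zooms = tuple(series.voxel_size_mm) + (series.repetition_time_s,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume_series(path, drop_initial: int = DROP_INITIAL_FRAMES) -> VolumeSeries:
    """Load a 4D NIfTI, dropping the first ``drop_initial`` frames."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    data = np.moveaxis(data, -1, 0)
    if drop_initial:
        if data.shape[0] <= drop_initial + 1:
            raise ValueError(f"{path}: too few frames to drop {drop_initial}")
        data = data[drop_initial:]
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VolumeSeries(
        data=data,
        voxel_size_mm=np.asarray(zooms[:3], dtype=float),
        repetition_time_s=tr,
        affine=np.asarray(img.affine, dtype=float),
    )


def load_motion(path, rotation_units: str = "rad") -> np.ndarray:
    """Read a 6-parameter motion table (3 translations mm, 3 rotations).

    The on-disk rotation unit is site-dependent; ``rotation_units`` selects
    between radians (default) and degrees, converted to radians on load.
    """
    motion = np.loadtxt(str(path), ndmin=2)
    if motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {motion.shape[1]}")
    if rotation_units == "deg":
        motion = motion.copy()
        motion[:, 3:] = np.deg2rad(motion[:, 3:])
    elif rotation_units != "rad":
        raise ValueError("rotation_units must be 'rad' or 'deg'")
    return motion
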