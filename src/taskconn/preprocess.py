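"""Per-scan preprocessing and quality control.

The simplified pipeline operates on functional series already resampled to a
common space: nuisance (motion) regression, temporal bandpass, spatial
smoothing, masking, plus framewise-displacement (FD) and tSNR quality metrics.
The fixed stage order is trim -> nuisance regression -> bandpass -> smooth ->
mask; despiking/slice-time steps are assumed to have happened upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VolumeSeries

__all__ = [
    "compute_fd",
    "qc_exclude",
    "QCDecision",
    "QCRecord",
    "regress_nuisance",
    "bandpass",
    "smooth_gaussian",
    "compute_tsnr",
    "group_mask",
]

#: Radius (mm) of the sphere used to convert head rotations to arc length.
ROTATION_RADIUS_MM = 50.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def compute_fd(motion: np.ndarray) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differences.

    ``motion`` is a (n_frames, 6) array of translations (mm) then rotations
    (rad). Rotations are converted to arc length on a 50 mm sphere. The first
    frame has FD 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (n_frames, 6): 3 translations mm, 3 rotations rad")
    if motion.shape[0] < 2:
        raise ValueError("need >= 2 frames to compute FD")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + ROTATION_RADIUS_MM * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


@dataclass(frozen=True)
class QCDecision:
    exclude: bool
    censored_fraction: float


@dataclass
class QCRecord:
    """Per-scan QC summary: FD trace, censoring level, and tSNR."""

    fd_series: np.ndarray
    censored_fraction: float
    tsnr: float
    exclude: bool


def qc_exclude(fd_series: np.ndarray, threshold_mm: float = 0.3,
               max_fraction: float = 0.05) -> QCDecision:
    """Exclude a scan iff the censored fraction strictly exceeds ``max_fraction``.

    A frame is censored when FD > ``threshold_mm``. Scans exactly at the
    boundary are kept (the inclusion rule is "< max_fraction censored" for
    excluded-vs-kept decisions made strictly above the bound).
    """
    fd = np.asarray(fd_series, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    frac = float(np.mean(fd > threshold_mm))
    return QCDecision(exclude=frac > max_fraction, censored_fraction=frac)


def _flat_time_by_voxel(series: VolumeSeries) -> np.ndarray:
    return series.data.reshape(series.n_frames, -1)


def regress_nuisance(series: VolumeSeries, regressors: np.ndarray) -> VolumeSeries:
    """Residualise every voxel against [intercept, regressors] by least squares.

    Rank-deficient regressor sets are handled by pseudoinverse projection and
    reported with a warning. The output is orthogonal to the regressors.
    """
    regs = np.asarray(regressors, dtype=float)
    if regs.ndim == 1:
        regs = regs[:, None]
    if regs.shape[0] != series.n_frames:
        raise ValueError(
            f"regressors have {regs.shape[0]} rows for {series.n_frames} frames")
    X = np.column_stack([np.ones(series.n_frames), regs])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance regressors; using pseudoinverse",
                      RuntimeWarning, stacklevel=2)
    Y = _flat_time_by_voxel(series)
    resid = Y - X @ (np.linalg.pinv(X) @ Y)
    return series.copy_with(resid.reshape(series.data.shape))


def bandpass(series: VolumeSeries, low_hz: float = 0.01,
             high_hz: float = 0.1) -> VolumeSeries:
    """Ideal (frequency-domain projection) bandpass filter.

    Discrete-Fourier bins with frequency in [low_hz, high_hz] are retained,
    all others (including DC) are zeroed, so the output is zero-mean and the
    operation is an idempotent projection.
    """
    nyquist = 1.0 / (2.0 * series.repetition_time_s)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:.4g} Hz)")
    Y = _flat_time_by_voxel(series)
    freqs = np.fft.rfftfreq(series.n_frames, d=series.repetition_time_s)
    spectrum = np.fft.rfft(Y, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum[~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=series.n_frames, axis=0)
    return series.copy_with(filtered.reshape(series.data.shape))


def smooth_gaussian(series: VolumeSeries, fwhm_mm: float = 4.0,
                    mask: np.ndarray | None = None) -> VolumeSeries:
    """Per-frame 3D Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)).

    Anisotropic voxel sizes are handled per-axis. If ``mask`` is given the
    smoothed data are zeroed outside it.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    if np.any(series.voxel_size_mm <= 0):
        raise ValueError("voxel sizes must be positive")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / series.voxel_size_mm
    out = np.empty_like(series.data)
    for t in range(series.n_frames):
        out[t] = ndimage.gaussian_filter(series.data[t], sigma=sigma_vox,
                                         mode="nearest")
    if mask is not None:
        out = out * np.asarray(mask, dtype=bool)
    return series.copy_with(out)


def compute_tsnr(series: VolumeSeries, mask: np.ndarray) -> float:
    """Mean in-mask temporal SNR: average over voxels of mean/SD.

    Voxels with zero temporal SD are excluded and counted in a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError("mask shape does not match volume grid")
    if not mask.any():
        raise ValueError("empty mask")
    vox = series.data.reshape(series.n_frames, -1)[:, mask.ravel()]
    mean = vox.mean(axis=0)
    sd = vox.std(axis=0, ddof=1)
    good = sd > 0
    n_bad = int((~good).sum())
    if n_bad:
        warnings.warn(f"{n_bad} in-mask voxels with zero temporal SD excluded "
                      "from tSNR", RuntimeWarning, stacklevel=2)
    if not good.any():
        raise ValueError("no in-mask voxel with positive temporal SD")
    return float(np.mean(mean[good] / sd[good]))


def group_mask(masks) -> np.ndarray:
    """Voxelwise intersection (logical AND) of per-subject binary masks."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    for i, m in enumerate(masks[1:], start=1):
        if m.shape != shape:
            raise ValueError(f"mask {i} shape {m.shape} != {shape}")
    return np.logical_and.reduce(masks)
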