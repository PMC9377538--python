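"""Functional preprocessing for white-matter connectivity analysis.

Implements the fixed pipeline order

    drop initial volumes -> motion summaries / spike detection
    -> nuisance regression (with spike regressors) -> band-pass filtering
    -> Gaussian smoothing restricted to a tissue mask

on volumes that are assumed to be already realigned and resampled to a
common grid.  Motion is summarised both as framewise displacement (FD,
Power convention: summed absolute translation changes plus rotation
changes projected on a head-radius sphere) and as frame-to-frame RMS
translation (Van Dijk convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "MotionSummary",
    "NuisanceDesign",
    "drop_initial_volumes",
    "compute_fd_power",
    "compute_rms_vandijk",
    "summarize_motion",
    "max_motion_exceeded",
    "build_nuisance_design",
    "nuisance_regress",
    "bandpass",
    "smooth_within_mask",
]


@dataclass
class MotionSummary:
    """Per-subject head-motion summary."""

    fd: np.ndarray
    mean_fd: float
    rel_rms: np.ndarray
    mean_rel_rms: float
    spike_frames: np.ndarray
    spike_threshold: float


@dataclass
class NuisanceDesign:
    """Named nuisance regressor matrix (t x q)."""

    matrix: np.ndarray
    names: list = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])


def _check_motion(motion: np.ndarray) -> np.ndarray:
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (t, 6)")
    if motion.shape[0] < 2:
        raise ValueError("motion trace needs at least 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")
    return motion


def drop_initial_volumes(bold: np.ndarray, n_drop: int) -> np.ndarray:
    """Discard the first ``n_drop`` frames (magnetisation-equilibration)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    t = bold.shape[-1]
    if t <= n_drop:
        raise ValueError(f"cannot drop {n_drop} of {t} volumes")
    return bold[..., n_drop:]


def compute_fd_power(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement: sum of |Δtranslation| plus head-radius-scaled
    |Δrotation| (arc length on a sphere of ``head_radius_mm``).  fd[0] = 0."""
    motion = _check_motion(motion)
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_rms_vandijk(motion: np.ndarray) -> np.ndarray:
    """Per-frame relative RMS motion over the three translation axes.

    Frame i carries sqrt(mean of squared frame-to-frame displacement over
    x, y, z); the first frame is 0 by convention.
    """
    motion = _check_motion(motion)
    d = np.diff(motion[:, :3], axis=0)
    rms = np.sqrt(np.mean(d**2, axis=1))
    return np.concatenate([[0.0], rms])


def summarize_motion(
    motion: np.ndarray,
    head_radius_mm: float = 50.0,
    spike_threshold: float = 1.0,
) -> MotionSummary:
    """FD, relative RMS and FD-spike frames for one motion trace."""
    fd = compute_fd_power(motion, head_radius_mm)
    rel_rms = compute_rms_vandijk(motion)
    spikes = np.nonzero(fd > spike_threshold)[0]
    return MotionSummary(
        fd=fd,
        mean_fd=float(fd.mean()),
        rel_rms=rel_rms,
        mean_rel_rms=float(rel_rms[1:].mean()),
        spike_frames=spikes,
        spike_threshold=spike_threshold,
    )


def max_motion_exceeded(
    motion: np.ndarray,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> bool:
    """Cohort QC rule: maximum head motion beyond 2 mm or 2 degrees."""
    motion = _check_motion(motion)
    max_trans = np.abs(motion[:, :3]).max()
    max_rot_deg = np.degrees(np.abs(motion[:, 3:]).max())
    return bool(max_trans > max_translation_mm or max_rot_deg > max_rotation_deg)


def build_nuisance_design(
    motion: np.ndarray,
    csf_signal: np.ndarray,
    fd: np.ndarray,
    spike_threshold: float = 1.0,
) -> NuisanceDesign:
    """Intercept, linear trend, 24 motion regressors, mean CSF signal and
    one one-hot column per FD spike frame.

    The 24 motion regressors are the 6 rigid parameters, their backward
    differences (first row zero-padded), and the squares of both sets.
    """
    motion = _check_motion(motion)
    t = motion.shape[0]
    csf_signal = np.asarray(csf_signal, dtype=np.float64).ravel()
    fd = np.asarray(fd, dtype=np.float64).ravel()
    if len(csf_signal) != t or len(fd) != t:
        raise ValueError("motion, csf_signal and fd lengths disagree")

    diffs = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols = [
        np.ones(t),
        np.linspace(-0.5, 0.5, t),
        *motion.T,
        *diffs.T,
        *(motion**2).T,
        *(diffs**2).T,
        csf_signal,
    ]
    names = (
        ["intercept", "trend"]
        + [f"mot{i}" for i in range(6)]
        + [f"dmot{i}" for i in range(6)]
        + [f"mot{i}_sq" for i in range(6)]
        + [f"dmot{i}_sq" for i in range(6)]
        + ["csf"]
    )
    for j in np.nonzero(fd > spike_threshold)[0]:
        spike = np.zeros(t)
        spike[j] = 1.0
        cols.append(spike)
        names.append(f"spike{j}")
    return NuisanceDesign(matrix=np.column_stack(cols), names=names)


def _prune_rank_deficient(x: np.ndarray, names) -> tuple[np.ndarray, list]:
    """Drop redundant columns (pivoted QR) so the design has full rank."""
    from scipy.linalg import qr

    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank == x.shape[1]:
        return x, list(names)
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in range(x.shape[1]) if j not in set(keep.tolist())]
    warnings.warn(
        f"rank-deficient nuisance design: dropped columns {dropped}", stacklevel=3
    )
    return x[:, keep], [names[j] for j in keep]


def nuisance_regress(
    bold: np.ndarray, design: NuisanceDesign, mask: np.ndarray
) -> np.ndarray:
    """Replace each in-mask voxel series by its least-squares residual
    against the nuisance design.  Out-of-mask voxels are untouched.
    WM-mean and global-mean signals are deliberately never regressors."""
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(design.matrix, dtype=np.float64)
    if x.shape[0] != bold.shape[-1]:
        raise ValueError("design rows do not match number of volumes")
    x, _ = _prune_rank_deficient(x, design.names)
    out = np.array(bold, dtype=np.float64, copy=True)
    y = out[mask].T  # (t, V)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    out[mask] = (y - x @ beta).T
    return out


def bandpass(
    data: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
) -> np.ndarray:
    """Zero-phase ideal (rectangular) band-pass along the last axis.

    The series is linearly detrended, transformed with a real FFT, and all
    frequency bins outside [low_hz, high_hz] are zeroed.  DC is removed
    whenever low_hz > 0.
    """
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz {high_hz} must be below Nyquist {nyquist}")
    data = np.asarray(data, dtype=np.float64)
    t = data.shape[-1]
    detrended = signal.detrend(data, axis=-1, type="linear")
    freqs = np.fft.rfftfreq(t, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(detrended, axis=-1)
    spec[..., ~keep] = 0
    return np.fft.irfft(spec, n=t, axis=-1)


def smooth_within_mask(
    bold: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float = 4.0,
    voxel_size_mm: float = 3.0,
) -> np.ndarray:
    """Gaussian smoothing restricted to a tissue compartment.

    Both the masked data and the mask itself are smoothed and divided
    (normalised convolution), so no signal leaks across the compartment
    boundary; out-of-mask voxels are set to 0.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    bold = np.asarray(bold, dtype=np.float64)
    out = np.zeros_like(bold)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    if sigma < 1e-8:
        out[mask] = bold[mask]
        return out
    maskf = mask.astype(np.float64)
    denom = ndimage.gaussian_filter(maskf, sigma=sigma)
    masked = bold * maskf[..., None]
    for ti in range(bold.shape[-1]):
        num = ndimage.gaussian_filter(masked[..., ti], sigma=sigma)
        vol = np.zeros(mask.shape)
        vol[mask] = num[mask] / denom[mask]
        out[..., ti] = vol
    return out
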