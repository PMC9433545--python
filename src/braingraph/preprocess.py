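"""ROI-level time-series cleaning.

Fixed stage order: discard initial volumes -> linear detrend -> band-pass
(0.01-0.1 Hz ideal frequency-domain filter) -> motion scrubbing with linear
interpolation -> nuisance regression.  Every stage is deterministic.

Frame-wise displacement follows the Power convention: the sum of absolute
backward differences of the three translations (mm) plus the head radius
(50 mm) times the sum of absolute rotation differences (rad).  The 24-motion
nuisance design is the Friston expansion: the six parameters, their one-lag
backward differences, and the squares of both.  Because only ROI averages
exist at this level, the optional "global-like" regressor is the grand mean
over all ROI series, standing in for the voxel-level global signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessConfig",
    "framewise_displacement",
    "exclude_by_mean_fd",
    "detrend_linear",
    "bandpass",
    "scrub_interpolate",
    "nuisance_regress",
    "preprocess_subject",
]


@dataclass
class PreprocessConfig:
    discard_initial_volumes: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    tr_seconds: float = 2.0
    fd_scrub_threshold_mm: float = 0.5
    fd_subject_exclusion_mm: float = 0.3
    head_radius_mm: float = 50.0
    nuisance_mode: str = "motion24"   # none | motion24 | motion24+global-like

    def validate(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not 0.0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ValueError(
                f"band [{self.band_low_hz}, {self.band_high_hz}] Hz invalid "
                f"for Nyquist {nyquist} Hz"
            )
        if self.fd_scrub_threshold_mm <= 0 or self.fd_subject_exclusion_mm <= 0:
            raise ValueError("FD thresholds must be positive")
        if self.nuisance_mode not in ("none", "motion24", "motion24+global-like"):
            raise ValueError(f"unknown nuisance_mode {self.nuisance_mode!r}")


def framewise_displacement(motion: np.ndarray,
                           head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD in mm; FD[0] = 0 by convention."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(
            f"motion trace must be T x 6 (3 translations mm, 3 rotations rad); "
            f"got shape {motion.shape}"
        )
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def exclude_by_mean_fd(fd: np.ndarray, threshold_mm: float = 0.3) -> bool:
    """True (drop subject) iff mean FD strictly exceeds the threshold."""
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    return bool(fd.mean() > threshold_mm)


def detrend_linear(timeseries: np.ndarray) -> np.ndarray:
    """Remove the per-column least-squares line (including the mean)."""
    x = np.asarray(timeseries, dtype=float)
    T = x.shape[0]
    if T < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(T, dtype=float)
    design = np.column_stack([np.ones(T), t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def bandpass(timeseries: np.ndarray, low_hz: float, high_hz: float,
             tr_seconds: float) -> np.ndarray:
    """Ideal (rectangular) frequency-domain band-pass filter.

    Fourier coefficients at frequencies outside ``[low_hz, high_hz]`` are
    zeroed (the 0 Hz mean is always removed); the result is real.
    """
    x = np.asarray(timeseries, dtype=float)
    T = x.shape[0]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0.0 < low_hz < high_hz <= nyquist:
        raise ValueError(f"invalid band [{low_hz}, {high_hz}] Hz at TR={tr_seconds}")
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise ValueError(
            f"pass band [{low_hz}, {high_hz}] Hz contains no frequency bin "
            f"at T={T}, TR={tr_seconds}"
        )
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=T, axis=0)


def scrub_mask(fd: np.ndarray, threshold_mm: float) -> np.ndarray:
    """Boolean censor mask: FD > threshold plus 1 before and 2 after."""
    fd = np.asarray(fd, dtype=float)
    bad = fd > threshold_mm
    mask = bad.copy()
    for t in np.flatnonzero(bad):
        mask[max(t - 1, 0):min(t + 3, fd.size)] = True
    return mask


def scrub_interpolate(timeseries: np.ndarray, fd: np.ndarray,
                      threshold_mm: float = 0.5
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Censor high-motion volumes and linearly interpolate over them.

    Volumes with FD above threshold, plus one before and two after, are
    replaced per column by linear interpolation between the nearest
    uncensored neighbours (nearest-value extension at the series ends).
    Returns ``(cleaned, mask)``.
    """
    x = np.asarray(timeseries, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if x.shape[0] != fd.size:
        raise ValueError("time series and FD lengths differ")
    mask = scrub_mask(fd, threshold_mm)
    if mask.all():
        raise ValueError("all volumes censored by scrubbing; subject unusable")
    if not mask.any():
        return x.copy(), mask
    t = np.arange(x.shape[0], dtype=float)
    good = ~mask
    out = x.copy()
    for j in range(x.shape[1]):
        out[mask, j] = np.interp(t[mask], t[good], x[good, j])
    return out, mask


def _friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter expansion: [m, back-diff m, m^2, (back-diff m)^2]."""
    m = np.asarray(motion, dtype=float)
    dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    return np.hstack([m, dm, m ** 2, dm ** 2])


def nuisance_regress(timeseries: np.ndarray, motion: np.ndarray | None,
                     mode: str = "motion24") -> np.ndarray:
    """Regress nuisance signals out of every ROI column.

    ``motion24`` uses the Friston-24 design; ``motion24+global-like`` adds the
    grand mean over all ROI columns as a global-signal proxy.  Residuals are
    orthogonal to the design by construction; collinear design columns are
    handled by least squares with a rank warning.
    """
    x = np.asarray(timeseries, dtype=float)
    if mode == "none":
        return x.copy()
    if motion is None:
        raise ValueError(f"nuisance mode {mode!r} requires a motion trace")
    if motion.shape[0] != x.shape[0]:
        raise ValueError("motion trace and time series lengths differ")
    design = [np.ones((x.shape[0], 1)), _friston24(motion)]
    if mode == "motion24+global-like":
        design.append(x.mean(axis=1, keepdims=True))
    elif mode != "motion24":
        raise ValueError(f"unknown nuisance_mode {mode!r}")
    d = np.hstack(design)
    rank = np.linalg.matrix_rank(d)
    if rank < d.shape[1]:
        warnings.warn(
            f"nuisance design rank deficient ({rank}/{d.shape[1]} columns); "
            "collinear regressors absorbed", RuntimeWarning)
    beta, *_ = np.linalg.lstsq(d, x, rcond=None)
    return x - d @ beta


def preprocess_subject(timeseries: np.ndarray, motion: np.ndarray | None,
                       config: PreprocessConfig | None = None) -> dict:
    """Run the fixed pipeline on one subject.

    Returns a dict with ``timeseries`` (cleaned, T minus discarded volumes),
    ``fd``, ``mean_fd``, ``censored`` (volume indices after discard),
    ``exclude`` (mean-FD decision) and the stage order applied.
    """
    config = config or PreprocessConfig()
    config.validate()
    x = np.asarray(timeseries, dtype=float)[config.discard_initial_volumes:]
    stages = ["discard"]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)[config.discard_initial_volumes:]
        fd = framewise_displacement(motion, config.head_radius_mm)
    else:
        fd = np.zeros(x.shape[0])
    exclude = exclude_by_mean_fd(fd, config.fd_subject_exclusion_mm)
    if exclude:
        # high-motion subject: report QC only, no cleaned series
        return {"timeseries": None, "fd": fd, "mean_fd": float(fd.mean()),
                "censored": [], "exclude": True, "stages": ["discard"]}

    x = detrend_linear(x)
    stages.append("detrend")
    x = bandpass(x, config.band_low_hz, config.band_high_hz, config.tr_seconds)
    stages.append("bandpass")
    x, mask = scrub_interpolate(x, fd, config.fd_scrub_threshold_mm)
    stages.append("scrub")
    mode = config.nuisance_mode if motion is not None else "none"
    x = nuisance_regress(x, motion, mode)
    stages.append("nuisance")
    return {
        "timeseries": x,
        "fd": fd,
        "mean_fd": float(fd.mean()),
        "censored": np.flatnonzero(mask).tolist(),
        "exclude": exclude,
        "stages": stages,
    }
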