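"""Minimal temporal preprocessing and motion summary metrics.

The temporal chain is deliberately small: discard the leading volumes
(magnetization equilibration), clip spikes against a running-median
baseline, and polynomial detrending.  Spatial stages (slice timing,
realignment, template normalisation, spatial smoothing) are out of
scope: synthetic cohorts are generated on a common grid with motion
represented only as a rigid-body parameter track.

Motion is summarised with the Euclidean-norm (enorm) convention: the
per-frame norm of the backward difference of the six rigid-body
parameters, rotations converted to millimetres of arc on a 50-mm-radius
sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .exceptions import ParameterError, ValidationError
from .simulate import CohortScan

__all__ = [
    "PreprocessConfig",
    "discard_and_detrend",
    "despike",
    "motion_enorm",
    "motion_exclude",
    "preprocess_scan",
]

ROTATION_RADIUS_MM = 50.0
MOTION_AXES = ("x", "y", "z", "roll", "pitch", "yaw")


@dataclass(frozen=True)
class PreprocessConfig:
    n_discard: int = 10
    despike_enabled: bool = True
    despike_mad_threshold: float = 5.0
    detrend_order: int = 1
    motion_exclude_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.despike_mad_threshold <= 0:
            raise ParameterError("despike_mad_threshold must be > 0")
        if self.detrend_order not in (0, 1):
            raise ParameterError("detrend_order must be 0 or 1")


def discard_and_detrend(scan: CohortScan, cfg: PreprocessConfig = PreprocessConfig()) -> CohortScan:
    """Drop the first ``n_discard`` volumes and detrend every voxel series.

    Order 0 removes the mean, order 1 the best-fit line; output series
    are zero mean either way.  The motion track is truncated in step.
    """
    if scan.n_volumes <= cfg.n_discard + 20:
        raise ValidationError(
            f"{scan.subject_id}: {scan.n_volumes} volumes too short for "
            f"n_discard={cfg.n_discard}"
        )
    data = scan.data[:, cfg.n_discard :].astype(float)
    t = np.arange(data.shape[1], dtype=float)
    if cfg.detrend_order == 1:
        # least-squares line per voxel, vectorised
        t0 = t - t.mean()
        slope = (data @ t0) / (t0 @ t0)
        data = data - data.mean(axis=1, keepdims=True) - slope[:, None] * t0[None, :]
    else:
        data = data - data.mean(axis=1, keepdims=True)
    motion = scan.motion[cfg.n_discard :] if scan.motion is not None else None
    return replace(scan, data=data, motion=motion)


def despike(series: np.ndarray, mad_threshold: float = 5.0, window: int = 7) -> np.ndarray:
    """Clip samples deviating from a running-median baseline.

    The baseline is a running median (window 7); the spread is the MAD
    of the residuals per series (scaled to sigma-equivalent).  Samples
    beyond ``mad_threshold`` MADs are shrunk onto the threshold
    envelope; everything else passes through unchanged.  Accepts a 1-D
    series or a (voxels, time) matrix despiked along the last axis.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 9:
        raise ValidationError("despike needs at least 9 samples")
    if mad_threshold <= 0:
        raise ParameterError("mad_threshold must be > 0")
    size = (1,) * (series.ndim - 1) + (window,)
    baseline = median_filter(series, size=size, mode="nearest")
    resid = series - baseline
    mad = 1.4826 * np.median(
        np.abs(resid - np.median(resid, axis=-1, keepdims=True)),
        axis=-1,
        keepdims=True,
    )
    limit = np.where(mad > 0, mad_threshold * mad, np.inf)
    return baseline + np.clip(resid, -limit, limit)


def _motion_in_mm(motion: np.ndarray) -> np.ndarray:
    """Rigid-body track with rotation columns (degrees) mapped to arc mm."""
    m = np.asarray(motion, dtype=float).copy()
    m[:, 3:] *= np.pi / 180.0 * ROTATION_RADIUS_MM
    return m


def motion_enorm(motion: np.ndarray) -> np.ndarray:
    """Per-frame Euclidean norm of backward-differenced motion parameters.

    Frame 0 is defined as 0.  Rotations (degrees) are converted to mm of
    displacement on a 50-mm radius before taking the norm.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 2:
        raise ValidationError("motion track must be (>=2 frames, 6 parameters)")
    if np.any(~np.isfinite(motion)):
        raise ValidationError("motion track contains NaN")
    diffs = np.diff(_motion_in_mm(motion), axis=0)
    enorm = np.sqrt((diffs**2).sum(axis=1))
    return np.concatenate([[0.0], enorm])


def motion_exclude(
    scan: CohortScan, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[bool, str]:
    """Keep/drop decision from peak-to-peak excursion per parameter.

    Drop iff any single parameter's range strictly exceeds the threshold
    (rotations on the mm-equivalent scale); the reason names the first
    offending axis.  Returns (keep, reason).
    """
    if scan.motion is None:
        raise ValidationError(f"{scan.subject_id}: no motion track")
    mm = _motion_in_mm(scan.motion)
    ranges = mm.max(axis=0) - mm.min(axis=0)
    for axis, r in zip(MOTION_AXES, ranges):
        if r > cfg.motion_exclude_mm:
            return False, axis
    return True, ""


def preprocess_scan(scan: CohortScan, cfg: PreprocessConfig = PreprocessConfig()) -> CohortScan:
    """Full temporal chain: discard + detrend, then optional despiking."""
    out = discard_and_detrend(scan, cfg)
    if cfg.despike_enabled:
        out = replace(out, data=despike(out.data, cfg.despike_mad_threshold))
    return out
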