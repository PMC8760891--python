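"""Frame-to-frame motion correction and surface-coil intensity correction.

Motion is modeled as a rigid in-plane translation per frame, estimated by
cross-correlation against an iteratively refined reference image (the
median of the mid-enhancement frames, re-averaged over registered frames
on subsequent passes).  Shifts are applied with linear, edge-clamped
interpolation.  The coil sensitivity (bias) field is estimated from the
proton-density frames as a heavily low-pass-filtered mean image
normalized to unit mean over a robust foreground mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation

from .core_model_io import (
    DegenerateInputError,
    DynamicSeries,
    GeometryError,
)

__all__ = [
    "BiasField",
    "DisplacementTrace",
    "estimate_bias_field",
    "apply_bias_correction",
    "motion_correct",
]


@dataclass
class BiasField:
    """Smooth multiplicative gain field, strictly positive with mean ~1."""

    field: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if np.any(self.field <= 0):
            raise DegenerateInputError("bias field must be strictly positive")


@dataclass
class DisplacementTrace:
    """Per-frame (dy, dx) translations applied to register each frame.

    ``reference_index`` names the frame carrying displacement (0, 0);
    ``flagged`` marks frames that fell back to a zero shift because the
    registration metric was non-finite.
    """

    shifts: np.ndarray
    reference_index: int
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.shifts.shape[0], dtype=bool)


def estimate_bias_field(pd_frames, smoothing_scale: float = 12.0) -> BiasField:
    """Estimate the coil gain field from proton-density frames.

    Parameters
    ----------
    pd_frames : DynamicSeries or ndarray
        The PD frames (stacked on axis 0) sharing geometry with the
        target series.
    smoothing_scale : float
        Gaussian sigma in pixels; in the limit of total smoothing the
        field tends to 1 everywhere.
    """
    frames = pd_frames.frames if isinstance(pd_frames, DynamicSeries) else np.asarray(pd_frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    mean_pd = frames.mean(axis=0)
    if not np.any(mean_pd > 0):
        raise DegenerateInputError("proton-density frames are all zero")
    smooth = ndi.gaussian_filter(mean_pd, smoothing_scale, mode="nearest")
    foreground = mean_pd > np.percentile(mean_pd, 5)
    if not foreground.any():  # perfectly uniform image
        foreground = np.ones_like(foreground)
    norm = smooth[foreground].mean()
    if norm <= 0:
        raise DegenerateInputError("degenerate proton-density frames (nonpositive foreground)")
    fld = smooth / norm
    return BiasField(np.clip(fld, 1e-3, None))


def apply_bias_correction(series: DynamicSeries, bias: BiasField) -> DynamicSeries:
    """Divide every frame pixel-wise by the gain field."""
    if bias.field.shape != series.shape:
        raise GeometryError(
            f"bias field shape {bias.field.shape} != series shape {series.shape}"
        )
    return series.with_frames(series.frames / bias.field[None])


def _reference_from_enhancement(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median image over the middle tertile of the series-mean enhancement."""
    means = frames.mean(axis=(1, 2))
    order = np.argsort(means, kind="stable")
    n = len(order)
    mid = order[n // 3 : max(2 * n // 3, n // 3 + 1)]
    return np.median(frames[mid], axis=0), mid


def _registration_image(frame: np.ndarray, highpass_sigma: float) -> np.ndarray:
    """High-passed, Hann-windowed image used for shift estimation.

    The high-pass removes the smooth first-pass enhancement (which
    changes frame to frame and otherwise dominates the correlation);
    the window suppresses the circular wrap-around the FFT correlator
    assumes.
    """
    hp = frame - ndi.gaussian_filter(frame, highpass_sigma)
    hp -= hp.mean()
    wy = np.hanning(frame.shape[0])[:, None]
    wx = np.hanning(frame.shape[1])[None, :]
    return hp * wy * wx


def _pairwise_shift(a: np.ndarray, b: np.ndarray, upsample_factor: int) -> np.ndarray:
    """Translation to apply to ``b`` to align it with ``a``."""
    sh, _, _ = phase_cross_correlation(
        a, b, upsample_factor=upsample_factor, normalization=None
    )
    return np.asarray(sh, dtype=float)


def motion_correct(
    series: DynamicSeries,
    max_shift_px: float = 6.0,
    n_reference_passes: int = 2,
    upsample_factor: int = 50,
    highpass_sigma: float = 3.0,
) -> tuple[DynamicSeries, DisplacementTrace]:
    """Estimate and undo per-frame in-plane translation.

    Inter-frame displacements are estimated between consecutive frames
    (whose enhancement states are nearly identical), cross-checked for
    outliers against lag-2 detours, and integrated into per-frame
    positions.  ``n_reference_passes`` small refinement passes against
    the mean of the registered frames then polish the solution; each
    refinement increment is limited to half a pixel so an unreliable
    composite reference cannot destabilize the chain solution.  The
    trace is anchored so the mid-enhancement frame closest to the median
    position carries displacement (0, 0).

    Frames whose registration metric is non-finite fall back to a zero
    inter-frame shift and are flagged in the trace.
    """
    frames = series.frames
    n = frames.shape[0]
    if n < 3:
        raise DegenerateInputError("motion correction needs at least 3 frames")

    reg_imgs = [_registration_image(f, highpass_sigma) for f in frames]
    flagged = np.zeros(n, dtype=bool)

    def link(i: int, j: int) -> np.ndarray | None:
        try:
            sh = _pairwise_shift(reg_imgs[i], reg_imgs[j], upsample_factor)
            if not np.all(np.isfinite(sh)):
                raise ValueError
            return sh
        except (ValueError, ZeroDivisionError):
            return None

    lag1 = np.zeros((n - 1, 2))
    for i in range(n - 1):
        d = link(i, i + 1)
        if d is None:
            flagged[i + 1] = True
            d = np.zeros(2)
        lag1[i] = d
    lag2 = {}
    for i in range(n - 2):
        d = link(i, i + 2)
        if d is not None:
            lag2[i] = d

    # outlier repair: each consecutive link gets a consensus of the direct
    # estimate and the two lag-2 detours around it
    links = lag1.copy()
    for i in range(n - 1):
        cands = [lag1[i]]
        if i - 1 in lag2:
            cands.append(lag2[i - 1] - lag1[i - 1])
        if i in lag2 and i + 1 <= n - 2:
            cands.append(lag2[i] - lag1[i + 1])
        links[i] = np.median(np.stack(cands), axis=0)

    shifts = np.vstack([np.zeros(2), np.cumsum(links, axis=0)])

    def apply_all(sh: np.ndarray) -> np.ndarray:
        out = np.empty_like(frames)
        for i in range(n):
            out[i] = ndi.shift(frames[i], sh[i], order=1, mode="nearest")
        return out

    for _ in range(max(n_reference_passes, 0)):
        registered = apply_all(shifts)
        ref = _registration_image(registered.mean(axis=0), highpass_sigma)
        for i in range(n):
            d = link_to = None
            try:
                link_to = _pairwise_shift(
                    ref, _registration_image(registered[i], highpass_sigma), upsample_factor
                )
            except (ValueError, ZeroDivisionError):
                pass
            if link_to is not None and np.all(np.isfinite(link_to)):
                shifts[i] += np.clip(link_to, -0.5, 0.5)

    # anchor: center the displacement trace (breathing motion has no
    # absolute reference), then pin it exactly to the frame closest to
    # the centered origin so one frame carries displacement (0, 0)
    shifts = shifts - shifts.mean(axis=0)
    ref_idx = int(np.argmin((shifts**2).sum(axis=1)))
    shifts = shifts - shifts[ref_idx]
    shifts = np.clip(shifts, -max_shift_px, max_shift_px)

    registered = np.clip(apply_all(shifts), 0.0, None)
    corrected = series.with_frames(registered)
    return corrected, DisplacementTrace(shifts=shifts, reference_index=ref_idx, flagged=flagged)
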