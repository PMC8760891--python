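"""Automatic ROI detection, first-pass timing detection, and sectorization.

Detection operates on motion/bias-corrected series and uses only
scale-relative intensity features (peak enhancement amplitude, upslope,
arrival time), so all decisions are invariant to a global intensity
scale factor.

Angular convention: sector 1 starts at the anterior reference angle
(default straight up, +90 degrees) and proceeds counterclockwise on the
image viewed in standard short-axis orientation (row axis pointing down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import measure, morphology

from .core_model_io import (
    DetectionFailureError,
    DynamicSeries,
    ParameterError,
    TimingFailureError,
)

__all__ = [
    "SignalCurve",
    "TimingPoints",
    "RoiSet",
    "detect_aif_roi",
    "detect_myocardium",
    "detect_timing",
    "sectorize",
]


@dataclass
class SignalCurve:
    """A time-signal intensity curve with its sampling times."""

    t: np.ndarray
    y: np.ndarray
    provenance: str = "pixel"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ParameterError("t and y must have equal length")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ParameterError("t must be strictly increasing")


@dataclass(frozen=True)
class TimingPoints:
    """Contrast-arrival foot, enhancement peak, and first-pass end indices."""

    foot_index: int
    peak_index: int
    end_index: int

    def __post_init__(self) -> None:
        if not (self.foot_index < self.peak_index <= self.end_index):
            raise ParameterError(
                f"require foot < peak <= end, got "
                f"({self.foot_index}, {self.peak_index}, {self.end_index})"
            )


@dataclass
class RoiSet:
    """Detected regions for one condition of a study."""

    lv_bloodpool_mask: np.ndarray  # on the AIF-series grid
    myocardium_masks: list[np.ndarray]  # per slice, on the MYO grid
    lv_centers: list[tuple[float, float]]  # per slice (row, col)
    reference_angle: float = np.pi / 2


# ---------------------------------------------------------------------------
# per-pixel enhancement features
# ---------------------------------------------------------------------------

def _enhancement_features(frames: np.ndarray, baseline_n: int):
    """Per-pixel (baseline, amplitude, mid-rise arrival index, noise proxy).

    The time axis is lightly smoothed before taking extrema so that
    single-frame noise does not dominate the max statistic.
    """
    smooth = ndi.uniform_filter1d(frames, size=3, axis=0, mode="nearest")
    baseline = smooth[:baseline_n].mean(axis=0)
    amp = smooth.max(axis=0) - baseline
    # first index exceeding half the pixel's own enhancement
    thresh = baseline + 0.5 * amp
    above = smooth >= thresh[None]
    arrival = np.where(above.any(axis=0), above.argmax(axis=0), frames.shape[0] - 1)
    noise = frames[:baseline_n].std(axis=0)
    return baseline, amp, arrival.astype(float), noise


# ---------------------------------------------------------------------------
# AIF blood-pool detection
# ---------------------------------------------------------------------------

def detect_aif_roi(
    aif_series: DynamicSeries,
    baseline_n: int = 4,
    amp_fraction: float = 0.4,
    min_area_px: int = 5,
) -> tuple[np.ndarray, SignalCurve]:
    """Locate the LV blood pool on the low-resolution AIF series.

    Bright, strongly enhancing connected components are ranked by area;
    among the two largest the one with the LATER median arrival is taken
    as the LV (the right ventricle enhances first).  The returned curve
    is the per-frame mean over a one-pixel-eroded mask.

    Raises
    ------
    DetectionFailureError
        When no enhancing region rises convincingly above the noise.
    """
    frames = aif_series.frames
    _, amp, arrival, noise = _enhancement_features(frames, baseline_n)
    noise_level = float(np.median(noise))
    amp_max = float(amp.max())
    if amp_max <= 0 or amp_max < 8.0 * max(noise_level, 1e-12 * max(amp_max, 1.0)):
        raise DetectionFailureError("no first-pass enhancement found in AIF series")

    cand = amp > amp_fraction * amp_max
    labels = measure.label(cand)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area_px]
    if not props:
        raise DetectionFailureError("no candidate blood-pool component of sufficient size")
    props.sort(key=lambda p: p.area, reverse=True)
    top = props[:2]
    if len(top) == 1:
        warnings.warn("only one enhancing chamber candidate found; using it as the LV")
        chosen = top[0]
    else:
        arrivals = [float(np.median(arrival[labels == p.label])) for p in top]
        chosen = top[int(np.argmax(arrivals))]

    mask = labels == chosen.label
    eroded = ndi.binary_erosion(mask)
    if not eroded.any():
        eroded = mask
    curve = frames[:, eroded].mean(axis=1)
    return mask, SignalCurve(t=aif_series.times, y=curve, provenance="AIF")


# ---------------------------------------------------------------------------
# myocardium detection
# ---------------------------------------------------------------------------

def detect_myocardium(
    myo_series: DynamicSeries,
    baseline_n: int = 4,
    lo_fraction: float = 0.05,
    hi_fraction: float = 0.55,
    min_area_px: int = 20,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Detect the myocardial annulus and LV center on one slice.

    The LV cavity is found as the largest compact, strongly enhancing
    component; the myocardium is the ring of moderate, delayed
    enhancement that encircles it after morphological closure.

    Returns ``(mask, lv_center)`` with the cavity projection excluded
    from the mask.
    """
    frames = myo_series.frames
    _, amp, arrival, noise = _enhancement_features(frames, baseline_n)
    amp = ndi.median_filter(amp, size=3)

    robust_max = float(np.percentile(amp, 99.5))
    if robust_max <= 0:
        raise DetectionFailureError("no enhancement on myocardial slice (cavity not found)")
    cav_cand = amp > 0.6 * robust_max
    cav_labels = measure.label(cav_cand)
    cav_props = measure.regionprops(cav_labels)
    if not cav_props:
        raise DetectionFailureError("no enhancement on myocardial slice (cavity not found)")
    cavity = cav_labels == max(cav_props, key=lambda p: p.area).label
    cavity = ndi.binary_fill_holes(cavity)
    cav_amp = float(np.median(amp[cavity]))
    cav_arrival = float(np.median(arrival[cavity]))
    center = ndi.center_of_mass(cavity)

    cavity_guard = ndi.binary_dilation(cavity, iterations=1)
    cand = (
        (amp > lo_fraction * cav_amp)
        & (amp < hi_fraction * cav_amp)
        & (arrival >= cav_arrival)
        & ~cavity_guard
    )
    cand = ndi.binary_closing(cand, structure=morphology.disk(2))
    cand &= ~cavity_guard
    labels = measure.label(cand)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area_px]

    annular = None
    for p in sorted(props, key=lambda q: q.area, reverse=True):
        comp = labels == p.label
        filled = ndi.binary_fill_holes(comp)
        if cavity.sum() and (filled & cavity).sum() / cavity.sum() > 0.9:
            annular = comp
            break
    if annular is None:
        raise DetectionFailureError(
            f"no annular myocardial component (candidates={len(props)}, cavity_found=True)"
        )
    mask = annular & ~cavity_guard
    return mask, (float(center[0]), float(center[1]))


# ---------------------------------------------------------------------------
# first-pass timing detection
# ---------------------------------------------------------------------------

def detect_timing(curve: SignalCurve, baseline_n: int = 4) -> TimingPoints:
    """Detect foot, peak, and end of the first pass on a signal curve.

    The foot is the last frame before the signal first exceeds
    baseline mean + 3 SD sustained for two consecutive frames; the peak
    is the post-foot maximum; the end is the first local minimum after
    the washout has begun, falling back to the half-enhancement crossing
    and finally the series end.
    """
    y = np.asarray(curve.y, dtype=float)
    n = y.size
    if baseline_n < 1 or baseline_n >= n:
        raise ParameterError(f"baseline_n must be in [1, {n - 1})")
    base_mean = float(y[:baseline_n].mean())
    base_sd = float(y[:baseline_n].std())
    scale = float(np.ptp(y)) or 1.0
    # the 3-SD criterion is floored at 2% of the curve range: a handful of
    # baseline frames underestimates the noise SD, which would otherwise
    # let single-sample wiggles fire the foot detector frames too early
    # (the floor preserves invariance to affine rescaling of y)
    thr = base_mean + max(3.0 * base_sd, 0.02 * scale, 1e-9 * scale)

    above = y > thr
    sustained = above[:-1] & above[1:]
    idx = np.nonzero(sustained)[0]
    if idx.size == 0:
        raise TimingFailureError("no sustained suprathreshold rise found")
    rise = int(idx[0])
    foot = max(rise - 1, 0)

    peak = foot + 1 + int(np.argmax(y[foot + 1 :]))
    peak_val = float(y[peak])

    end = n - 1
    washout_level = base_mean + 0.8 * (peak_val - base_mean)
    found = False
    for j in range(peak + 1, n - 1):
        if y[j] <= y[j - 1] and y[j] <= y[j + 1] and y[j] < washout_level:
            end = j
            found = True
            break
    if not found:
        half = base_mean + 0.5 * (peak_val - base_mean)
        below = np.nonzero(y[peak + 1 :] < half)[0]
        if below.size:
            end = peak + 1 + int(below[0])
    if end <= foot:
        end = n - 1
    peak = min(peak, end)
    return TimingPoints(foot_index=foot, peak_index=peak, end_index=end)


# ---------------------------------------------------------------------------
# sectorization
# ---------------------------------------------------------------------------

def sectorize(
    mask: np.ndarray,
    lv_center: tuple[float, float],
    reference_angle: float = np.pi / 2,
    n_sectors: int = 6,
) -> np.ndarray:
    """Label each masked pixel 1..n_sectors by angle about the LV center.

    Angles are measured counterclockwise from ``reference_angle`` with
    the image viewed in standard orientation (row axis pointing down),
    in equal bins of 2*pi/n_sectors.  Unmasked pixels get label 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_sectors < 1:
        raise ParameterError("n_sectors must be >= 1")
    cy, cx = lv_center
    if not (0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1]):
        raise ParameterError(f"lv_center {lv_center} outside image {mask.shape}")
    rr, cc = np.indices(mask.shape)
    angle = np.arctan2(-(rr - cy), cc - cx)  # +y up
    rel = np.mod(angle - reference_angle, 2 * np.pi)
    width = 2 * np.pi / n_sectors
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = np.minimum((rel[mask] / width).astype(np.int64), n_sectors - 1) + 1
    return labels
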