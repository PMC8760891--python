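"""Synthetic dual-sequence perfusion studies with known ground truth.

The phantom emulates the acquisition the pipeline expects: a
low-resolution blood-pool (AIF) series plus 3 myocardial slices per
heartbeat, with 2 proton-density frames per slice.  Myocardial pixels
carry tissue curves obtained by convolving a gamma-variate bolus with a
delayed-Fermi impulse response at sector-specific flow, the LV cavity
carries the bolus itself, and corruption stages (multiplicative coil
shading, per-frame in-plane translation, additive Gaussian noise) are
applied on top.  All randomness flows through a single seed.

Unit convention
---------------
Flow amplitudes ``F`` are stated in ml/g/min while the time axis runs in
seconds.  :func:`fermi_irf` returns the amplitude-``F`` response used in
closed-form identities; :func:`tissue_impulse_response` divides it by
60 s/min, which is the physically scaled kernel used to paint tissue
curves (and the convention expected by the deconvolution stage, which
reapplies the factor when reporting flow).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from .autoseg import sectorize
from .core_model_io import (
    AIF_SLICE,
    CONDITIONS,
    ConditionData,
    DynamicSeries,
    FrameMeta,
    GeometryError,
    ParameterError,
    PerfusionStudy,
    ROLE_AIF,
    ROLE_MYO,
    ROLE_PD,
)

__all__ = [
    "SECONDS_PER_MINUTE",
    "GammaVariateParams",
    "FermiIRFParams",
    "PhantomSpec",
    "GroundTruth",
    "gamma_variate",
    "fermi_irf",
    "tissue_impulse_response",
    "flow_to_amplitude",
    "synthesize_tissue_curve",
    "sample_tissue_curve",
    "polynomial_field",
    "ischemic_spec",
    "build_phantom",
]

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class GammaVariateParams:
    """First-pass bolus surrogate, normalized so the primary peak equals A.

    The primary-bolus peak occurs at ``t0 + alpha * beta``.
    """

    amplitude: float = 100.0
    t0: float = 8.0
    alpha: float = 2.5
    beta: float = 1.5
    recirculation_fraction: float = 0.0
    recirculation_delay: float = 20.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("gamma-variate requires alpha > 0 and beta > 0")
        if not (0 <= self.recirculation_fraction < 1):
            raise ParameterError("recirculation_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class FermiIRFParams:
    """Delayed logistic-decay impulse response parameters.

    ``F`` is the flow amplitude (ml/g/min), ``k`` the decay rate (1/s),
    ``w`` the plateau width (s) and ``tau_d`` the delay (s).  The
    response at ``t = tau_d`` equals ``F / (1 + exp(-k*w))``.
    """

    F: float
    k: float
    w: float
    tau_d: float = 0.0

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ParameterError("F must be >= 0")
        if self.k <= 0:
            raise ParameterError("k must be > 0")
        if self.w < 0 or self.tau_d < 0:
            raise ParameterError("w and tau_d must be >= 0")

    @property
    def flow(self) -> float:
        """Impulse-response value at t = tau_d, i.e. the flow estimate."""
        return self.F / (1.0 + np.exp(-self.k * self.w))


def gamma_variate(params: GammaVariateParams, tgrid: np.ndarray) -> np.ndarray:
    """Evaluate the (peak-normalized) gamma-variate bolus on ``tgrid``."""
    t = np.asarray(tgrid, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ParameterError("tgrid must be nondecreasing")

    def primary(t0: float) -> np.ndarray:
        dt = t - t0
        out = np.zeros_like(t)
        pos = dt > 0
        u = dt[pos] / (params.alpha * params.beta)
        out[pos] = params.amplitude * u**params.alpha * np.exp(
            params.alpha - dt[pos] / params.beta
        )
        return out

    curve = primary(params.t0)
    if params.recirculation_fraction > 0:
        curve = curve + params.recirculation_fraction * primary(
            params.t0 + params.recirculation_delay
        )
    return curve


def fermi_irf(params: FermiIRFParams, tgrid: np.ndarray) -> np.ndarray:
    """Delayed-Fermi impulse response with amplitude-``F`` convention.

    ``h(t) = 0`` for ``t < tau_d`` and
    ``h(t) = F / (1 + exp(k * (t - tau_d - w)))`` afterwards; the result
    is monotonically nonincreasing beyond the delay.
    """
    t = np.asarray(tgrid, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ParameterError("tgrid must be nondecreasing")
    h = np.zeros_like(t)
    after = t >= params.tau_d
    h[after] = params.F / (1.0 + np.exp(params.k * (t[after] - params.tau_d - params.w)))
    return h


def tissue_impulse_response(params: FermiIRFParams, tgrid: np.ndarray) -> np.ndarray:
    """Physically scaled residue kernel (per-second) for a seconds grid."""
    return fermi_irf(params, tgrid) / SECONDS_PER_MINUTE


def flow_to_amplitude(mbf: float, k: float, w: float) -> float:
    """Amplitude ``F`` whose Fermi response carries flow ``mbf`` at the delay."""
    return float(mbf) * (1.0 + np.exp(-k * w))


def synthesize_tissue_curve(aif: np.ndarray, irf: np.ndarray, dt: float) -> np.ndarray:
    """Discrete causal convolution ``c[n] = dt * sum_{m<=n} aif[m] irf[n-m]``."""
    aif = np.asarray(aif, dtype=float)
    irf = np.asarray(irf, dtype=float)
    if aif.shape != irf.shape:
        raise ParameterError("aif and irf must share one uniform grid")
    return dt * np.convolve(aif, irf)[: aif.size]


def sample_tissue_curve(
    aif_params: GammaVariateParams,
    irf_params: FermiIRFParams,
    tgrid: np.ndarray,
    oversample: int = 8,
) -> np.ndarray:
    """Continuous-model tissue curve sampled at ``tgrid``.

    The convolution of the analytic bolus with the per-second residue
    kernel is evaluated on an ``oversample``-times finer grid and then
    read out at the acquisition times, so the painted curves approximate
    the continuous indicator-dilution model rather than the coarse
    rectangle-rule quadrature of :func:`synthesize_tissue_curve`.
    """
    t = np.asarray(tgrid, dtype=float)
    if t.size < 2:
        raise ParameterError("tgrid must contain at least 2 samples")
    dt = float(t[1] - t[0])
    if not np.allclose(np.diff(t), dt):
        raise ParameterError("tgrid must be uniform")
    dtf = dt / max(1, int(oversample))
    n_fine = (t.size - 1) * int(oversample) + 1
    tf = t[0] + np.arange(n_fine) * dtf
    aif_f = gamma_variate(aif_params, tf)
    irf_f = tissue_impulse_response(irf_params, tf - tf[0])
    conv = dtf * np.convolve(aif_f, irf_f)[:n_fine]
    idx = np.round((t - t[0]) / dtf).astype(int)
    return conv[idx]


def polynomial_field(coeffs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate sum_ij c[i,j] * X^i * Y^j on coordinates normalized to [-1, 1].

    X runs along columns, Y along rows.  The result is normalized to
    mean 1 so it can act as a multiplicative gain field.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    ny, nx = shape
    Y = np.linspace(-1, 1, ny)[:, None]
    X = np.linspace(-1, 1, nx)[None, :]
    out = np.zeros(shape)
    for i in range(coeffs.shape[0]):
        for j in range(coeffs.shape[1]):
            if coeffs[i, j]:
                out += coeffs[i, j] * X**i * Y**j
    if np.any(out <= 0):
        raise ParameterError("shading field must be strictly positive")
    return out / out.mean()


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

def _default_mbf() -> dict[str, np.ndarray]:
    return {
        "stress": np.full((3, 6), 3.0),
        "rest": np.full((3, 6), 1.0),
    }


def _default_aif_params() -> dict[str, GammaVariateParams]:
    return {
        "stress": GammaVariateParams(),
        "rest": GammaVariateParams(),
    }


@dataclass
class PhantomSpec:
    """Full description of a synthetic study.

    ``mbf`` maps condition -> (n_slices, 6) sector ground-truth flows in
    ml/g/min.  ``motion_amplitude_px`` generates a smooth random
    per-frame translation schedule bounded by that amplitude (one
    schedule per condition, shared across that condition's myocardial
    slices); an explicit (n_frames, 2) array can be supplied instead.
    """

    image_size: tuple[int, int] = (64, 64)
    aif_size: tuple[int, int] = (24, 32)
    center: tuple[float, float] | None = None
    radii: tuple[tuple[float, float], ...] = ((11.0, 17.0), (10.0, 16.0), (8.0, 13.0))
    mbf: dict[str, np.ndarray] = field(default_factory=_default_mbf)
    aif_params: dict[str, GammaVariateParams] = field(default_factory=_default_aif_params)
    tissue_k: float = 0.5
    tissue_w: float = 8.0
    tissue_delay: float = 1.2
    shading_coeffs: np.ndarray | None = None
    motion_amplitude_px: float = 0.0
    motion_schedule: np.ndarray | None = None
    # scalar, or a {condition: sd} map so each condition's tissue curves
    # can be given the same signal-to-noise ratio
    noise_sd: float | dict = 0.0
    pd_noise_sd: float = 0.0
    baseline_body: float = 50.0
    # flat mean baseline anatomy by default: ROI detection keys on
    # enhancement amplitude, and a flat proton-density background lets the
    # coil-gain estimator be exercised without anatomy structure leaking
    # into the recovered field
    baseline_background: float = 50.0
    # static fine-grained anatomy texture (fractional sd, correlation
    # length ~2 px): gives every frame registration structure while
    # averaging out of the heavily smoothed bias field
    texture_amplitude: float = 0.10
    texture_scale_px: float = 1.5
    n_frames: int = 60
    rr_interval_s: float = 1.0
    include_rv: bool = True
    rv_advance_s: float = 4.0
    myo_pixel_spacing: tuple[float, float] = (2.8, 2.8)
    aif_pixel_spacing: tuple[float, float] = (5.6, 5.6)
    subject_id: str = "phantom"

    def validate(self) -> None:
        for cond, arr in self.mbf.items():
            arr = np.asarray(arr)
            if arr.shape != (len(self.radii), 6):
                raise ParameterError(
                    f"mbf[{cond!r}] must have shape ({len(self.radii)}, 6), got {arr.shape}"
                )
            if np.any(arr < 0) or np.any(arr > 10):
                raise ParameterError("ground-truth MBF must lie in [0, 10] ml/g/min")
        for endo, epi in self.radii:
            if not endo < epi:
                raise ParameterError("endocardial radius must be smaller than epicardial")
        cy, cx = self._center()
        margin = 2.0 + self.motion_amplitude_px
        for _, epi in self.radii:
            if (
                cy - epi < margin
                or cx - epi < margin
                or cy + epi > self.image_size[0] - margin
                or cx + epi > self.image_size[1] - margin
            ):
                raise GeometryError("myocardial annulus does not fit inside the image")

    def _center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (self.image_size[0] / 2.0, self.image_size[1] / 2.0)


def ischemic_spec(
    stress_normal: float = 3.0,
    stress_ischemic: float = 0.8,
    rest: float = 1.0,
    ischemic_slice: int = 1,
    ischemic_sectors: tuple[int, ...] = (3, 4),
    **kwargs,
) -> PhantomSpec:
    """A study with one hypoperfused territory (two adjacent sectors).

    Sector numbers are 1-based; the default pair (3, 4) forms one
    complete coronary territory on the mid slice.
    """
    mbf = {
        "stress": np.full((3, 6), stress_normal),
        "rest": np.full((3, 6), rest),
    }
    for s in ischemic_sectors:
        mbf["stress"][ischemic_slice, s - 1] = stress_ischemic
    return PhantomSpec(mbf=mbf, **kwargs)


@dataclass
class GroundTruth:
    """Noise-free quantities associated with a generated study."""

    mbf_maps: dict[str, np.ndarray]  # cond -> (n_slices, R, C), NaN outside mask
    sector_labels: np.ndarray  # (n_slices, R, C), 0 outside
    myocardium_masks: np.ndarray  # (n_slices, R, C) bool
    cavity_masks: np.ndarray  # (n_slices, R, C) bool
    shading: np.ndarray  # (R, C)
    motion: dict[str, np.ndarray]  # cond -> (n_frames, 2) (dy, dx)
    aif_curves: dict[str, np.ndarray]  # cond -> noise-free concentration curve
    aif_lv_mask: np.ndarray  # LV blood-pool blob on the AIF grid
    aif_rv_mask: np.ndarray  # RV blob (empty if include_rv is False)
    tgrid: np.ndarray
    baseline_body: float


# ---------------------------------------------------------------------------
# study synthesis
# ---------------------------------------------------------------------------

def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _motion_schedule(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.motion_schedule is not None:
        sched = np.asarray(spec.motion_schedule, dtype=float)
        if sched.shape != (spec.n_frames, 2):
            raise ParameterError("motion_schedule must have shape (n_frames, 2)")
        return sched
    if spec.motion_amplitude_px <= 0:
        return np.zeros((spec.n_frames, 2))
    raw = rng.standard_normal((spec.n_frames, 2))
    sched = ndi.gaussian_filter1d(raw, sigma=2.0, axis=0, mode="nearest")
    sched -= sched.mean(axis=0)
    peak = np.abs(sched).max()
    if peak > 0:
        sched *= spec.motion_amplitude_px / peak
    return sched


def _frame_meta(n: int, rr: float, slice_index: int, spacing, offset: float = 0.0):
    return [
        FrameMeta(
            acquisition_time=i * rr + offset,
            trigger_index=i,
            slice_index=slice_index,
            pixel_spacing=spacing,
        )
        for i in range(n)
    ]


def build_phantom(spec: PhantomSpec, seed: int) -> tuple[PerfusionStudy, GroundTruth]:
    """Generate a deterministic synthetic study and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n_slices = len(spec.radii)
    R, C = spec.image_size
    n = spec.n_frames
    dt = spec.rr_interval_s
    tgrid = np.arange(n) * dt
    center = spec._center()

    shading = (
        polynomial_field(spec.shading_coeffs, (R, C))
        if spec.shading_coeffs is not None
        else np.ones((R, C))
    )

    # geometry and sector labels (shared across conditions)
    cavity_masks = np.zeros((n_slices, R, C), dtype=bool)
    myo_masks = np.zeros((n_slices, R, C), dtype=bool)
    labels = np.zeros((n_slices, R, C), dtype=np.int32)
    for s, (endo, epi) in enumerate(spec.radii):
        cavity_masks[s] = _disk((R, C), center, endo)
        annulus = _disk((R, C), center, epi) & ~_disk((R, C), center, endo)
        myo_masks[s] = annulus
        labels[s] = sectorize(annulus, center, np.pi / 2, 6)

    body = _disk((R, C), center, max(epi for _, epi in spec.radii) + 6.0)
    baseline_img = np.where(body, spec.baseline_body, spec.baseline_background)
    if spec.texture_amplitude > 0:
        raw = ndi.gaussian_filter(rng.standard_normal((R, C)), spec.texture_scale_px)
        raw /= raw.std()
        texture = np.clip(1.0 + spec.texture_amplitude * raw, 0.1, None)
        baseline_img = baseline_img * texture

    mbf_maps: dict[str, np.ndarray] = {}
    aif_curves: dict[str, np.ndarray] = {}
    motion: dict[str, np.ndarray] = {}
    conditions: dict[str, ConditionData] = {}

    def noise_for(cond: str) -> float:
        if isinstance(spec.noise_sd, dict):
            return float(spec.noise_sd.get(cond, 0.0))
        return float(spec.noise_sd)

    for cond in CONDITIONS:
        if cond not in spec.mbf:
            continue
        noise_sd = noise_for(cond)
        aif_c = gamma_variate(spec.aif_params[cond], tgrid)
        aif_curves[cond] = aif_c
        sched = _motion_schedule(spec, rng)
        motion[cond] = sched

        # tissue curves per unique flow value
        flows = np.asarray(spec.mbf[cond], dtype=float)
        curve_cache: dict[float, np.ndarray] = {}
        for v in np.unique(flows):
            irf_params = FermiIRFParams(
                F=flow_to_amplitude(v, spec.tissue_k, spec.tissue_w),
                k=spec.tissue_k,
                w=spec.tissue_w,
                tau_d=spec.tissue_delay,
            )
            curve_cache[float(v)] = sample_tissue_curve(
                spec.aif_params[cond], irf_params, tgrid
            )

        truth = np.full((n_slices, R, C), np.nan)
        myo_series = []
        pd_series = []
        for s in range(n_slices):
            conc = np.zeros((n, R, C))
            conc[:, cavity_masks[s]] = aif_c[:, None]
            for sec in range(1, 7):
                sel = labels[s] == sec
                v = float(flows[s, sec - 1])
                conc[:, sel] = curve_cache[v][:, None]
                truth[s][sel] = v

            frames = (baseline_img[None] + conc) * shading[None]
            if np.any(sched != 0):
                shifted = np.empty_like(frames)
                for i in range(n):
                    shifted[i] = ndi.shift(frames[i], sched[i], order=1, mode="nearest")
                frames = shifted
            if noise_sd > 0:
                frames = frames + rng.normal(0.0, noise_sd, frames.shape)
            frames = np.clip(frames, 0.0, None)
            myo_series.append(
                DynamicSeries(
                    frames,
                    _frame_meta(n, dt, s, spec.myo_pixel_spacing, offset=0.02 * (s + 1)),
                    ROLE_MYO,
                )
            )

            pd_frames = np.repeat((baseline_img * shading)[None], 2, axis=0)
            if spec.pd_noise_sd > 0:
                pd_frames = np.clip(
                    pd_frames + rng.normal(0.0, spec.pd_noise_sd, pd_frames.shape), 0.0, None
                )
            pd_series.append(
                DynamicSeries(
                    pd_frames, _frame_meta(2, dt, s, spec.myo_pixel_spacing), ROLE_PD
                )
            )

        # low-resolution AIF series: LV blob (later arrival) + optional RV blob
        aR, aC = spec.aif_size
        lv_center = (aR / 2.0, aC * 0.68)
        rv_center = (aR / 2.0, aC * 0.28)
        lv_mask = _disk((aR, aC), lv_center, min(aR, aC) * 0.18)
        aif_frames = np.full((n, aR, aC), spec.baseline_background)
        aif_body = _disk((aR, aC), (aR / 2.0, aC / 2.0), min(aR, aC) * 0.48)
        aif_frames[:, aif_body] = spec.baseline_body
        aif_frames[:, lv_mask] = spec.baseline_body + aif_c[:, None]
        if spec.include_rv:
            rv_params = replace(spec.aif_params[cond], t0=max(spec.aif_params[cond].t0 - spec.rv_advance_s, 0.5))
            rv_c = gamma_variate(rv_params, tgrid)
            rv_mask = _disk((aR, aC), rv_center, min(aR, aC) * 0.18)
            aif_frames[:, rv_mask] = spec.baseline_body + 0.9 * rv_c[:, None]
        if noise_sd > 0:
            aif_frames = aif_frames + rng.normal(0.0, noise_sd, aif_frames.shape)
        aif_frames = np.clip(aif_frames, 0.0, None)
        aif = DynamicSeries(
            aif_frames, _frame_meta(n, dt, AIF_SLICE, spec.aif_pixel_spacing), ROLE_AIF
        )

        conditions[cond] = ConditionData(aif=aif, myo=tuple(myo_series), pd=tuple(pd_series))
        mbf_maps[cond] = truth
        last_lv_mask = lv_mask
        last_rv_mask = rv_mask if spec.include_rv else np.zeros_like(lv_mask)

    study = PerfusionStudy(
        condition_series=conditions,
        subject_id=spec.subject_id,
        rr_interval_s=spec.rr_interval_s,
    )
    study.validate()
    truth_obj = GroundTruth(
        mbf_maps=mbf_maps,
        sector_labels=labels,
        myocardium_masks=myo_masks,
        cavity_masks=cavity_masks,
        shading=shading,
        motion=motion,
        aif_curves=aif_curves,
        tgrid=tgrid,
        baseline_body=spec.baseline_body,
        aif_lv_mask=last_lv_mask,
        aif_rv_mask=last_rv_mask,
    )
    return study, truth_obj
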