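"""Shared fixtures: small deterministic phantoms reused across modules."""

import numpy as np
import pytest

from perfquant import phantom as ph


@pytest.fixture(scope="session")
def tgrid():
    return np.arange(60) * 1.0


@pytest.fixture(scope="session")
def aif_params():
    return ph.GammaVariateParams()


@pytest.fixture(scope="session")
def aif_curve(aif_params, tgrid):
    return ph.gamma_variate(aif_params, tgrid)


def stress_tissue_peak(mbf: float = 3.0) -> float:
    """Peak tissue enhancement for the default phantom at a given flow."""
    t = np.arange(60) * 1.0
    p = ph.FermiIRFParams(F=ph.flow_to_amplitude(mbf, 0.5, 8.0), k=0.5, w=8.0, tau_d=1.2)
    return float(ph.sample_tissue_curve(ph.GammaVariateParams(), p, t).max())


def snr20_noise() -> dict:
    """Per-condition noise SD giving tissue-curve SNR ~ 20."""
    return {"stress": stress_tissue_peak(3.0) / 20.0, "rest": stress_tissue_peak(1.0) / 20.0}


@pytest.fixture(scope="session")
def clean_phantom():
    """Uncorrupted ischemic study: no shading, motion, or noise."""
    spec = ph.ischemic_spec()
    study, truth = ph.build_phantom(spec, seed=11)
    return spec, study, truth


@pytest.fixture(scope="session")
def shaded_phantom():
    """Polynomial coil shading only (no motion, no noise)."""
    spec = ph.ischemic_spec(shading_coeffs=np.array([[1.0, -0.15], [0.25, 0.08]]))
    study, truth = ph.build_phantom(spec, seed=11)
    return spec, study, truth


@pytest.fixture(scope="session")
def corrupted_phantom():
    """Shading + up-to-3-pixel motion + curve SNR ~ 20, both conditions."""
    spec = ph.ischemic_spec(
        shading_coeffs=np.array([[1.0, -0.15], [0.25, 0.08]]),
        motion_amplitude_px=3.0,
        noise_sd=snr20_noise(),
    )
    study, truth = ph.build_phantom(spec, seed=7)
    return spec, study, truth
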