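import warnings

import pytest
from hypothesis import HealthCheck, settings

import amynet as an

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_clip_warnings():
    # tiny negative-concentration clips are expected near depleted states
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="clipped negative", category=RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def params_molar() -> an.KineticParameters:
    """Reference Abeta42 kinetics in molar-hour units."""
    return an.ab42_hepes_parameters(scaled=False)


@pytest.fixture(scope="session")
def params_scaled() -> an.KineticParameters:
    """Reference kinetics in micromolar-hour units (scale 1e6)."""
    return an.ab42_hepes_parameters(scaled=True)


@pytest.fixture(scope="session")
def params_homog_scaled() -> an.KineticParameters:
    """Scaled kinetics with homogeneous (k_n m^2) primary nucleation."""
    return an.rescale_parameters(
        an.ab42_hepes_parameters(scaled=False).with_convention("homogeneous"), 1e6
    )


@pytest.fixture(scope="session")
def params_slow_elongation(params_molar) -> an.KineticParameters:
    """Reference kinetics with elongation slowed 1000x.

    The full-rate reference produces fibrils of ~1e4 monomers, far past any
    affordable truncation; slowing elongation keeps the whole distribution
    inside a few hundred size classes so size-resolved runs can be checked
    against the exact moment system.
    """
    return params_molar.replace(k_plus=params_molar.k_plus * 1e-3)
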