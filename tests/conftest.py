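import numpy as np
import pytest

from chromohop import AcquisitionSettings, KineticModel, NucleusGeometry


@pytest.fixture(scope="session")
def fast_settings():
    """Fast acquisition regime (15 ms exposure, 64.5 frames/s)."""
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def instant_settings():
    """Fast frame rate with effectively instantaneous exposure and no
    localization noise — isolates pure Brownian statistics."""
    return AcquisitionSettings(sigma_loc=0.0, exposure=1e-4)


@pytest.fixture(scope="session")
def big_geometry():
    """A nucleus so large that boundary reflections are negligible."""
    return NucleusGeometry(semi_axes=(60.0, 60.0))


@pytest.fixture(scope="session")
def nucleus():
    return NucleusGeometry(semi_axes=(8.0, 8.0))


@pytest.fixture(scope="session")
def two_state_model():
    return KineticModel.two_state(D_free=0.6, k_on=2.0, k_off=3.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
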