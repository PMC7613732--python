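import numpy as np
import pytest

from memfluct import CalibrationCurve, MechanicalParams


@pytest.fixture()
def curve() -> CalibrationCurve:
    """Reference calibration: lambda=546 nm, n=1.337, mid-range gain."""
    return CalibrationCurve(i_min=100.0, i_max=200.0)


@pytest.fixture()
def default_params() -> MechanicalParams:
    """Generator-default mechanical parameters (tensed adherent membrane)."""
    return MechanicalParams(sigma=1.2e-5, gamma=1e5, eta_eff=4.0, a_active=1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
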