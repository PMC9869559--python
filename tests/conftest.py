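import pytest

import xyloflux as xf


@pytest.fixture()
def core_model():
    """Fresh copy of the shipped core model (safe to mutate)."""
    return xf.load_core_model()


@pytest.fixture(scope="session")
def calibration():
    """Energetics calibrated against the two published ATP yields.

    Session-scoped: the nested grid search takes a few seconds and is
    deterministic, so all tests can share one result.
    """
    model = xf.load_core_model()
    return xf.calibrate_energetics(
        model, {"weimberg": 26.6, "oxo_reductive": 28.3}
    )


@pytest.fixture(scope="session")
def calibrated_config(calibration):
    return calibration.config
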