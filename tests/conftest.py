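import numpy as np
import pytest

from berncusum import CrudeIndicator, demo_risk_population


@pytest.fixture(scope="session")
def nec():
    """Rare-event crude indicator (neonatal surgery, c0 = 1.25%)."""
    return CrudeIndicator(id="neonatal_nec_surgery", c0=0.0125)


@pytest.fixture(scope="session")
def femur():
    """Frequent-event crude indicator (delayed femur-fracture surgery, c0 = 19.21%)."""
    return CrudeIndicator(id="femur_fracture_delay", c0=0.1921)


@pytest.fixture(scope="session")
def carotid_pop():
    """Synthetic carotid-surgery-like risk-score population."""
    return demo_risk_population(size=5000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
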