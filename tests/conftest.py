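import numpy as np
import pytest

from wellsense.circuit import CircuitParams, FrequencyGrid
from wellsense.synth import POST_EGTA_PARAMS, PRE_EGTA_PARAMS


@pytest.fixture
def band_grid():
    """Default 50-point log grid over the 10 Hz - 100 kHz instrument band."""
    return FrequencyGrid.default_band()


@pytest.fixture
def pre_params():
    return PRE_EGTA_PARAMS


@pytest.fixture
def post_params():
    return POST_EGTA_PARAMS


def random_circuit(rng: np.random.Generator) -> CircuitParams:
    """Log-uniform draw over physiological barrier-parameter ranges."""
    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return CircuitParams(
        r_media=logu(5, 50),
        r1=logu(50, 800),
        c1=logu(0.5, 15),
        r2=logu(50, 800),
        c2=logu(0.5, 15),
    )
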