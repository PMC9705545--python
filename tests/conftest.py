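import numpy as np
import pytest

from foragecast.ecocrop import CropParameters
from foragecast.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def crop():
    """A mid-of-the-road tropical grass parameter set."""
    return CropParameters(
        species_name="testgrass",
        g_used=4,
        ktmp=0.0,
        t_min=10.0,
        t_opmin=20.0,
        t_opmax=30.0,
        t_max=40.0,
        r_min=100.0,
        r_opmin=300.0,
        r_opmax=800.0,
        r_max=1500.0,
    )


@pytest.fixture
def small_config():
    """A small synthetic world that keeps grid operations fast."""
    return SyntheticConfig(n_rows=16, n_cols=20, seed=7)


def random_cell(rng, cold_chance=0.2):
    """Random 12-month (tmin, tmax, prec) exercising all score branches."""
    tavg = rng.uniform(-5.0, 45.0, 12)
    half = rng.uniform(0.0, 8.0, 12)
    tmin = tavg - half
    tmax = tavg + half
    if rng.random() < cold_chance:
        m = rng.integers(0, 12)
        tmin[m] = rng.uniform(-20.0, -1.0)
        tmax[m] = max(tmax[m], tmin[m])
    prec = rng.uniform(0.0, 400.0, 12)
    return tmin, tmax, prec
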