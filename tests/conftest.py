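import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from krillscape.grids import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20180815)


@pytest.fixture
def small_grid():
    """20x20 grid of 1-km cells."""
    return GridSpec(0.0, 0.0, 1.0, 20, 20)


@pytest.fixture
def grid_3km():
    """30x30 grid of 3-km cells (90 km square domain)."""
    return GridSpec(0.0, 0.0, 3.0, 30, 30)


@pytest.fixture
def glm_obs(rng):
    """Intercept-only Tweedie observations (no spatial structure)."""
    from krillscape.tweedie import tweedie_rvs

    n = 1500
    y = tweedie_rvs(2.5, 1.4, 0.9, rng, size=n)
    return pd.DataFrame(
        {
            "x_km": rng.uniform(0, 100, n),
            "y_km": rng.uniform(0, 100, n),
            "year": 2018,
            "nasc": y,
        }
    )
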