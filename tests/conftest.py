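import numpy as np
import pandas as pd
import pytest

from mrgxe import Dataset

# single root seed convention for the whole suite
SEED = 12345


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def iv_dataset(rng):
    """Moderate-size dataset with a real interaction, confounding, and
    pleiotropy: the generic happy-path input for estimator tests."""
    n = 4000
    g = rng.standard_normal(n)
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    x = g + 0.5 * z + 0.8 * g * z + u + rng.standard_normal(n)
    y = 1.0 * x + 0.3 * g + 0.2 * z + u + rng.standard_normal(n)
    return Dataset(y=y, x=x, g=g, z=pd.DataFrame({"z1": z}))


@pytest.fixture
def tiny_dataset(rng):
    """Fixed 16-row dataset for exact oracle comparisons."""
    n = 16
    g = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = g + z + g * z + rng.standard_normal(n)
    y = 2.0 * x + g + rng.standard_normal(n)
    return Dataset(y=y, x=x, g=g, z=pd.DataFrame({"z1": z}))
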