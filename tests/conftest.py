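import numpy as np
import pandas as pd
import pytest

from benthosom.data import CommunityMatrix, EnvMatrix
from benthosom.synthetic import GeneratorConfig, generate


@pytest.fixture
def toy_community() -> CommunityMatrix:
    """Two sites, three taxa, hand-checkable numbers."""
    ab = pd.DataFrame(
        [[16.0, 0.0, 48.0], [0.0, 32.0, 16.0]],
        index=["s1", "s2"], columns=["chironomus", "radix", "tubifex"])
    return CommunityMatrix(
        abundance=ab,
        biomass=pd.Series([2.5, 4.0], index=ab.index, name="biomass_g_m2"),
        meta=pd.DataFrame({"lake": ["A", "B"], "season": ["spring", "autumn"]},
                          index=ab.index))


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset (74 sites, 44 taxa, 13 vars)."""
    return generate(GeneratorConfig(), seed=20260922)


@pytest.fixture
def coenocline():
    """Factory for Poisson coenocline communities of known gradient length.

    Sites sit evenly along a gradient of ``length`` species-turnover SD;
    species have Gaussian responses with unit tolerance.
    """
    def make(length, n_sites=60, n_species=40, peak=50.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, length, n_sites)
        opt = np.linspace(-1.0, length + 1.0, n_species)
        mu = peak * np.exp(-0.5 * (t[:, None] - opt[None, :]) ** 2)
        y = rng.poisson(mu).astype(float)
        y = y[y.sum(axis=1) > 0][:, y.sum(axis=0) > 0]
        return pd.DataFrame(y)
    return make
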