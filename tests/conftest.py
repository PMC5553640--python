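import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

from trophoflow import (
    IndexConfig,
    TaxonTraits,
    TraitTable,
    TrophicGrid,
    TrophicSpectrum,
)


@pytest.fixture
def grid():
    return TrophicGrid()


@pytest.fixture
def toy_traits():
    """Three fish plus one invertebrate spanning TL 2.1-4.4."""
    return TraitTable(
        [
            TaxonTraits("inv", "invertebrate", 2.1, direct_pb=2.0, direct_qb=10.0),
            TaxonTraits("sprat", "fish", 3.0, K=0.5, W_inf=20.0, aspect_ratio=1.2),
            TaxonTraits("cod", "fish", 4.1, K=0.2, W_inf=9000.0, aspect_ratio=1.8),
            TaxonTraits("tuna", "fish", 4.4, K=0.3, W_inf=60000.0, aspect_ratio=3.0),
        ]
    )


@pytest.fixture
def toy_ecosystems():
    return pd.DataFrame(
        [
            {
                "ecosystem_id": "NS",
                "name": "Toy Shelf",
                "sst_mean": 10.0,
                "primary_production": 2000.0,
                "area": 100000.0,
                "eco_type": "temperate",
            }
        ]
    ).set_index("ecosystem_id", drop=False)


def uniform_spectrum(pb=1.0, pq=0.1, grid=None):
    """Spectrum with constant rates and unit catch on every class."""
    grid = grid or TrophicGrid()
    n = grid.n_classes
    return TrophicSpectrum(
        grid=grid,
        catch=np.ones(n),
        pb=np.full(n, float(pb)),
        pq=np.full(n, float(pq)),
    )


@pytest.fixture
def make_uniform_spectrum():
    return uniform_spectrum
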