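import numpy as np
import pandas as pd
import pytest

import sdmkit as sk


@pytest.fixture
def toy_table():
    """Four hand-placed records, two variables."""
    return sk.SWDTable(
        species="toy",
        coords=np.array([[0.5, 0.5], [1.5, 0.5], [0.5, 1.5], [1.5, 1.5]]),
        labels=np.array([1, 1, 0, 0]),
        data=pd.DataFrame({"temp": [1.0, 2.0, 3.0, 4.0], "rain": [10.0, 20.0, 30.0, 5.0]}),
        contrast_kind="background",
    )


def _species(seed=1, **overrides):
    base = dict(
        grid_shape=(50, 50),
        n_layers=4,
        informative=[(0, 3.0), (1, -2.0)],
        intercept=0.0,
        duplicate_of=[(3, 0, 0.05)],
        smoothness=5.0,
        n_presence=200,
        n_absence=200,
        n_background=500,
        seed=seed,
    )
    base.update(overrides)
    cfg = sk.VirtualSpeciesConfig(**base)
    stack, suit, samples = sk.simulate(cfg)
    return cfg, stack, suit, samples


@pytest.fixture(scope="session")
def species():
    """Standard virtual species: two informative layers, one pure-noise
    layer, one near-duplicate of layer 0."""
    return _species()


@pytest.fixture(scope="session")
def species_pb(species):
    return species[3]["presence_background"]


@pytest.fixture(scope="session")
def species_pa(species):
    return species[3]["presence_absence"]


@pytest.fixture(scope="session")
def maxent_pb(species_pb):
    return sk.Maxent(species_pb, fc="lq", seed=0).fit()


@pytest.fixture
def make_species():
    return _species
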