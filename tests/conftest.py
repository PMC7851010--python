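import numpy as np
import pytest

from mitemorph import LandmarkConfiguration, LandmarkDataset
from mitemorph.synthetic import SyntheticStudyConfig, simulate_specimens


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_study():
    """The default two-species study (85 specimens, Table-1-like sizes)."""
    return simulate_specimens(SyntheticStudyConfig(seed=7))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast pipeline-level tests."""
    cfg = SyntheticStudyConfig(
        seed=11,
        n_per_population=((8, 8, 7), (9, 8, 6, 5)),
        singletons_per_species=(0, 2),
    )
    return simulate_specimens(cfg)


def make_dataset(coords_list, ids=None):
    ids = ids or [f"s{i}" for i in range(len(coords_list))]
    return LandmarkDataset(
        [LandmarkConfiguration(i, c) for i, c in zip(ids, coords_list)]
    )


@pytest.fixture
def triangle_pair():
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.2, 0.8]])
    b = np.array([[0.1, -0.1], [1.1, 0.3], [-0.2, 0.9]])
    return a, b
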