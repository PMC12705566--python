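import numpy as np
import pytest

from eemstress.core import DEFAULT_GRID, EEMSample, make_grid
from eemstress.preprocess import preprocess_dataset
from eemstress.synthetic import generate_dataset, generate_worked_fixtures


@pytest.fixture(scope="session")
def default_grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def small_grid():
    """A coarse grid (14 x 53) used where full resolution is irrelevant."""
    return make_grid(240, 370, 10, 260, 520, 5)


@pytest.fixture(scope="session")
def fixtures():
    return generate_worked_fixtures()


@pytest.fixture(scope="session")
def small_study():
    """A small labelled study (7 groups x 6) with its ground truth, preprocessed."""
    dataset, truth = generate_dataset(n_per_group=6, seed=11)
    return dataset, preprocess_dataset(dataset), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sample(grid, rng, sample_id="rand") -> EEMSample:
    return EEMSample(sample_id, rng.uniform(0, 100, grid.shape), grid)
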