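import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from nonlocalpls import center_dataset, default_spec, fit_pls, sample_cohort
from nonlocalpls.phantom import PhantomSpec

MASTER_SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture(scope="session")
def tiny_spec():
    """A 2-component, 2-group phantom small enough for per-test sampling."""
    return PhantomSpec(
        grid_shape=(8, 8, 8),
        n_components=2,
        component_centers_x=((2, 2, 2), (5, 2, 5)),
        component_centers_y=((5, 5, 5), (2, 6, 2)),
        blob_sigma=1.0,
        smoothing_fwhm=1.5,
        group_means={"A": (0.0, 0.0), "B": (1.5, 0.0)},
        subjects_per_group={"A": 6, "B": 6},
        confound_amplitude=0.3,
        seed=MASTER_SEED,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 240-subject cohort with ground truth (sampled once)."""
    return sample_cohort(default_spec())


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    dataset, truth = default_cohort
    model = fit_pls(center_dataset(dataset), 6)
    return dataset, truth, model


def noiseless_spec(spec, **overrides):
    return dataclasses.replace(spec, noise_sd=0.0, confound_amplitude=0.0, **overrides)
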