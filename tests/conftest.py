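"""Shared fixtures.

The two recovery experiments (regional-effect-only and TIV-only cohorts,
three seeds each) dominate the suite's runtime, so they are session-scoped
and shared between the module tests and the end-to-end acceptance tests.
"""

import numpy as np
import pytest

from brainsexmap.experiments import (effect_recovery_experiment,
                                     tiv_signal_experiment)
from brainsexmap.phantoms import PhantomConfig, generate_cohort, make_atlas

SEEDS = (1, 2, 3)
EPOCHS = 8


@pytest.fixture(scope="session")
def effect_runs():
    """Three seeded end-to-end runs where the only sex signal is the planted
    regional intensity effect (no TIV deficit)."""
    return [effect_recovery_experiment(seed, epochs=EPOCHS) for seed in SEEDS]


@pytest.fixture(scope="session")
def tiv_runs():
    """Three seeded end-to-end runs where the only sex signal is TIV."""
    return [tiv_signal_experiment(seed, epochs=EPOCHS) for seed in SEEDS]


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas((32, 32, 32), 3, seed=5, voxel_mm=3.0,
                      envelope_tiv_ml=80.0)


@pytest.fixture(scope="session")
def small_cohort(small_atlas):
    """A 12-subject cohort of 32^3 phantoms with both signal arms on."""
    cfg = PhantomConfig(n_subjects=12, grid_shape=(32, 32, 32),
                        tiv_mean_male=120.0, tiv_sd=8.0,
                        effect_regions=(1,), seed=9)
    table, volumes = generate_cohort(cfg, small_atlas)
    return cfg, table, volumes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
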