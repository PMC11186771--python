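import numpy as np
import pytest
from hypothesis import settings

import stochclock as sc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ground():
    return sc.make_ground_state(60, seed=101)


@pytest.fixture(scope="session")
def small_bulk_clock(small_ground):
    """A quick clamped bulk dataset plus the clock trained on half of it.

    Shared by tests that need *a* working clock rather than a specific
    study design (permutation controls, serialization, CLI round trips).
    """
    cfg = sc.NoiseConfig(per_step_sd=0.1, seed=102)
    ds = sc.generate_dataset(small_ground, max_age=40, n_sets=4, cfg=cfg)
    train, validation = ds.train_validation_split(2)
    model = sc.train_clock(train, seed=0)
    return ds, train, validation, model


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
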