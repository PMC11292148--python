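import numpy as np
import pytest

import fedhybrid as fh
from fedhybrid.strategies import StrategyConfig


@pytest.fixture(scope="session")
def heart_clients():
    """heart-like cohort with holdout splits assigned (seed 11)."""
    spec = fh.preset("heart-like", seed=11)
    return fh.assign_holdout_splits(fh.generate_classification_sites(spec), 11)


@pytest.fixture(scope="session")
def surv_clients():
    """Small survival cohort with holdout splits (seed 11)."""
    spec = fh.iid_cohort(
        d=4, beta_true=[0.8, -0.5, 0.3, -0.2], task="survival",
        n_sites=3, n_per_site=80, seed=11, censoring_rate=0.3,
    )
    return fh.assign_holdout_splits(fh.generate_survival_sites(spec), 11)


@pytest.fixture()
def fast_cfg():
    return StrategyConfig(name="fedavg", rounds=5, local_epochs=2, batch_size=32)


def random_classification(rng, n, d):
    X = rng.standard_normal((n, d))
    y = (rng.random(n) < 0.5).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    return X, y


def random_survival(rng, n, d):
    X = rng.standard_normal((n, d))
    time = rng.exponential(1.0, n) + 1e-3
    event = (rng.random(n) < 0.7).astype(float)
    if event.sum() == 0:
        event[0] = 1.0
    return X, time, event
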