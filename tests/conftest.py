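import numpy as np
import pytest

from wardflow.capplan import build_cap_plan, cap_message_schemas
from wardflow.engine import Engine
from wardflow.model import mortality_training_table, train_mortality_model
from wardflow.simulate import SimConfig, simulate_cohort, simulate_reviews
from wardflow.store import ReplayStore


class StubModel:
    """Classifier stub whose positive-class probability is a function of the
    feature row (default: the first feature, clipped to [0, 1])."""

    def __init__(self, fn=None, n_features_in_=None):
        self.fn = fn or (lambda row: float(np.clip(row[0], 0.0, 1.0)))
        if n_features_in_ is not None:
            self.n_features_in_ = n_features_in_

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        p = np.array([self.fn(row) for row in X])
        return np.column_stack([1.0 - p, p])


@pytest.fixture(scope="session")
def cap_plan():
    return build_cap_plan()


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_admissions=60, seed=11)
    messages, truth = simulate_cohort(cfg)
    reviews = simulate_reviews(truth, cfg)
    return cfg, messages, truth, reviews


@pytest.fixture(scope="session")
def small_store(small_cohort):
    _, messages, _, _ = small_cohort
    return ReplayStore.from_messages(messages)


@pytest.fixture(scope="session")
def replayed_engine(cap_plan, small_store):
    engine = Engine(cap_plan, message_schemas=cap_message_schemas())
    engine.run_replay(small_store)
    return engine


@pytest.fixture(scope="session")
def demo_model():
    cfg = SimConfig(n_admissions=240, seed=23, cap_fraction=1.0)
    messages, truth = simulate_cohort(cfg)
    store = ReplayStore.from_messages(messages)
    table = mortality_training_table(store, truth)
    return train_mortality_model(table, seed=23), table
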