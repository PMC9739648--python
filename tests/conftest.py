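"""Shared fixtures: the seed-42 desk-scale corpus and trained node models.

Session-scoped so the corpus is generated and the four position classifiers
are trained exactly once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pansense.domain import PANConfig, position_by_code
from pansense.node_classifier import ModelSpec
from pansense.pipeline import corpus_to_datasets, split_aligned, train_position_models
from pansense.synth_imu import default_model, generate_corpus

DESK_SEED = 42
DESK_SESSIONS = 10
DESK_DURATION = 24.0


@pytest.fixture(scope="session")
def signal_model():
    return default_model()


@pytest.fixture(scope="session")
def desk_corpus(signal_model):
    return generate_corpus(
        signal_model,
        sessions_per_activity=DESK_SESSIONS,
        duration=DESK_DURATION,
        seed=DESK_SEED,
    )


@pytest.fixture(scope="session")
def desk_pan():
    return PANConfig(
        main_node=position_by_code("s1"),
        support_nodes=[position_by_code(c) for c in ("s2", "s3", "s4")],
        sample_rate=20.0,
        window_size=64,
    )


@pytest.fixture(scope="session")
def desk_datasets(desk_corpus, desk_pan):
    return corpus_to_datasets(desk_corpus, desk_pan)


@pytest.fixture(scope="session")
def desk_split(desk_datasets):
    return split_aligned(desk_datasets, 0.8, DESK_SEED)


@pytest.fixture(scope="session")
def desk_models(desk_split):
    train_d, _ = desk_split
    return train_position_models(train_d, ModelSpec(backend="light"), seed=DESK_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
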