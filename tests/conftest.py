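import numpy as np
import pytest

from seqembed import (
    ModelConfig, OptimizerConfig, TrajectorySpec, init_model, make_circle,
    make_ellipse, make_prediction_pair, train,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def circle_ellipse_pairs():
    circle = TrajectorySpec("circle", period_steps=50, type_id=0)
    ellipse = TrajectorySpec("ellipse", period_steps=50, type_id=1)
    return [
        make_prediction_pair(make_circle(circle), type_id=0),
        make_prediction_pair(make_ellipse(ellipse), type_id=1),
    ]


@pytest.fixture
def tiny_model():
    """Small untrained model for shape/wiring tests."""
    return init_model(ModelConfig(n_units=8, n_features=2, seed=7))


@pytest.fixture(scope="session")
def short_trained():
    """One briefly-trained circle/ellipse model shared by wiring tests."""
    circle = TrajectorySpec("circle", period_steps=20, type_id=0)
    ellipse = TrajectorySpec("ellipse", period_steps=20, type_id=1)
    pairs = [
        make_prediction_pair(make_circle(circle), type_id=0),
        make_prediction_pair(make_ellipse(ellipse), type_id=1),
    ]
    model = init_model(ModelConfig(n_units=8, n_features=2, seed=11))
    model, log = train(model, pairs, 150,
                       optimizer_config=OptimizerConfig(learning_rate=5e-3))
    return model, pairs, log
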