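"""The convolutional classifier: shapes, activations, gradients, training."""

import numpy as np
import pytest

from delfilter.model import (CNNArchitecture, TrainConfig, activation,
                             build_model, grid_search, train_sgd)
from conftest import numerical_gradient

SMALL_ARCH = CNNArchitecture(input_width=12, conv_blocks=((2, 3, 1),),
                             hidden_width=4, dropout_rate=0.0)


def test_default_layer_widths():
    arch = CNNArchitecture()
    # width 49 -> conv(1x4, stride 1) -> 46 -> pool(2) -> 23
    assert arch.layer_widths() == [(46, 23)]
    assert arch.flat_width == 8 * 23


def test_deeper_variants_are_constructible():
    arch = CNNArchitecture(conv_blocks=((8, 4, 1), (8, 4, 1)))
    (w1c, w1p), (w2c, w2p) = arch.layer_widths()
    assert (w1c, w1p) == (46, 23)
    assert (w2c, w2p) == (20, 10)
    m = build_model(arch, seed=0)
    p = m.predict_proba(np.zeros((3, 49)))
    assert p.shape == (3,)


def test_filter_wider_than_input_rejected():
    with pytest.raises(ValueError):
        CNNArchitecture(input_width=3, conv_blocks=((2, 4, 1),)).validate()


def test_same_seed_gives_identical_initial_weights():
    m1 = build_model(seed=11)
    m2 = build_model(seed=11)
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])


def test_zero_weights_output_half():
    m = build_model(seed=0)
    for k in m.params:
        m.params[k] = np.zeros_like(m.params[k])
    X = np.random.default_rng(0).random((5, 49))
    assert np.allclose(m.predict_proba(X), 0.5)


def test_activation_closed_forms():
    assert activation(0.0, "tanh") == 0.0
    assert activation(-3.0, "relu") == 0.0
    assert activation(2.5, "relu") == 2.5
    assert activation(0.0, "softplus") == pytest.approx(np.log(2))
    x = np.linspace(-50, 50, 101)
    assert np.all(np.abs(activation(x, "tanh")) <= 1.0)
    # softplus approaches relu from above
    assert activation(30.0, "softplus") - activation(30.0, "relu") < 1e-9
    assert np.isfinite(activation(1000.0, "softplus"))
    with pytest.raises(ValueError):
        activation(0.0, "sigmoidal")


@pytest.mark.parametrize("act", ["tanh", "relu", "softplus"])
def test_analytic_gradients_match_finite_differences(act):
    arch = CNNArchitecture(input_width=12, conv_blocks=((2, 3, 1),),
                           hidden_width=4, dropout_rate=0.0, activation=act)
    m = build_model(arch, seed=3)
    rng = np.random.default_rng(4)
    X = rng.random((10, 12))
    y = rng.integers(0, 2, size=10).astype(float)
    _, grads = m.loss_grads(X, y)
    num = numerical_gradient(m, X, y)
    for k in grads:
        denom = np.maximum(np.abs(num[k]), 1e-8)
        rel = np.abs(grads[k] - num[k]) / denom
        # ignore coordinates where both gradients are essentially zero
        mask = np.abs(num[k]) > 1e-7
        if mask.any():
            assert rel[mask].max() < 1e-4, k


def test_mean_pooling_gradients_also_correct():
    arch = CNNArchitecture(input_width=12, conv_blocks=((2, 3, 1),),
                           hidden_width=4, dropout_rate=0.0, pool_mode="mean")
    m = build_model(arch, seed=5)
    rng = np.random.default_rng(6)
    X = rng.random((8, 12))
    y = rng.integers(0, 2, size=8).astype(float)
    _, grads = m.loss_grads(X, y)
    num = numerical_gradient(m, X, y)
    for k in grads:
        mask = np.abs(num[k]) > 1e-7
        if mask.any():
            rel = np.abs(grads[k] - num[k]) / np.maximum(np.abs(num[k]), 1e-8)
            assert rel[mask].max() < 1e-4, k


def _toy_separable(n=20, seed=0):
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.random((n, 12)) * 0.1
    X[y == 1, :4] += 0.9
    return X, y.astype(float)


def test_separable_toy_set_reaches_full_training_accuracy():
    X, y = _toy_separable()
    m = build_model(SMALL_ARCH, seed=1)
    cfg = TrainConfig(learning_rate=0.1, batch_size=5, max_epochs=200,
                      validation_fraction=0.0, seed=1)
    m = train_sgd(m, X, y, cfg)
    _, calls = m.predict(X)
    assert (calls == y).mean() == 1.0


def test_full_batch_equals_one_update_per_epoch():
    X, y = _toy_separable(n=12, seed=2)
    calls = []
    m = build_model(SMALL_ARCH, seed=2)
    orig = type(m).loss_grads

    def counting(self, *a, **k):
        calls.append(1)
        return orig(self, *a, **k)

    type(m).loss_grads = counting
    try:
        cfg = TrainConfig(batch_size=12, max_epochs=7,
                          validation_fraction=0.0, seed=2)
        train_sgd(m, X, y, cfg)
    finally:
        type(m).loss_grads = orig
    assert len(calls) == 7  # one full-batch update per epoch


def test_epoch_update_count_is_ceil_n_over_batch():
    X, y = _toy_separable(n=13, seed=3)
    n_updates = []
    m = build_model(SMALL_ARCH, seed=3)
    orig = type(m).loss_grads

    def counting(self, *a, **k):
        n_updates.append(1)
        return orig(self, *a, **k)

    type(m).loss_grads = counting
    try:
        cfg = TrainConfig(batch_size=5, max_epochs=4, validation_fraction=0.0,
                          seed=3)
        train_sgd(m, X, y, cfg)
    finally:
        type(m).loss_grads = orig
    assert len(n_updates) == 4 * int(np.ceil(13 / 5))


def test_batch_larger_than_training_set_rejected():
    X, y = _toy_separable(n=10)
    m = build_model(SMALL_ARCH, seed=0)
    with pytest.raises(ValueError):
        train_sgd(m, X, y, TrainConfig(batch_size=11, validation_fraction=0.0))


def test_one_sgd_step_decreases_loss_at_small_rate():
    X, y = _toy_separable(n=16, seed=5)
    m = build_model(SMALL_ARCH, seed=5)
    before = m.loss(X, y)
    _, grads = m.loss_grads(X, y)
    for k, g in grads.items():
        m.params[k] = m.params[k] - 1e-3 * g
    assert m.loss(X, y) < before


def test_training_is_reproducible_from_seed():
    X, y = _toy_separable(n=30, seed=6)
    cfg = TrainConfig(batch_size=10, max_epochs=20, seed=9)
    arch = CNNArchitecture(input_width=12, conv_blocks=((2, 3, 1),),
                           hidden_width=4, dropout_rate=0.3)
    m1 = train_sgd(build_model(arch, seed=9), X, y, cfg)
    m2 = train_sgd(build_model(arch, seed=9), X, y,
                   TrainConfig(batch_size=10, max_epochs=20, seed=9))
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])
    assert [h["val_loss"] for h in m1.history] == \
        [h["val_loss"] for h in m2.history]


def test_prediction_is_deterministic_despite_dropout():
    arch = CNNArchitecture(input_width=12, conv_blocks=((2, 3, 1),),
                           hidden_width=4, dropout_rate=0.5)
    m = build_model(arch, seed=1)
    X = np.random.default_rng(2).random((6, 12))
    assert np.array_equal(m.predict_proba(X), m.predict_proba(X))


def test_threshold_boundaries():
    m = build_model(SMALL_ARCH, seed=4)
    X = np.random.default_rng(3).random((8, 12))
    _, all_one = m.predict(X, threshold=0.0)
    assert all_one.tolist() == [1] * 8
    probs, all_zero = m.predict(X, threshold=1.0 + 1e-12)
    assert all_zero.tolist() == [0] * 8


def test_wrong_feature_count_rejected():
    m = build_model(seed=0)
    with pytest.raises(ValueError):
        m.predict_proba(np.zeros((2, 48)))


def test_model_round_trips_through_disk(tmp_path):
    from delfilter.features import Normalizer
    X, y = _toy_separable(n=18, seed=7)
    norm = Normalizer().fit(X)
    m = train_sgd(build_model(SMALL_ARCH, seed=7, normalizer=norm), X, y,
                  TrainConfig(batch_size=6, max_epochs=10, seed=7))
    m.save(tmp_path / "model")
    from delfilter.model import TrainedModel
    back = TrainedModel.load(tmp_path / "model")
    assert np.allclose(back.predict_proba(X), m.predict_proba(X))
    assert np.allclose(back.normalizer.min_, norm.min_)


def test_grid_search_table_shape_and_single_cell():
    X, y = _toy_separable(n=60, seed=8)
    cfg = TrainConfig(max_epochs=30)
    df = grid_search(X, y, lr_grid=[0.1, 0.01], batch_grid=[4, 16],
                     replicates=1, train_config=cfg,
                     architecture=SMALL_ARCH, seed=0)
    assert len(df) == 4
    assert set(df.columns) >= {"learning_rate", "batch_size", "accuracy",
                               "sensitivity", "f_score", "mortality"}
    one = grid_search(X, y, lr_grid=[0.1], batch_grid=[8], replicates=1,
                      train_config=cfg, architecture=SMALL_ARCH, seed=0)
    assert len(one) == 1
    assert 0.0 <= one.loc[0, "f_score"] <= 1.0
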