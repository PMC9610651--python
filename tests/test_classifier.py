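"""MLP mechanics, backprop correctness, training behavior, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octdr.classifier import (ClassifierError, FeatureScaler, MLPParams,
                              TrainConfig, default_search_space,
                              fit_single_feature, fit_two_stage, forward,
                              grid_search_architecture, init_network,
                              load_model, loss_and_grads, predict,
                              save_model, train_backprop)
from octdr.classifier import _one_hot

from conftest import synthetic_records


def test_init_is_deterministic_and_shaped():
    a = init_network(9, 67, 123)
    b = init_network(9, 67, 123)
    assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)
    assert a.W1.shape == (9, 67) and a.W2.shape == (67, 2)
    assert np.all(a.b1 == 0) and np.all(a.b2 == 0)


def test_zero_weights_give_uniform_probabilities():
    net = init_network(5, 7, 0)
    net.W1[:], net.W2[:] = 0.0, 0.0
    p = forward(net, np.array([3.0, -1.0, 2.0, 0.0, 9.0]))
    assert p == pytest.approx([0.5, 0.5])


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10_000))
def test_softmax_outputs_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    net = init_network(4, 6, seed)
    p = forward(net, rng.normal(size=(20, 4)) * 10)
    assert np.all((p > 0) & (p < 1))
    assert np.allclose(p.sum(axis=1), 1.0)


def test_forward_matches_hand_computed_2_2_2_net():
    """Weights small enough to track through tanh and softmax by hand."""
    net = init_network(2, 2, 0)
    net.W1[:] = [[0.5, -0.5], [1.0, 0.0]]
    net.b1[:] = [0.1, -0.1]
    net.W2[:] = [[1.0, -1.0], [0.5, 0.5]]
    net.b2[:] = [0.0, 0.2]
    x = np.array([1.0, 2.0])
    h = np.tanh([0.5 + 2.0 + 0.1, -0.5 + 0.0 - 0.1])
    logits = np.array([h[0] * 1.0 + h[1] * 0.5,
                       h[0] * -1.0 + h[1] * 0.5 + 0.2])
    expected = np.exp(logits) / np.exp(logits).sum()
    assert forward(net, x) == pytest.approx(expected, rel=1e-12)


def test_backprop_gradients_match_finite_differences():
    rng = np.random.default_rng(1)
    net = init_network(4, 5, 2)
    X = rng.normal(size=(7, 4))
    Y = _one_hot(rng.integers(0, 2, 7))
    _, grads = loss_and_grads(net, X, Y)
    eps = 1e-6
    for name in ("W1", "b1", "W2", "b2"):
        P = getattr(net, name)
        it = np.nditer(P, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = P[i]
            P[i] = orig + eps
            lp, _ = loss_and_grads(net, X, Y)
            P[i] = orig - eps
            lm, _ = loss_and_grads(net, X, Y)
            P[i] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(1e-8, abs(num) + abs(grads[name][i]))
            assert abs(num - grads[name][i]) / denom < 1e-5


def test_linearly_separable_cohort_trains_to_high_accuracy():
    rng = np.random.default_rng(42)
    X = np.vstack([rng.normal(-1, 0.5, (100, 2)), rng.normal(1, 0.5, (100, 2))])
    y = np.r_[np.zeros(100, int), np.ones(100, int)]
    net = train_backprop(init_network(2, 8, 0), X, y, TrainConfig(seed=0))
    acc = (np.argmax(forward(net, X), axis=1) == y).mean()
    assert acc >= 0.99
    assert net.trained


def test_xor_learnable_with_four_hidden_units():
    X = np.tile(np.array([[-1.0, -1], [-1, 1], [1, -1], [1, 1]]), (10, 1))
    y = np.tile(np.array([0, 1, 1, 0]), 10)
    net = train_backprop(init_network(2, 4, 3), X, y,
                         TrainConfig(seed=3, max_epochs=2000))
    assert (np.argmax(forward(net, X), axis=1) == y).mean() == 1.0


def test_training_loss_non_increasing_at_default_rate():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(-1, 1, (50, 3)), rng.normal(1, 1, (50, 3))])
    y = np.r_[np.zeros(50, int), np.ones(50, int)]
    net = init_network(3, 10, 7)
    cfg = TrainConfig()
    Y = _one_hot(y)
    params = {"W1": net.W1, "b1": net.b1, "W2": net.W2, "b2": net.b2}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    losses = []
    for _ in range(500):
        loss, grads = loss_and_grads(net, X, Y)
        losses.append(loss)
        for k in params:
            vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * grads[k]
            params[k] += vel[k]
    assert np.all(np.diff(losses) <= 1e-6)


def test_single_class_input_rejected():
    X = np.zeros((10, 3))
    with pytest.raises(ClassifierError, match="each class"):
        train_backprop(init_network(3, 4, 0), X, np.zeros(10, int),
                       TrainConfig())


def test_divergence_raises_helpful_error():
    """A wildly excessive rate on non-separable data blows the loss up."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(20, 2))
    y = rng.integers(0, 2, 20)
    with pytest.raises(ClassifierError, match="learning rate"):
        train_backprop(init_network(2, 4, 0), X, y,
                       TrainConfig(learning_rate=1000.0))


# ---------------------------------------------------------------------------
# two-stage model
# ---------------------------------------------------------------------------

CFG = TrainConfig(seed=0, max_epochs=300)


def test_fusion_input_dimension_is_24(feature_records):
    model = fit_two_stage(feature_records[:20] + feature_records[-20:], CFG)
    assert model.fusion_input_dim == 24
    assert model.fusion.input_dim == 24
    assert len(model.stage1) == 24


def test_two_stage_resubstitution_accuracy(feature_records):
    model = fit_two_stage(feature_records, CFG)
    correct = [model.predict_record(r)[1] == r.class_label
               for r in feature_records]
    assert np.mean(correct) >= 0.95


def test_two_stage_probabilities_in_unit_interval(feature_records):
    model = fit_two_stage(feature_records, CFG)
    for rec in feature_records[::5]:
        p, label = predict(model, rec)
        assert 0.0 < p < 1.0
        assert label in ("normal", "DR")


def test_two_stage_training_is_bit_deterministic(tmp_path, feature_records):
    m1 = fit_two_stage(feature_records, CFG)
    m2 = fit_two_stage(feature_records, CFG)
    for key in m1.stage1:
        assert np.array_equal(m1.stage1[key].W1, m2.stage1[key].W1)
        assert np.array_equal(m1.stage1[key].W2, m2.stage1[key].W2)
    assert np.array_equal(m1.fusion.W1, m2.fusion.W1)
    # and the serialized containers are byte-identical
    p1, p2 = tmp_path / "m1.npz", tmp_path / "m2.npz"
    save_model(m1, p1)
    save_model(m2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_model_save_load_round_trip(tmp_path, feature_records):
    model = fit_two_stage(feature_records, CFG)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    for rec in feature_records[::7]:
        assert back.predict_record(rec)[0] == pytest.approx(
            model.predict_record(rec)[0])


def test_naive_and_oof_fusion_modes_differ(feature_records):
    oof = fit_two_stage(feature_records, CFG, fusion_mode="oof")
    naive = fit_two_stage(feature_records, CFG, fusion_mode="naive")
    assert not np.array_equal(oof.fusion.W1, naive.fusion.W1)


def test_untrained_model_prediction_rejected(feature_records):
    from octdr.classifier import TwoStageModel, init_network

    model = TwoStageModel(stage1={}, scalers={}, fusion=init_network(24, 6, 0),
                          kinds=("reflectivity", "thickness"),
                          layers=tuple(range(1, 13)), cfg=CFG)
    with pytest.raises(ClassifierError, match="not trained"):
        model.predict_record(feature_records[0])


def test_single_feature_model(feature_records):
    model = fit_single_feature(feature_records, "thickness", 1, CFG)
    acc = np.mean([model.predict_record(r)[1] == r.class_label
                   for r in feature_records])
    assert acc >= 0.9


def test_scaler_handles_constant_features():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    s = FeatureScaler.fit(X)
    out = s.transform(X)
    assert np.all(np.isfinite(out))
    assert np.all(out[:, 0] == 0.0)


# ---------------------------------------------------------------------------
# architecture search
# ---------------------------------------------------------------------------

def test_selected_architecture_expressible_in_search_space():
    space = default_search_space()
    assert 1 in space["n_hidden_layers"]
    for width in (67, 72, 6):
        assert width in space["hidden_units"]


def test_grid_search_ranks_configs():
    records = synthetic_records(n_per_class=10, shift=3.0, seed=1)
    grid = [{"refl_hidden": 8, "thick_hidden": 8, "fusion_hidden": 4},
            {"refl_hidden": 16, "thick_hidden": 16, "fusion_hidden": 4}]
    cfg = TrainConfig(seed=0, max_epochs=100)
    table = grid_search_architecture(records, grid, "kfold5", cfg, seed=0)
    assert len(table) == 2
    assert table["accuracy"].is_monotonic_decreasing

    single = grid_search_architecture(records, grid[:1], "kfold5", cfg, seed=0)
    assert len(single) == 1

    with pytest.raises(ClassifierError, match="empty"):
        grid_search_architecture(records, [], "kfold5", cfg)
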