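"""The sigmoid MLP: forward pass, confidence, gradients, training, I/O."""

import json
import math
import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ptmnet.mlp import (
    MLPModel,
    ModelFormatError,
    TrainConfig,
    confidence,
    forward,
    forward_batch,
    gradient,
    init_network,
    load_model,
    one_hot_targets,
    predict,
    predict_batch,
    save_model,
    sse,
    train_backprop,
)
from ptmnet.model import PredictionRecord


def _bias_only_net(p_pos: float) -> MLPModel:
    """A 3-input network whose responses are (p_pos, 1 - p_pos) regardless of x."""
    logit = lambda p: math.log(p / (1 - p))
    return MLPModel(
        [3, 2],
        [np.zeros((3, 2))],
        [np.array([logit(p_pos), logit(1 - p_pos)])],
    )


class TestInit:
    def test_shapes_follow_layer_sizes(self):
        m = init_network([90, 10, 2], seed=1)
        assert [w.shape for w in m.weights] == [(90, 10), (10, 2)]
        assert [b.shape for b in m.biases] == [(10,), (2,)]

    def test_same_seed_reproduces_parameters(self):
        a, b = init_network([5, 3, 2], seed=42), init_network([5, 3, 2], seed=42)
        assert all((wa == wb).all() for wa, wb in zip(a.weights, b.weights))

    def test_parameters_respect_init_range(self):
        m = init_network([20, 10, 2], seed=0, init_range=0.25)
        assert all(np.abs(w).max() <= 0.25 for w in m.weights)

    @pytest.mark.parametrize("sizes", [[90], [5, 0, 2], [0, 2]])
    def test_degenerate_architectures_rejected(self, sizes):
        with pytest.raises(ValueError):
            init_network(sizes, seed=0)


class TestForward:
    def test_zero_network_outputs_half(self):
        m = MLPModel([4, 3, 2], [np.zeros((4, 3)), np.zeros((3, 2))],
                     [np.zeros(3), np.zeros(2)])
        assert forward(m, np.ones(4)) == pytest.approx([0.5, 0.5])

    def test_single_hidden_unit_matches_hand_computation(self):
        m = MLPModel(
            [2, 1, 2],
            [np.array([[0.3], [-0.2]]), np.array([[0.5, -0.4]])],
            [np.array([0.1]), np.array([0.2, -0.1])],
        )
        sig = lambda z: 1.0 / (1.0 + math.exp(-z))
        a1 = sig(1.0 * 0.3 + 0.5 * -0.2 + 0.1)
        expected = [sig(0.5 * a1 + 0.2), sig(-0.4 * a1 - 0.1)]
        assert forward(m, np.array([1.0, 0.5])) == pytest.approx(expected, abs=1e-12)

    def test_responses_lie_strictly_inside_unit_interval(self):
        m = init_network([6, 4, 2], seed=3)
        r = forward(m, np.linspace(-1, 1, 6))
        assert (r > 0).all() and (r < 1).all()

    def test_increasing_positive_output_weight_raises_response(self):
        m = init_network([6, 4, 2], seed=3)
        x = np.linspace(0, 1, 6)
        before = forward(m, x)[0]
        m.weights[1][0, 0] += 0.1
        assert forward(m, x)[0] > before

    def test_dimension_mismatch_rejected(self):
        m = init_network([6, 4, 2], seed=3)
        with pytest.raises(ValueError, match="shape"):
            forward(m, np.zeros(5))

    def test_batch_forward_agrees_with_single(self):
        m = init_network([6, 4, 2], seed=3)
        X = np.random.default_rng(0).uniform(0, 1, (5, 6))
        batch = forward_batch(m, X)
        for i in range(5):
            assert batch[i] == pytest.approx(forward(m, X[i]), abs=1e-14)


class TestConfidence:
    @pytest.mark.parametrize(
        "responses,expected",
        [((0.8, 0.2), (0.8, 0.2)), ((0.6, 0.6), (0.5, 0.5)), ((0.3, 0.1), (0.75, 0.25))],
    )
    def test_normalized_responses(self, responses, expected):
        assert confidence(np.array(responses)) == pytest.approx(expected)

    @given(r0=st.floats(0.01, 0.99), r1=st.floats(0.01, 0.99))
    def test_confidences_always_sum_to_one(self, r0, r1):
        c = confidence(np.array([r0, r1]))
        assert c.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nan_responses_rejected(self):
        with pytest.raises(ValueError):
            confidence(np.array([math.nan, 0.5]))


class TestPredict:
    def test_positive_class_wins_with_its_confidence(self):
        d, c = predict(_bias_only_net(0.9), np.zeros(3))
        assert d == 1
        assert c == pytest.approx(0.9)

    def test_tie_classifies_negative(self):
        d, c = predict(_bias_only_net(0.5), np.zeros(3))
        assert (d, c) == (0, pytest.approx(0.5))

    def test_rendered_line_matches_output_format(self):
        line = PredictionRecord("LYTHIGRNI", 1, 0.7823).render()
        assert line == "LYTHIGRNI 1 0.7823"
        assert re.fullmatch(r"[A-Z]{9} [01] (0\.\d{4}|1\.0000)", line)

    def test_batch_predict_agrees_with_single(self):
        m = init_network([6, 4, 2], seed=9)
        X = np.random.default_rng(1).uniform(0, 1, (8, 6))
        dec, conf, pos = predict_batch(m, X)
        for i in range(8):
            d, c = predict(m, X[i])
            assert dec[i] == d and conf[i] == pytest.approx(c)


class TestGradient:
    @pytest.mark.parametrize("sizes", [[3, 2], [4, 3, 2], [10, 8, 2]])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_central_finite_differences(self, sizes, seed):
        rng = np.random.default_rng(seed)
        m = init_network(sizes, seed=seed)
        x = rng.uniform(-1, 1, sizes[0])
        t = np.zeros(sizes[-1])
        t[0] = 1.0
        gw, gb = gradient(m, x, t)
        h = 1e-5
        worst = 0.0
        for l in range(len(m.weights)):
            for idx in np.ndindex(m.weights[l].shape):
                m.weights[l][idx] += h
                up = 0.5 * sse(m, x, t)
                m.weights[l][idx] -= 2 * h
                dn = 0.5 * sse(m, x, t)
                m.weights[l][idx] += h
                worst = max(worst, abs((up - dn) / (2 * h) - gw[l][idx]))
            for j in range(m.biases[l].size):
                m.biases[l][j] += h
                up = 0.5 * sse(m, x, t)
                m.biases[l][j] -= 2 * h
                dn = 0.5 * sse(m, x, t)
                m.biases[l][j] += h
                worst = max(worst, abs((up - dn) / (2 * h) - gb[l][j]))
        assert worst < 1e-6


def _reference_plain_sgd(model, X, T, eta, epochs):
    """Independent momentum-free SGD written with explicit neuron loops."""
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    W = [w.copy() for w in model.weights]
    B = [b.copy() for b in model.biases]
    trace = []
    for _ in range(epochs):
        total = 0.0
        for x, t in zip(X, T):
            acts = [list(x)]
            for l in range(len(W)):
                layer = []
                for j in range(W[l].shape[1]):
                    z = B[l][j]
                    for i in range(W[l].shape[0]):
                        z += acts[-1][i] * W[l][i, j]
                    layer.append(sig(z))
                acts.append(layer)
            err = [acts[-1][j] - t[j] for j in range(len(t))]
            total += sum(e * e for e in err)
            deltas = [err[j] * acts[-1][j] * (1 - acts[-1][j]) for j in range(len(err))]
            for l in range(len(W) - 1, -1, -1):
                prev = [
                    sum(W[l][i, j] * deltas[j] for j in range(len(deltas)))
                    * acts[l][i]
                    * (1 - acts[l][i])
                    for i in range(W[l].shape[0])
                ]
                for i in range(W[l].shape[0]):
                    for j in range(W[l].shape[1]):
                        W[l][i, j] -= eta * acts[l][i] * deltas[j]
                for j in range(W[l].shape[1]):
                    B[l][j] -= eta * deltas[j]
                deltas = prev
        trace.append(total)
    return W, B, trace


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        m = init_network([4, 3, 2], seed=0)
        before = [w.copy() for w in m.weights]
        X = np.random.default_rng(0).uniform(0, 1, (6, 4))
        T = one_hot_targets([1, 0, 1, 0, 1, 0])
        train_backprop(m, X, T, TrainConfig(eta=0.0, delta=0.0, epochs=3, seed=0))
        assert all((a == b).all() for a, b in zip(before, m.weights))

    def test_without_momentum_training_is_plain_sgd(self):
        m = init_network([4, 3, 2], seed=2)
        ref = m.copy()
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (7, 4))
        T = one_hot_targets(rng.integers(0, 2, 7))
        _, trace = train_backprop(
            m, X, T, TrainConfig(eta=0.3, delta=0.0, epochs=4, seed=0, shuffle=False)
        )
        W, B, ref_trace = _reference_plain_sgd(ref, X, T, eta=0.3, epochs=4)
        assert trace == pytest.approx(ref_trace, rel=1e-10)
        for l in range(len(W)):
            assert m.weights[l] == pytest.approx(W[l], rel=1e-10)
            assert m.biases[l] == pytest.approx(B[l], rel=1e-10)

    def test_single_sample_converges_below_tolerance(self):
        # independent check that the target is attainable by plain descent
        m0 = init_network([4, 3, 2], seed=1)
        X = np.array([[0.2, 0.8, 0.5, 0.1]])
        T = np.array([[1.0, 0.0]])
        _, _, ref_trace = _reference_plain_sgd(m0.copy(), X, T, eta=0.8, epochs=2000)
        assert ref_trace[-1] < 1e-2
        _, trace = train_backprop(
            m0, X, T, TrainConfig(eta=0.8, delta=0.8, epochs=5000, seed=1)
        )
        assert trace[-1] < 1e-3

    def test_learns_separable_motif_data(self, encoder, strong_dataset):
        # a step gentle enough for plain convergence without checkpointing
        X = encoder.encode_many(strong_dataset.segments())
        y = np.array(strong_dataset.labels())
        m = init_network([encoder.input_dim, 4, 2], seed=0)
        train_backprop(
            m, X, one_hot_targets(y), TrainConfig(eta=0.2, delta=0.2, epochs=150, seed=0)
        )
        dec, _, _ = predict_batch(m, X)
        assert (dec != y).mean() < 0.05

    def test_shape_mismatch_rejected(self):
        m = init_network([4, 3, 2], seed=0)
        with pytest.raises(ValueError):
            train_backprop(m, np.zeros((3, 5)), np.zeros((3, 2)), TrainConfig(epochs=1))


class TestPersistence:
    def test_roundtrip_preserves_forward_outputs_exactly(self, tmp_path):
        m = init_network([6, 4, 2], seed=8)
        m.metadata = {"ptm_type": "demo", "criterion": "auc", "seed": 8}
        path = tmp_path / "model.json"
        save_model(m, path)
        back = load_model(path)
        x = np.linspace(0, 1, 6)
        assert (forward(back, x) == forward(m, x)).all()
        assert back.metadata == m.metadata

    def test_tampered_dimensions_rejected(self, tmp_path):
        m = init_network([6, 4, 2], seed=8)
        path = tmp_path / "model.json"
        save_model(m, path)
        doc = json.loads(path.read_text())
        doc["layer_sizes"] = [6, 5, 2]
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_wrong_schema_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text(json.dumps({"schema": "other/9"}))
        with pytest.raises(ModelFormatError, match="schema"):
            load_model(path)
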