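"""Reference equation oracles, the autodiff layers, and the assembled network.

Every trainable layer type is checked against an independent loop-level
implementation of its defining equation, and the assembled small network is
checked end-to-end against a composition of those references.
"""

import numpy as np
import pytest

from apnea_st import autodiff as ad
from apnea_st.autodiff import Tensor
from apnea_st.errors import ConfigError, ShapeError
from apnea_st.model import Model, ModelSpec, build_model, model_forward
from apnea_st.reference import (
    GRUCellParams,
    bigru_run,
    conv1d,
    dot_attention,
    gru_step,
    max_pool,
)
from apnea_st.training import _bce_loss_graph


class TestConv:
    def test_hand_computed_valid_convolution(self):
        assert conv1d([1, 2, 3, 4], [1, 1, 1]).tolist() == [6.0, 9.0]

    def test_identity_kernel(self):
        x = np.arange(10, dtype=float)
        assert np.array_equal(conv1d(x, [0, 1, 0]), x[1:-1])

    def test_matches_double_loop_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 2))
        w = rng.normal(size=(3, 2, 4))
        got = conv1d(x, w)
        expected = np.zeros((18, 4))
        for k in range(4):
            for i in range(18):
                acc = 0.0
                for u in range(3):
                    for c in range(2):
                        acc += w[u, c, k] * x[i + u, c]
                expected[i, k] = acc
        assert np.max(np.abs(got - expected)) < 1e-10

    def test_autodiff_layer_agrees_with_reference(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 15, 2))
        w = rng.normal(size=(3, 2, 5))
        got = ad.conv1d_same(Tensor(x), Tensor(w)).data
        for b in range(3):
            assert np.max(np.abs(got[b] - conv1d(x[b], w, padding="same"))) < 1e-12

    def test_channel_mismatch_is_shape_error(self):
        with pytest.raises(ShapeError):
            conv1d(np.zeros((10, 3)), np.zeros((3, 2, 4)))


class TestMaxPool:
    def test_hand_examples(self):
        assert max_pool(np.array([1, 3, 2, 5, 4, 6.0])).tolist() == [3.0, 6.0]
        assert max_pool(np.full(9, 2.5)).tolist() == [2.5, 2.5, 2.5]

    def test_remainder_dropped_and_matches_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        got = max_pool(x, k=3, stride=3)
        assert len(got) == 33
        expected = [x[s : s + 3].max() for s in range(0, 98, 3)]
        assert np.allclose(got, expected)

    def test_autodiff_pool_agrees_with_reference(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 10, 4))
        got = ad.max_pool1d(Tensor(x), 3).data
        for b in range(2):
            assert np.array_equal(got[b], max_pool(x[b], 3, 3))

    def test_invalid_pool_size(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros(6), k=0)


class TestGRUStep:
    def test_zero_weights_halve_previous_state(self):
        """sigma(0)=0.5 and tanh(0)=0 force h_t = 0.5 * h_prev."""
        z = np.zeros((3, 2)), np.zeros((3, 3))
        p = GRUCellParams(z[0], z[1], z[0].copy(), z[1].copy(), z[0].copy(), z[1].copy())
        h_prev = np.array([1.0, -2.0, 4.0])
        assert np.allclose(gru_step(p, h_prev, np.zeros(2)), 0.5 * h_prev)

    def test_saturated_update_gate_keeps_state(self):
        n = 3
        big = 50.0 * np.ones((n, 2)), 50.0 * np.ones((n, n))
        zero = np.zeros((n, 2)), np.zeros((n, n))
        p = GRUCellParams(zero[0], zero[1], big[0], big[1], zero[0].copy(), zero[1].copy())
        h_prev = np.array([0.3, 0.2, 0.1])
        h = gru_step(p, h_prev, np.ones(2))
        assert np.allclose(h, h_prev, atol=1e-8)

    def test_matches_elementwise_scalar_oracle(self):
        rng = np.random.default_rng(4)
        p = GRUCellParams.random(2, 3, rng)
        h_prev, x_t = rng.normal(size=3), rng.normal(size=2)
        got = gru_step(p, h_prev, x_t)
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        for j in range(3):
            r_j = sig(p.W_r[j] @ x_t + p.U_r[j] @ h_prev)
            z_j = sig(p.W_z[j] @ x_t + p.U_z[j] @ h_prev)
            h_tilde_j = np.tanh(p.W_x[j] @ x_t + r_j * (p.U_x[j] @ h_prev))
            expected_j = z_j * h_prev[j] + (1 - z_j) * h_tilde_j
            assert abs(got[j] - expected_j) < 1e-12


class TestBiGRU:
    def test_single_step_equals_one_gru_step(self):
        rng = np.random.default_rng(5)
        pf, pb = GRUCellParams.random(2, 3, rng), GRUCellParams.random(2, 3, rng)
        seq = rng.normal(size=(1, 2))
        out = bigru_run(pf, pb, seq)
        assert np.allclose(out.F[0], gru_step(pf, np.zeros(3), seq[0]))
        assert np.allclose(out.B[0], gru_step(pb, np.zeros(3), seq[0]))

    def test_zero_weights_propagate_zero(self):
        z = np.zeros((2, 2))
        p = GRUCellParams(z, z, z.copy(), z.copy(), z.copy(), z.copy())
        out = bigru_run(p, p, np.ones((5, 2)))
        assert np.all(out.F == 0) and np.all(out.B == 0)

    def test_backward_equals_forward_on_reversed_input(self):
        rng = np.random.default_rng(6)
        pf, pb = GRUCellParams.random(3, 4, rng), GRUCellParams.random(3, 4, rng)
        seq = rng.normal(size=(7, 3))
        out = bigru_run(pf, pb, seq)
        rev = bigru_run(pb, pb, seq[::-1])
        assert np.allclose(out.B, rev.F[::-1])

    def test_empty_sequence_rejected(self):
        rng = np.random.default_rng(7)
        p = GRUCellParams.random(2, 2, rng)
        with pytest.raises(ValueError):
            bigru_run(p, p, np.zeros((0, 2)))


class TestAttention:
    def test_zero_queries_give_uniform_average(self):
        rng = np.random.default_rng(8)
        B = rng.normal(size=(4, 3))
        a = dot_attention(np.zeros((4, 3)), B)
        assert np.allclose(a, np.tile(B.mean(axis=0), (4, 1)))

    def test_one_hot_limit_selects_key_row(self):
        s = 4
        B = np.eye(s)
        F = np.zeros((s, s))
        F[1] = 200.0 * np.eye(s)[2]
        a = dot_attention(F, B)
        assert np.allclose(a[1], np.eye(s)[2], atol=1e-8)

    def test_matches_explicit_softmax_oracle(self):
        rng = np.random.default_rng(9)
        F, B = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        got = dot_attention(F, B)
        for i in range(4):
            scores = np.array([F[i] @ B[j] for j in range(4)])
            w = np.exp(scores) / np.exp(scores).sum()
            assert np.max(np.abs(got[i] - w @ B)) < 1e-10

    def test_autodiff_attention_agrees_with_reference(self):
        rng = np.random.default_rng(10)
        F, B = rng.normal(size=(2, 5, 3)), rng.normal(size=(2, 5, 3))
        tF, tB = Tensor(F), Tensor(B)
        got = (ad.softmax(tF @ tB.swapaxes(1, 2), axis=-1) @ tB).data
        for b in range(2):
            assert np.max(np.abs(got[b] - dot_attention(F[b], B[b]))) < 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            dot_attention(np.zeros((4, 3)), np.zeros((4, 2)))


class TestBuildModel:
    def test_default_stack_matches_published_architecture(self):
        model = build_model(ModelSpec())
        names = [layer.name for layer in model.layers]
        block = ["Convolutional", "Max-Pooling", "Dropout", "Bidirectional GRU", "Dropout"]
        expected = (
            ["Convolutional"]
            + block * 2
            + ["Convolutional", "Max-Pooling", "Dropout", "Bidirectional GRU"]
            + ["Attention", "Flatten", "Dense", "Dropout", "Dense", "Dense"]
        )
        assert names == expected
        assert len(names) == 21
        convs = [l for l in model.layers if l.name == "Convolutional"]
        assert all(l.w.shape[2] == 128 and l.kernel == 3 for l in convs)
        denses = [l for l in model.layers if l.name == "Dense"]
        assert [d.w.shape[1] for d in denses] == [64, 64, 2]

    def test_sequence_length_contraction(self):
        assert build_model(ModelSpec()).seq_lengths == [900, 300, 100, 33]

    def test_parameter_count_is_stable(self):
        assert build_model(ModelSpec()).num_params() == 1_111_042

    def test_single_block_configuration(self):
        model = build_model(ModelSpec(n_blocks=1))
        names = [layer.name for layer in model.layers]
        assert names == [
            "Convolutional", "Convolutional", "Max-Pooling", "Dropout",
            "Bidirectional GRU", "Attention", "Flatten", "Dense", "Dropout",
            "Dense", "Dense",
        ]

    def test_collapsing_sequence_is_config_error(self):
        with pytest.raises(ConfigError, match="block"):
            build_model(ModelSpec(n_blocks=3, input_len=9))

    def test_forward_outputs_valid_probability_pairs(self):
        spec = ModelSpec(n_blocks=1, filters=6, gru_units=4, dense_units=8, input_len=36)
        model = build_model(spec, seed=0)
        X = np.random.default_rng(0).normal(size=(8, 36, 2))
        probs = model_forward(model, X)
        assert probs.shape == (8, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert np.max(np.abs(probs.sum(axis=1) - 1.0)) < 1e-6

    def test_inference_is_deterministic(self):
        spec = ModelSpec(n_blocks=1, filters=4, gru_units=3, dense_units=4, input_len=18)
        model = build_model(spec, seed=1)
        X = np.random.default_rng(1).normal(size=(4, 18, 2))
        assert np.array_equal(model_forward(model, X), model_forward(model, X))

    def test_wrong_input_shape_rejected(self):
        model = build_model(ModelSpec(n_blocks=1, filters=4, gru_units=3, input_len=18))
        with pytest.raises(ShapeError):
            model.forward(np.zeros((2, 17, 2)))


def _reference_forward(model: Model, x: np.ndarray) -> np.ndarray:
    """Compose the network from the reference equation implementations."""
    spec = model.spec
    layers = model.layers
    li = 0
    h = x
    # stem + blocks
    h = np.maximum(conv1d(h, layers[li].w.data, padding="same"), 0.0); li += 1
    for b in range(spec.n_blocks):
        h = np.maximum(conv1d(h, layers[li].w.data, padding="same"), 0.0); li += 1
        h = max_pool(h, spec.pool_size, spec.pool_size); li += 1
        li += 1  # dropout inactive at inference
        gru = layers[li]; li += 1
        def params(ws):
            W_r, U_r, W_z, U_z, W_x, U_x = [w.data for w in ws]
            return GRUCellParams(W_r.T, U_r.T, W_z.T, U_z.T, W_x.T, U_x.T)
        out = bigru_run(params(gru.fwd), params(gru.bwd), h)
        if gru.return_pair:
            F, B = out.F, out.B
        else:
            h = np.concatenate([out.F, out.B], axis=-1)
            li += 1  # inter-block dropout
    a = dot_attention(F, B)
    li += 1  # attention
    h = a.reshape(-1)
    li += 1  # flatten
    d1 = layers[li]; li += 1
    h = np.maximum(h @ d1.w.data + d1.b.data, 0.0)
    li += 1  # dropout
    d2 = layers[li]; li += 1
    h = np.maximum(h @ d2.w.data + d2.b.data, 0.0)
    d3 = layers[li]
    logits = h @ d3.w.data + d3.b.data
    e = np.exp(logits - logits.max())
    return e / e.sum()


def test_network_matches_reference_equation_composition():
    """The assembled tiny network equals the composed per-equation oracles."""
    spec = ModelSpec(
        n_blocks=2, filters=4, gru_units=2, dense_units=5, input_len=27,
        input_channels=2, dropout_rate=0.0,
    )
    model = build_model(spec, seed=3)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(3, 27, 2))
    got = model_forward(model, X)
    for b in range(3):
        expected = _reference_forward(model, X[b])
        assert np.max(np.abs(got[b] - expected)) < 1e-5


def test_gradients_match_finite_differences():
    """Backprop through the full layer stack against central differences."""
    spec = ModelSpec(
        n_blocks=1, filters=3, gru_units=2, dense_units=4, input_len=18,
        dropout_rate=0.0,
    )
    model = build_model(spec, seed=0)
    X = np.random.default_rng(0).normal(size=(3, 18, 2))
    y = np.array([0, 1, 1])

    loss = _bce_loss_graph(y, model.forward(X)[:, 1])
    for p in model.params():
        p.zero_grad()
    loss.backward()

    rng = np.random.default_rng(5)
    for p in model.params():
        grad = p.grad if p.grad is not None else np.zeros_like(p.data)
        for _ in range(2):
            i = tuple(rng.integers(0, s) for s in p.data.shape)
            eps, old = 1e-6, p.data[i]
            p.data[i] = old + eps
            lp = float(_bce_loss_graph(y, model.forward(X)[:, 1]).data)
            p.data[i] = old - eps
            lm = float(_bce_loss_graph(y, model.forward(X)[:, 1]).data)
            p.data[i] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - grad[i]) <= 1e-6 + 1e-4 * (abs(num) + abs(grad[i]))
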