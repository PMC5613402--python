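"""Forward model: embedding, GRU cell, regression, softmax, window pass."""

import numpy as np
import pytest

from grusynth.network import (
    GruLayerParams,
    GruState,
    embed,
    forward_window,
    gru_step,
    init_params,
    regression,
    softmax,
)


def zero_layer(hidden, input_dim):
    z = lambda *s: np.zeros(s)
    return GruLayerParams(W_r=z(hidden, input_dim), U_r=z(hidden, hidden),
                          W_z=z(hidden, input_dim), U_z=z(hidden, hidden),
                          W_h=z(hidden, input_dim), U_h=z(hidden, hidden))


class TestInitParams:
    def test_seed_determinism(self):
        a, b = init_params(8, 4, 5), init_params(8, 4, 5)
        for (ka, va), (kb, vb) in zip(a.to_dict().items(), b.to_dict().items()):
            assert ka == kb
            np.testing.assert_array_equal(va, vb)

    def test_shapes(self):
        p = init_params(6, 3, 0)
        assert p.E.shape == (6, 6)
        assert p.V.shape == (3, 6)
        assert p.b_o.shape == (6,)
        assert p.layers[0].W_r.shape == (3, 6)  # layer 1 projects S_D
        assert p.layers[1].W_r.shape == (3, 3)  # deeper layers project H_D
        assert p.layers[2].U_h.shape == (3, 3)
        np.testing.assert_array_equal(p.b_o, 0.0)

    def test_init_range(self):
        p = init_params(16, 8, 1)
        for name, arr in p.to_dict().items():
            if name != "b_o":
                assert np.all(np.abs(arr) <= 0.08)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            init_params(1, 4, 0)
        with pytest.raises(ValueError):
            init_params(8, 0, 0)


class TestEmbed:
    def test_identity_gives_one_hot(self):
        e = embed(3, np.eye(6))
        np.testing.assert_array_equal(e, np.eye(6)[3])

    def test_returns_requested_column(self, rng):
        E = rng.standard_normal((5, 5))
        np.testing.assert_array_equal(embed(0, E), E[:, 0])
        np.testing.assert_array_equal(embed(4, E), E[:, 4])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            embed(5, np.eye(5))


class TestGruStep:
    """The three analytic cell identities."""

    def test_zero_weights_halve_previous_state(self, rng):
        layer = zero_layer(4, 3)
        v = rng.standard_normal(4)
        out = gru_step(rng.standard_normal(3), v, layer)
        np.testing.assert_allclose(out, 0.5 * v, rtol=0, atol=1e-15)

    def test_saturated_update_gate_keeps_old_state(self, rng):
        layer = zero_layer(4, 3)
        layer.W_z[:] = 1e4  # sigmoid saturates to 1 -> state kept
        v = rng.standard_normal(4)
        out = gru_step(np.ones(3), v, layer)
        np.testing.assert_allclose(out, v, rtol=0, atol=1e-12)

    def test_closed_gates_give_pure_input_response(self, rng):
        layer = zero_layer(4, 3)
        layer.W_z[:] = -1e4  # z -> 0: state fully rewritten
        layer.W_r[:] = -1e4  # r -> 0: previous state ignored
        layer.W_h[:] = rng.standard_normal((4, 3))
        x = rng.standard_normal(3)
        for h_prev in (np.zeros(4), rng.standard_normal(4)):
            out = gru_step(x, h_prev, layer)
            np.testing.assert_allclose(out, np.tanh(layer.W_h @ x), atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        layer = zero_layer(4, 3)
        with pytest.raises(ValueError):
            gru_step(np.zeros(4), np.zeros(4), layer)


class TestRegression:
    def test_zero_state_returns_bias(self, rng):
        V = rng.standard_normal((4, 6))
        b = rng.standard_normal(6)
        np.testing.assert_array_equal(regression(np.zeros(4), V, b), b)

    def test_hand_case(self):
        out = regression(np.array([2.0]), np.array([[1.0, -1.0]]),
                         np.array([0.5, 0.0]))
        np.testing.assert_allclose(out, [2.5, -2.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression(np.zeros(3), np.zeros((4, 6)), np.zeros(6))


class TestSoftmax:
    def test_uniform_for_equal_inputs(self):
        np.testing.assert_allclose(softmax(np.full(5, 2.3)), 0.2)

    def test_known_ratio(self):
        np.testing.assert_allclose(softmax(np.array([0.0, np.log(2)])),
                                   [1 / 3, 2 / 3])

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(10)
        np.testing.assert_allclose(softmax(x), softmax(x + 123.4), atol=1e-12)

    def test_large_inputs_stable(self):
        out = softmax(np.array([1000.0, 1000.0]))
        np.testing.assert_allclose(out, 0.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([np.inf, 0.0]))


class TestForwardWindow:
    def test_output_shape_and_normalization(self, tiny_params, rng):
        x = rng.integers(0, 8, size=20)
        probs, state = forward_window(x, tiny_params)
        assert probs.shape == (20, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_deterministic(self, tiny_params, rng):
        x = rng.integers(0, 8, size=15)
        p1, _ = forward_window(x, tiny_params)
        p2, _ = forward_window(x, tiny_params)
        np.testing.assert_array_equal(p1, p2)

    def test_state_continuity_across_halves(self, tiny_params, rng):
        """Forward over 2n samples == two n-sample passes with threaded state."""
        x = rng.integers(0, 8, size=30)
        full, _ = forward_window(x, tiny_params)
        first, state = forward_window(x[:15], tiny_params)
        second, _ = forward_window(x[15:], tiny_params, state)
        np.testing.assert_allclose(np.vstack([first, second]), full, atol=1e-14)

    def test_gate_and_state_bounds(self, rng):
        p = init_params(8, 4, 3)
        # scale weights up so gates operate away from 0.5
        for arr in p.to_dict().values():
            arr *= 30
        x = rng.integers(0, 8, size=200)
        probs, state = forward_window(x, p)
        for h in state.h:
            assert np.all(np.abs(h) <= 1.0 + 1e-12)

    def test_matches_scalar_oracle(self):
        """Unrolled scalar-by-scalar recomputation of the whole model."""
        rng = np.random.default_rng(7)
        p = init_params(4, 2, 11)
        for arr in p.to_dict().values():
            arr += rng.normal(0, 0.4, arr.shape)
        x = np.array([1, 3, 0])
        probs, _ = forward_window(x, p)

        def sig(a):
            return 1.0 / (1.0 + np.exp(-a))

        h = [np.zeros(2) for _ in range(3)]
        expected = []
        for xn in x:
            vec = p.E[:, xn]
            for l, layer in enumerate(p.layers):
                r = sig(layer.W_r @ vec + layer.U_r @ h[l])
                z = sig(layer.W_z @ vec + layer.U_z @ h[l])
                hc = np.tanh(layer.W_h @ vec + layer.U_h @ (r * h[l]))
                h[l] = z * h[l] + (1 - z) * hc
                vec = h[l]
            o_hat = p.b_o + p.V.T @ h[2]
            e = np.exp(o_hat - o_hat.max())
            expected.append(e / e.sum())
        np.testing.assert_allclose(probs, np.array(expected), atol=1e-12)

    def test_out_of_alphabet_rejected(self, tiny_params):
        with pytest.raises(ValueError):
            forward_window(np.array([0, 8]), tiny_params)


class TestGruState:
    def test_zero_init(self):
        s = GruState.zeros(5)
        assert len(s.h) == 3
        for h in s.h:
            np.testing.assert_array_equal(h, 0.0)
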