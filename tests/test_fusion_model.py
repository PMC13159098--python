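"""Recurrence semantics, heads, losses and analytic gradients."""

import numpy as np
import pytest

from biscale import (FusionParams, coefficients, finetune_losses, forward,
                     forward_backward, loss_global, loss_local,
                     recurrence_step)

from _reference import reference_forward


def small_params(d=3, G=2, seed=0, **kw):
    return FusionParams.init(d, G, seed=seed, **kw)


class TestCoefficients:
    def test_zero_input_zero_bias_gives_zero(self):
        p = small_params()
        a, b, c, g = coefficients(np.zeros(3), p)
        for v in (a, b, c, g):
            np.testing.assert_array_equal(v, 0.0)

    def test_identity_decay_map_passes_input_through(self):
        p = small_params()
        p.params["W_a"] = np.eye(3)
        x = np.array([0.3, -1.2, 2.0])
        a, *_ = coefficients(x, p)
        np.testing.assert_allclose(a, x)

    def test_matches_matrix_vector_oracle(self):
        rng = np.random.default_rng(5)
        p = small_params(seed=5)
        x = rng.normal(size=3)
        a, b, c, g = coefficients(x, p)
        for got, (W, bias) in zip(
                (a, b, c, g),
                ((p.params["W_a"], p.params["b_a"]),
                 (p.params["W_b"], p.params["b_b"]),
                 (p.params["W_c"], p.params["b_c"]),
                 (p.params["W_g"], p.params["b_g"]))):
            expected = [sum(W[i][j] * x[j] for j in range(3)) + bias[i]
                        for i in range(3)]
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(FloatingPointError):
            coefficients(np.array([1.0, np.nan, 0.0]), small_params())


class TestRecurrenceStep:
    def test_first_step_is_input_injection_only(self):
        p = small_params(seed=2)
        x = np.array([1.0, -2.0, 0.5])
        h, y = recurrence_step(np.zeros(3), x, p)
        _, b, c, g = coefficients(x, p)
        np.testing.assert_allclose(h, b * x)
        np.testing.assert_allclose(y, g * c * h)

    def test_zero_decay_is_memoryless(self):
        p = small_params(seed=3)
        p.params["W_a"][:] = 0.0
        x = np.array([0.2, 0.4, -0.1])
        h_prev = np.array([9.0, -9.0, 9.0])
        h, _ = recurrence_step(h_prev, x, p)
        _, b, *_ = coefficients(x, p)
        np.testing.assert_allclose(h, b * x)

    def test_trace_matches_hand_unrolled_loop(self):
        # d=2, n=3 with small integer weights, fully hand-checkable
        p = FusionParams.init(2, 1, seed=0)
        p.params["W_a"] = np.array([[1.0, 0.0], [0.0, 0.5]])
        p.params["W_b"] = np.eye(2)
        p.params["W_c"] = np.array([[0.0, 1.0], [1.0, 0.0]])
        p.params["W_g"] = np.eye(2) * 2.0
        for k in ("b_a", "b_b", "b_c", "b_g"):
            p.params[k][:] = 0.0
        xs = [np.array([1.0, 1.0]), np.array([0.5, -1.0]), np.array([2.0, 0.0])]
        h = np.zeros(2)
        for x in xs:
            a = p.params["W_a"] @ x
            b, c, g = x.copy(), p.params["W_c"] @ x, 2.0 * x
            h_expected = a * h + b * x
            h, y = recurrence_step(h, x, p)
            np.testing.assert_allclose(h, h_expected, atol=1e-12)
            np.testing.assert_allclose(y, g * c * h_expected, atol=1e-12)


class TestForward:
    def test_cls_state_depends_on_input(self):
        p = small_params(seed=1)
        x = np.array([[0.5, -0.2, 1.0]])
        base = forward(x, p).global_output
        bumped = forward(x + 0.1, p).global_output
        assert np.abs(base - bumped).max() > 0

    def test_order_sensitivity(self):
        rng = np.random.default_rng(9)
        p = small_params(seed=9)
        X = rng.normal(size=(4, 3))
        out1 = forward(X, p)
        out2 = forward(X[::-1], p)
        assert np.abs(out1.global_prediction - out2.global_prediction).max() > 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            forward(np.zeros((0, 3)), small_params())

    @pytest.mark.parametrize("sigmoid_decay", [False, True])
    def test_matches_reference_loop(self, sigmoid_decay):
        rng = np.random.default_rng(12)
        for trial in range(10):
            d, n, G = rng.integers(2, 5), rng.integers(1, 6), rng.integers(1, 4)
            p = FusionParams.init(int(d), int(G), seed=trial,
                                  sigmoid_decay=sigmoid_decay)
            for k in ("b_a", "b_b", "b_c", "b_g"):
                p.params[k][:] = rng.normal(scale=0.3, size=int(d))
            X = rng.normal(size=(int(n), int(d)))
            out = forward(X, p)
            ref_local_y, ref_cls_y, ref_local_z, ref_global_z = \
                reference_forward(X, p)
            np.testing.assert_allclose(out.local_outputs, ref_local_y, atol=1e-9)
            np.testing.assert_allclose(out.global_output, ref_cls_y, atol=1e-9)
            np.testing.assert_allclose(out.local_predictions, ref_local_z, atol=1e-9)
            np.testing.assert_allclose(out.global_prediction, ref_global_z, atol=1e-9)

    def test_recurrence_homogeneity_in_input_scale(self):
        # zero biases, single step: a,b and c,g each contribute one input
        # factor, so h is quadratic and y quartic in the input scale
        rng = np.random.default_rng(21)
        p = small_params(seed=21)
        X = rng.normal(size=(1, 3))
        y1 = forward(X, p).local_outputs
        s = 1.7
        ys = forward(s * X, p).local_outputs
        np.testing.assert_allclose(ys, s ** 4 * y1, rtol=1e-9)


class TestLosses:
    def test_zero_at_perfection(self):
        z = np.random.default_rng(0).normal(size=(4, 3))
        assert loss_local(z, z) == 0.0
        assert loss_global(z[0], z[0]) == 0.0

    def test_uniform_offset_gives_squared_delta(self):
        z = np.random.default_rng(1).normal(size=(5, 4))
        assert loss_local(z + 0.3, z) == pytest.approx(0.09)
        assert loss_global(z[0] + 0.3, z[0]) == pytest.approx(0.09)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        pred, truth = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        expected = sum((pred[i, j] - truth[i, j]) ** 2
                       for i in range(3) for j in range(4)) / (3 * 4)
        assert loss_local(pred, truth) == pytest.approx(expected)
        g_expected = sum((pred[0, j] - truth[0, j]) ** 2 for j in range(4)) / 4
        assert loss_global(pred[0], truth[0]) == pytest.approx(g_expected)

    def test_sum_convention(self):
        rng = np.random.default_rng(3)
        pred, truth = rng.normal(size=(2, 5)), rng.normal(size=(2, 5))
        assert loss_local(pred, truth, reduce="sum") == \
            pytest.approx(5 * loss_local(pred, truth))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_local(np.zeros((2, 3)), np.zeros((2, 4)))


class TestFinetuneLosses:
    def test_reference_values(self):
        assert finetune_losses(1.0, 2.0, 0.1) == (pytest.approx(1.9),
                                                  pytest.approx(1.1))

    def test_symmetric_at_half(self):
        lb, ls = finetune_losses(0.7, 1.3, 0.5)
        assert lb == pytest.approx(ls)

    def test_equal_terms_collapse(self):
        lb, ls = finetune_losses(2.5, 2.5, 0.3)
        assert lb == pytest.approx(2.5) and ls == pytest.approx(2.5)

    def test_convex_pair_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            local, glob = rng.uniform(0, 5, 2)
            lam = rng.uniform(0.01, 0.99)
            lb, ls = finetune_losses(local, glob, lam)
            assert lb + ls == pytest.approx(local + glob)

    @pytest.mark.parametrize("lam", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_lambda_rejected(self, lam):
        with pytest.raises(ValueError):
            finetune_losses(1.0, 1.0, lam)


@pytest.mark.parametrize("sigmoid_decay", [False, True])
def test_analytic_gradients_match_finite_differences(sigmoid_decay):
    rng = np.random.default_rng(6)
    d, G, n = 3, 2, 4
    p = FusionParams.init(d, G, seed=6, sigmoid_decay=sigmoid_decay)
    X = rng.normal(size=(n, d))
    zl, zg = rng.normal(size=(n, G)), rng.normal(size=G)

    def total(params):
        out = forward(X, params)
        return (0.7 * loss_local(out.local_predictions, zl)
                + 1.3 * loss_global(out.global_prediction, zg))

    _, _, grads = forward_backward(X, p, zl, zg, w_local=0.7, w_global=1.3)
    eps = 1e-6
    for key, arr in p.params.items():
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            f1 = total(p)
            arr[idx] = orig - eps
            f2 = total(p)
            arr[idx] = orig
            num = (f1 - f2) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7), key


def test_checkpoint_roundtrip(tmp_path):
    p = FusionParams.for_training(5, 4, "bulk", seed=8,
                                  meta={"gene_panel": ["a", "b", "c", "d"]})
    path = tmp_path / "ckpt.npz"
    p.save(path, stage_tag="pretrain_bulk")
    q, header = FusionParams.load(path)
    assert header["stage_tag"] == "pretrain_bulk"
    assert header["gene_panel"] == ["a", "b", "c", "d"]
    assert q.sigmoid_decay is True
    for k in p.params:
        np.testing.assert_array_equal(p.params[k], q.params[k])
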