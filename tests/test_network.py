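"""Network stages against independent, explicitly-looped oracles."""

import numpy as np
import pytest

from deepcatcr._autodiff import Tensor, kmax_pool
from deepcatcr.network import (ModelConfig, NumericError, bilstm,
                               conv_multiscale, forward, forward_parts,
                               init_parameters, motif_importance,
                               self_attention)

RNG = np.random.default_rng(2024)


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def params(config):
    return init_parameters(config, np.random.default_rng(0))


class TestConvMultiscale:
    def test_zero_input_gives_relu_of_bias(self, config, params):
        x = Tensor(np.zeros((2, 20, 15)))
        maps = conv_multiscale(x, params, config)
        for k in config.kernel_heights:
            expected = np.maximum(params[f"conv{k}.b"].data, 0.0)
            np.testing.assert_allclose(
                maps[k].data, np.broadcast_to(expected, maps[k].shape))

    def test_feature_map_lengths_are_L_minus_k_plus_1(self, config, params):
        x = Tensor(RNG.standard_normal((3, 20, 15)))
        maps = conv_multiscale(x, params, config)
        for k in config.kernel_heights:
            assert maps[k].shape == (3, 20 - k + 1, 4)

    def test_matches_explicit_sliding_window_loop(self, config, params):
        """Direct two-loop dot-product oracle over windows and filters."""
        x = RNG.standard_normal((2, 20, 15))
        maps = conv_multiscale(Tensor(x), params, config)
        for k in config.kernel_heights:
            W = params[f"conv{k}.W"].data  # (k*15, 4)
            b = params[f"conv{k}.b"].data
            for s in range(2):
                for i in range(20 - k + 1):
                    window = x[s, i:i + k, :].ravel()
                    for f in range(4):
                        expected = max(0.0, window @ W[:, f] + b[f])
                        assert maps[k].data[s, i, f] == pytest.approx(
                            expected, abs=1e-12)

    def test_width_mismatch_raises(self, config, params):
        with pytest.raises(ValueError, match="width"):
            conv_multiscale(Tensor(np.zeros((1, 20, 14))), params, config)


class TestKmaxPool:
    def test_sort_then_reorder_oracle(self):
        rng = np.random.default_rng(5)
        fm = rng.standard_normal((4, 19, 4))
        out = kmax_pool(Tensor(fm), 3, axis=1).data
        for s in range(4):
            for f in range(4):
                col = fm[s, :, f]
                top_idx = np.sort(np.argsort(col)[-3:])
                np.testing.assert_array_equal(out[s, :, f], col[top_idx])

    def test_constant_map_returns_constants(self):
        out = kmax_pool(Tensor(np.full((1, 7, 1), 2.5)), 3, axis=1)
        np.testing.assert_allclose(out.data, 2.5)

    def test_k_equals_length_is_identity(self):
        fm = RNG.standard_normal((1, 5, 2))
        out = kmax_pool(Tensor(fm), 5, axis=1)
        np.testing.assert_array_equal(out.data, fm)

    def test_permutation_covariance_of_value_multiset(self):
        fm = RNG.standard_normal((1, 11, 1))
        perm = np.random.default_rng(1).permutation(11)
        a = kmax_pool(Tensor(fm), 4, axis=1).data.ravel()
        b = kmax_pool(Tensor(fm[:, perm, :]), 4, axis=1).data.ravel()
        np.testing.assert_allclose(np.sort(a), np.sort(b))


class TestSelfAttention:
    def test_zero_projections_give_uniform_attention(self):
        H = RNG.standard_normal((2, 5, 4))
        zero = Tensor(np.zeros((4, 4)))
        eye = Tensor(np.eye(4))
        out, alpha = self_attention(Tensor(H), zero, zero, eye, heads=2,
                                    return_weights=True)
        np.testing.assert_allclose(alpha.data, 1.0 / 5)
        # with uniform weights and identity value projection, each output row
        # is the mean of the inputs
        np.testing.assert_allclose(out.data, np.broadcast_to(
            H.mean(axis=1, keepdims=True), H.shape), atol=1e-12)

    def test_single_position_weight_is_exactly_one(self):
        H = RNG.standard_normal((1, 1, 4))
        Wq = Tensor(RNG.standard_normal((4, 4)))
        _, alpha = self_attention(Tensor(H), Wq, Wq, Wq, heads=2,
                                  return_weights=True)
        np.testing.assert_allclose(alpha.data, 1.0)

    def test_rows_are_stochastic_per_head(self):
        H = RNG.standard_normal((3, 6, 4))
        Wq = Tensor(RNG.standard_normal((4, 4)))
        Wk = Tensor(RNG.standard_normal((4, 4)))
        _, alpha = self_attention(Tensor(H), Wq, Wk, None, heads=2,
                                  return_weights=True)
        np.testing.assert_allclose(alpha.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_matches_naive_double_loop_oracle(self):
        """Explicit per-head, per-position loop implementation."""
        H = RNG.standard_normal((1, 4, 4))
        Wq = RNG.standard_normal((4, 4))
        Wk = RNG.standard_normal((4, 4))
        Wv = RNG.standard_normal((4, 4))
        heads, d_h = 2, 2
        out = self_attention(Tensor(H), Tensor(Wq), Tensor(Wk), Tensor(Wv),
                             heads=heads).data[0]
        Q, K, V = H[0] @ Wq, H[0] @ Wk, H[0] @ Wv
        oracle = np.zeros((4, 4))
        for h in range(heads):
            sl = slice(h * d_h, (h + 1) * d_h)
            q, k, v = Q[:, sl], K[:, sl], V[:, sl]
            for i in range(4):
                logits = np.array([q[i] @ k[j] / np.sqrt(d_h)
                                   for j in range(4)])
                w = np.exp(logits - logits.max())
                w /= w.sum()
                oracle[i, sl] = sum(w[j] * v[j] for j in range(4))
        np.testing.assert_allclose(out, oracle, atol=1e-9)


class TestBiLSTM:
    def test_matches_hand_rolled_gate_recurrence(self, config, params):
        """Step-by-step sigmoid/tanh gate equations, forward and backward."""
        A = RNG.standard_normal((1, 3, 16))
        out = bilstm(Tensor(A), params, config).data[0]
        m = config.lstm_hidden

        def run(xs, Wx, Wh, b):
            h = np.zeros(m)
            c = np.zeros(m)
            outs = []
            for x in xs:
                z = x @ Wx + h @ Wh + b
                sig = lambda v: 1 / (1 + np.exp(-v))
                i, f = sig(z[:m]), sig(z[m:2 * m])
                g, o = np.tanh(z[2 * m:3 * m]), sig(z[3 * m:])
                c = f * c + i * g
                h = o * np.tanh(c)
                outs.append(h)
            return outs

        fwd = run(list(A[0]), params["lstm.fwd.Wx"].data,
                  params["lstm.fwd.Wh"].data, params["lstm.fwd.b"].data)
        bwd = run(list(A[0])[::-1], params["lstm.bwd.Wx"].data,
                  params["lstm.bwd.Wh"].data, params["lstm.bwd.b"].data)[::-1]
        oracle = np.hstack([np.stack(fwd), np.stack(bwd)])
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_reversal_symmetry(self, config, params):
        """Reversing the input sequence swaps forward and backward halves."""
        A = RNG.standard_normal((2, 3, 16))
        swapped = dict(params)
        swapped["lstm.fwd.Wx"], swapped["lstm.bwd.Wx"] = (
            params["lstm.bwd.Wx"], params["lstm.fwd.Wx"])
        swapped["lstm.fwd.Wh"], swapped["lstm.bwd.Wh"] = (
            params["lstm.bwd.Wh"], params["lstm.fwd.Wh"])
        swapped["lstm.fwd.b"], swapped["lstm.bwd.b"] = (
            params["lstm.bwd.b"], params["lstm.fwd.b"])
        out = bilstm(Tensor(A), params, config).data
        rev = bilstm(Tensor(A[:, ::-1, :].copy()), swapped, config).data
        m = config.lstm_hidden
        np.testing.assert_allclose(out[:, :, :m], rev[:, ::-1, m:], atol=1e-12)
        np.testing.assert_allclose(out[:, :, m:], rev[:, ::-1, :m], atol=1e-12)

    def test_length_one_sequence(self, config, params):
        A = RNG.standard_normal((1, 1, 16))
        out = bilstm(Tensor(A), params, config)
        assert out.shape == (1, 1, 2 * config.lstm_hidden)


class TestForward:
    def test_probabilities_sum_to_one_and_lie_in_unit_interval(
            self, config, params):
        x = RNG.standard_normal((100, 20, 15))
        probs = forward(x, params, config).data
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.isfinite(probs))

    def test_fully_ablated_equals_stage_composition_oracle(self):
        """With both BiLSTM and MHSA off, the forward pass is exactly
        conv -> kmax -> flatten -> FC -> softmax composed by hand."""
        config = ModelConfig(use_bilstm=False, use_mhsa=False)
        params = init_parameters(config, np.random.default_rng(3))
        x = RNG.standard_normal((4, 20, 15))
        got = forward(x, params, config).data

        blocks = []
        for k in config.kernel_heights:
            W, b = params[f"conv{k}.W"].data, params[f"conv{k}.b"].data
            n_win = 20 - k + 1
            fm = np.zeros((4, n_win, 4))
            for s in range(4):
                for i in range(n_win):
                    fm[s, i] = np.maximum(0.0, x[s, i:i + k].ravel() @ W + b)
            pooled = np.zeros((4, 3, 4))
            for s in range(4):
                for f in range(4):
                    idx = np.sort(np.argsort(fm[s, :, f])[-3:])
                    pooled[s, :, f] = fm[s, idx, f]
            blocks.append(pooled)
        H = np.concatenate(blocks, axis=2)  # (4, 3, 16)
        flat = H.reshape(4, -1)
        hidden = np.maximum(0.0, flat @ params["fc.W"].data + params["fc.b"].data)
        logits = hidden @ params["out.W"].data + params["out.b"].data
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        oracle = e / e.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    @pytest.mark.parametrize("use_bilstm,use_mhsa", [
        (True, True), (False, True), (True, False), (False, False)])
    def test_ablation_flags_keep_interfaces_intact(self, use_bilstm, use_mhsa):
        config = ModelConfig(use_bilstm=use_bilstm, use_mhsa=use_mhsa)
        params = init_parameters(config, np.random.default_rng(1))
        probs = forward(RNG.standard_normal((2, 20, 15)), params, config).data
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_eval_mode_is_deterministic(self, config, params):
        x = RNG.standard_normal((5, 20, 15))
        a = forward(x, params, config).data
        b = forward(x, params, config).data
        np.testing.assert_array_equal(a, b)

    def test_non_finite_intermediate_names_stage(self, config, params):
        params["out.W"].data[0, 0] = np.nan
        with pytest.raises(NumericError, match="logits"):
            forward_parts(Tensor(RNG.standard_normal((1, 20, 15))),
                          params, config)


class TestMotifImportance:
    def test_importance_vector_length_equals_sequence_length(
            self, config, params, fixture_proj):
        rng = np.random.default_rng(8)
        from deepcatcr.simulate import FixtureSpec, generate_cdr3
        spec = FixtureSpec(seed=8)
        for _ in range(10):
            seq = generate_cdr3(spec, rng)
            mi = motif_importance(seq, params, config, fixture_proj,
                                  trained=False)
            assert len(mi.residue_scores) == len(seq)
            assert np.all(mi.residue_scores >= 0)
            assert mi.metadata["trained"] is False

    def test_top_motif_lengths_match_kernel_heights(self, config, params,
                                                    fixture_proj):
        mi = motif_importance("CASSLGQAYEQYF", params, config, fixture_proj)
        assert all(2 <= len(m) <= 5 for m, _ in mi.top_motifs)
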