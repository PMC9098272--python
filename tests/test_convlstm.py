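"""The modified recurrent cell and attention head, checked element by element
against an independent scalar-loop evaluation of the defining equations."""

import math

import numpy as np
import pytest

from midecoder import (AttentionParams, AttentionSpec, ConvLSTMCell, ConvLSTMParams,
                       DSCConvLSTM, ModelConfig, RecurrentSpec, attention_pool,
                       bidirectional_fuse, build_model, convlstm_step, run_convlstm,
                       load_checkpoint, save_checkpoint)
from midecoder import BackboneConfig
from midecoder.exceptions import AssemblyError, ConfigurationError


def random_params(rng, n, k=3, scale=1.0) -> ConvLSTMParams:
    def mat():
        return (scale * rng.standard_normal((n, n))).astype(np.float32)

    def vec():
        return (scale * rng.standard_normal(n)).astype(np.float32)

    return ConvLSTMParams(
        w_xf=mat(), w_hf=mat(), b_f=vec(),
        w_xi=mat(), w_hi=mat(), b_i=vec(),
        w_xo=mat(), w_ho=mat(), b_o=vec(),
        w_xc=(scale * rng.standard_normal(k)).astype(np.float32),
        w_hc=(scale * rng.standard_normal(k)).astype(np.float32),
        b_c=vec())


def scalar_step(x, h_prev, c_prev, p: ConvLSTMParams):
    """Pure-python reference: the cell equations evaluated element by element.

    x may be [maps] or [maps, H, W]; spatial extents are mean-pooled first.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim > 1:
        x = x.reshape(x.shape[0], -1).mean(axis=1)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    n = len(h_prev)
    k = len(p.w_xc)
    half = k // 2

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    def gate(wx, wh, b):
        out = np.zeros(n)
        for j in range(n):
            s = b[j]
            for i in range(len(x)):
                s += x[i] * wx[i, j]
            for i in range(n):
                s += h_prev[i] * wh[i, j]
            out[j] = sig(s)
        return out

    def feat_conv(v, kernel):
        out = np.zeros(len(v))
        for j in range(len(v)):
            s = 0.0
            for t in range(k):
                src = j + t - half
                if 0 <= src < len(v):
                    s += v[src] * kernel[t]
            out[j] = s
        return out

    f = gate(p.w_xf, p.w_hf, p.b_f)
    i_g = gate(p.w_xi, p.w_hi, p.b_i)
    o = gate(p.w_xo, p.w_ho, p.b_o)
    cand = np.tanh(feat_conv(x, p.w_xc) + feat_conv(h_prev, p.w_hc) + p.b_c)
    c = f * c_prev + i_g * cand
    h = o * np.tanh(c)
    return h, c


class TestCellOracle:
    def test_matches_scalar_loop_on_100_random_instances(self):
        """Vectorised cell == element-wise reference, max abs diff < 1e-6."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for trial in range(100):
            n = int(rng.integers(2, 9))
            p = random_params(rng, n)
            x = rng.standard_normal(n).astype(np.float32)
            h0 = rng.standard_normal(n).astype(np.float32)
            c0 = rng.standard_normal(n).astype(np.float32)
            h, c = convlstm_step(x[None], (h0[None], c0[None]), p)
            h_ref, c_ref = scalar_step(x, h0, c0, p)
            worst = max(worst, np.abs(h[0] - h_ref).max(), np.abs(c[0] - c_ref).max())
        assert worst < 1e-6

    def test_spatial_input_is_mean_pooled(self):
        rng = np.random.default_rng(5)
        n = 4
        p = random_params(rng, n)
        x_map = rng.standard_normal((n, 2, 3)).astype(np.float32)
        h0 = np.zeros(n, dtype=np.float32)
        c0 = np.zeros(n, dtype=np.float32)
        h_a, _ = convlstm_step(x_map[None], (h0[None], c0[None]), p)
        h_b, _ = convlstm_step(x_map.reshape(n, -1).mean(axis=1)[None],
                               (h0[None], c0[None]), p)
        np.testing.assert_allclose(h_a, h_b, atol=1e-6)

    def test_zero_weights_halve_everything(self):
        """All-zero weights: every gate is sigmoid(0)=1/2, so the memory is
        halved and H = 0.5 * tanh(0.5 * C_prev)."""
        n = 5
        zeros = ConvLSTMParams(*[np.zeros(s, dtype=np.float32) for s in
                                 [(n, n), (n, n), n, (n, n), (n, n), n,
                                  (n, n), (n, n), n, 3, 3, n]])
        c_prev = np.linspace(-2, 2, n).astype(np.float32)
        x = np.ones(n, dtype=np.float32)
        h, c = convlstm_step(x[None], (np.zeros((1, n), np.float32), c_prev[None]), zeros)
        np.testing.assert_allclose(c[0], 0.5 * c_prev, atol=1e-7)
        np.testing.assert_allclose(h[0], 0.5 * np.tanh(0.5 * c_prev), atol=1e-7)

    def test_zero_memory_and_candidate_give_zero_output(self):
        rng = np.random.default_rng(6)
        n = 4
        p = random_params(rng, n)
        p.w_xc[:] = 0
        p.w_hc[:] = 0
        p.b_c[:] = 0
        x = rng.standard_normal((1, n)).astype(np.float32)
        h, c = convlstm_step(x, (np.zeros((1, n), np.float32),
                                 np.zeros((1, n), np.float32)), p)
        assert np.all(h == 0) and np.all(c == 0)

    def test_gate_and_hidden_bounds(self):
        """On 1000 random draws every gate lies strictly in (0,1) and |H| < 1."""
        rng = np.random.default_rng(7)
        from midecoder.autodiff import Tensor

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v.astype(np.float64)))

        for _ in range(10):
            p = random_params(rng, 8, scale=0.5)
            cell = ConvLSTMCell.from_params(p)
            x = rng.standard_normal((100, 8)).astype(np.float32)
            h0 = rng.uniform(-1, 1, (100, 8)).astype(np.float32)
            c0 = rng.standard_normal((100, 8)).astype(np.float32)
            for wx, wh, b in [(p.w_xf, p.w_hf, p.b_f), (p.w_xi, p.w_hi, p.b_i),
                              (p.w_xo, p.w_ho, p.b_o)]:
                gate = sig(x @ wx + h0 @ wh + b)
                assert (gate > 0).all() and (gate < 1).all()
            h, c = cell.step(Tensor(x), (Tensor(h0), Tensor(c0)))
            assert np.abs(h.data).max() < 1.0

    def test_mismatched_hidden_width_rejected(self):
        with pytest.raises(AssemblyError, match="hidden_size"):
            ConvLSTMCell(16, RecurrentSpec(hidden_size=8))


class TestSequence:
    def test_single_step_directions_agree(self):
        rng = np.random.default_rng(8)
        p = random_params(rng, 4)
        seq = rng.standard_normal((1, 2, 4)).astype(np.float32)
        np.testing.assert_array_equal(run_convlstm(seq, p, "forward"),
                                      run_convlstm(seq, p, "backward"))

    def test_backward_is_reversed_forward_of_reversed_input(self):
        rng = np.random.default_rng(9)
        p = random_params(rng, 5)
        seq = rng.standard_normal((6, 3, 5)).astype(np.float32)
        bwd = run_convlstm(seq, p, "backward")
        ref = run_convlstm(seq[::-1], p, "forward")[::-1]
        np.testing.assert_allclose(bwd, ref, atol=1e-7)

    def test_causality(self):
        """Perturbing the input at step 4 must not change hidden states 0-2."""
        rng = np.random.default_rng(10)
        p = random_params(rng, 5)
        seq = rng.standard_normal((6, 2, 5)).astype(np.float32)
        base = run_convlstm(seq, p, "forward")
        pert = seq.copy()
        pert[4] += 10.0
        out = run_convlstm(pert, p, "forward")
        np.testing.assert_array_equal(out[:4], base[:4])
        assert not np.allclose(out[4:], base[4:])

    def test_empty_sequence_rejected(self):
        with pytest.raises(ConfigurationError):
            run_convlstm([], random_params(np.random.default_rng(0), 3))


class TestFusion:
    def test_concatenation_layout(self):
        h = np.arange(12, dtype=float).reshape(3, 4)
        fused = bidirectional_fuse(h, np.zeros_like(h))
        assert fused.shape == (3, 8)
        np.testing.assert_array_equal(fused[:, :4], h)
        assert (fused[:, 4:] == 0).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(AssemblyError):
            bidirectional_fuse(np.zeros((3, 4)), np.zeros((2, 4)))

    def test_palindrome_with_shared_weights(self):
        """On a time-palindromic input with shared weights, the backward
        stream is the time-reversed forward stream."""
        rng = np.random.default_rng(11)
        p = random_params(rng, 4)
        half = rng.standard_normal((3, 1, 4)).astype(np.float32)
        seq = np.concatenate([half, half[::-1]])     # palindrome, T=6
        fwd = run_convlstm(seq, p, "forward")
        bwd = run_convlstm(seq, p, "backward")
        np.testing.assert_allclose(bwd, fwd[::-1], atol=1e-7)


class TestAttention:
    def params(self, rng, width=4, d_k=3):
        return AttentionParams(
            w_w=rng.standard_normal((width, d_k)).astype(np.float32),
            b_w=rng.standard_normal(d_k).astype(np.float32),
            z_w=rng.standard_normal(d_k).astype(np.float32))

    def test_identical_states_get_uniform_weights(self):
        rng = np.random.default_rng(12)
        p = self.params(rng)
        h = rng.standard_normal(4).astype(np.float32)
        seq = np.tile(h, (5, 1))
        y, a = attention_pool(seq, p)
        np.testing.assert_allclose(a, np.full(5, 0.2), atol=1e-7)
        np.testing.assert_allclose(y, h, atol=1e-6)

    def test_single_step(self):
        rng = np.random.default_rng(13)
        p = self.params(rng)
        h = rng.standard_normal((1, 4)).astype(np.float32)
        y, a = attention_pool(h, p)
        np.testing.assert_allclose(a, [1.0], atol=1e-7)
        np.testing.assert_allclose(y, h[0], atol=1e-7)

    def test_matches_brute_force_softmax(self):
        """Three steps, pencil-sized dims: keys, scores, softmax and the
        weighted sum evaluated directly with numpy."""
        rng = np.random.default_rng(14)
        p = self.params(rng, width=3, d_k=2)
        h = rng.standard_normal((3, 3)).astype(np.float32)
        y, a = attention_pool(h, p)
        keys = np.tanh(h.astype(np.float64) @ p.w_w + p.b_w)
        scores = keys @ p.z_w
        e = np.exp(scores - scores.max())
        a_ref = e / e.sum()
        y_ref = (a_ref[:, None] * h).sum(axis=0)
        np.testing.assert_allclose(a, a_ref, atol=1e-6)
        np.testing.assert_allclose(y, y_ref, atol=1e-6)

    def test_dominant_score_concentrates_mass(self):
        width, d_k = 2, 2
        p = AttentionParams(w_w=np.eye(2, dtype=np.float32) * 5,
                            b_w=np.zeros(2, np.float32),
                            z_w=np.array([5.0, 0.0], np.float32))
        h = np.array([[1.0, 0.0], [-1.0, 0.0], [-1.0, 0.0]], np.float32)
        y, a = attention_pool(h, p)
        assert a[0] > 0.98
        assert y[0] == pytest.approx(1.0, abs=0.1)

    def test_weights_conserve_and_output_in_hull(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            t, width = int(rng.integers(1, 9)), int(rng.integers(2, 7))
            p = self.params(rng, width=width, d_k=3)
            h = rng.standard_normal((t, width)).astype(np.float32)
            y, a = attention_pool(h, p)
            assert abs(a.sum() - 1.0) < 1e-6
            assert (a > 0).all()
            assert (y >= h.min(axis=0) - 1e-6).all()
            assert (y <= h.max(axis=0) + 1e-6).all()


class TestFullModel:
    def test_probability_outputs(self, small_model, rng):
        x = rng.standard_normal((8, 1, 8, 500)).astype(np.float32)
        probs = small_model.eval().predict_proba(x)
        assert probs.shape == (8, 4)
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(8), atol=1e-6)
        assert (probs >= 0).all()

    def test_default_model_hits_published_parameter_total(self):
        assert build_model().count_parameters() == 17972

    def test_ablated_head_still_emits_probabilities(self, small_model_cfg, rng):
        cfg = ModelConfig(**{**small_model_cfg.__dict__, "use_recurrent_head": False})
        model = DSCConvLSTM(cfg).eval()
        probs = model.predict_proba(rng.standard_normal((3, 1, 8, 500)).astype(np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(3), atol=1e-6)

    def test_attention_ablation_uses_temporal_mean(self, small_model_cfg, rng):
        cfg = ModelConfig(**{**small_model_cfg.__dict__, "use_attention": False})
        model = DSCConvLSTM(cfg).eval()
        probs = model.predict_proba(rng.standard_normal((3, 1, 8, 500)).astype(np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), np.ones(3), atol=1e-6)

    def test_eval_forward_is_deterministic(self, small_model, rng):
        x = rng.standard_normal((4, 1, 8, 500)).astype(np.float32)
        small_model.eval()
        np.testing.assert_array_equal(small_model.predict_proba(x),
                                      small_model.predict_proba(x))

    def test_checkpoint_round_trip(self, small_model, tmp_path, rng):
        x = rng.standard_normal((3, 1, 8, 500)).astype(np.float32)
        small_model.eval()
        before = small_model.predict_proba(x)
        path = tmp_path / "model.npz"
        save_checkpoint(small_model, path)
        restored = load_checkpoint(path).eval()
        np.testing.assert_array_equal(before, restored.predict_proba(x))
        assert restored.cfg.to_dict() == small_model.cfg.to_dict()
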