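"""Window partitioning, Q/K/V construction, attention semantics and fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invadenet.fwam import (
    AttentionConfig,
    FusedWindowTransformer,
    WindowConfigError,
    WindowSpec,
    build_qkv,
    fuse_windows,
    partition_windows,
    window_attention,
)
from invadenet.nn import softmax


class TestWindowSpec:
    def test_default_geometry_gives_nine_windows(self):
        spec = WindowSpec(window=64, stride=48, fringe=8, n_tokens=448)
        assert spec.n_windows == 9

    def test_whole_sequence_window_is_degenerate_single(self):
        spec = WindowSpec(window=448, stride=13, fringe=0, n_tokens=448)
        assert spec.n_windows == 1

    def test_non_integral_window_count_rejected(self):
        with pytest.raises(WindowConfigError):
            WindowSpec(window=64, stride=47, fringe=8, n_tokens=448)

    @given(
        w=st.integers(1, 64),
        s=st.integers(1, 64),
        t=st.integers(8, 256),
    )
    @settings(max_examples=200, deadline=None)
    def test_window_count_formula_or_rejection(self, w, s, t):
        """F = (T - W)/S + 1 whenever integral; explicit error otherwise."""
        if w > t:
            with pytest.raises(WindowConfigError):
                WindowSpec(window=w, stride=s, fringe=0, n_tokens=t)
        elif (t - w) % s == 0:
            spec = WindowSpec(window=w, stride=s, fringe=0, n_tokens=t)
            assert spec.n_windows == (t - w) // s + 1
            # windows tile the sequence: base indices stay in bounds
            idx = spec.base_indices()
            assert idx.min() == 0 and idx.max() == t - 1
        else:
            with pytest.raises(WindowConfigError):
                WindowSpec(window=w, stride=s, fringe=0, n_tokens=t)

    def test_every_token_covered_under_default_spec(self):
        spec = WindowSpec(window=64, stride=48, fringe=8, n_tokens=448)
        covered = np.zeros(448, bool)
        covered[spec.base_indices().ravel()] = True
        left, right = spec.fringe_indices()
        covered[left.ravel()] = True
        covered[right.ravel()] = True
        assert covered.all()


class TestPartition:
    def test_window_contents_and_edge_clamping(self, rng):
        seq = rng.standard_normal((20, 4))
        spec = WindowSpec(window=8, stride=6, fringe=2, n_tokens=20)
        wins = partition_windows(seq, spec)
        assert len(wins) == 3
        assert np.array_equal(wins[0].base, seq[0:8])
        assert np.array_equal(wins[1].base, seq[6:14])
        # left fringe of the first window clamps to the sequence edge
        assert np.array_equal(wins[0].left_fringe, seq[[0, 0]])
        assert np.array_equal(wins[2].right_fringe, seq[[19, 19]])

    def test_length_mismatch_rejected(self, rng):
        spec = WindowSpec(window=8, stride=6, fringe=2, n_tokens=20)
        with pytest.raises(ValueError):
            partition_windows(rng.standard_normal((21, 4)), spec)


class TestBuildQKV:
    def test_row_counts(self, rng):
        n = 784
        seq = rng.standard_normal((448, n))
        spec = WindowSpec(window=64, stride=48, fringe=8, n_tokens=448)
        win = partition_windows(seq, spec)[0]
        w_q, w_k = rng.standard_normal((n, n)), rng.standard_normal((n, n))
        q, k, v = build_qkv(win, w_q, w_k)
        assert q.shape == (65, n)
        assert k.shape == v.shape == (81, n)
        assert np.array_equal(k, v)  # shared projection per construction

    def test_zero_fringe_makes_rows_match(self, rng):
        seq = rng.standard_normal((20, 8))
        spec = WindowSpec(window=8, stride=6, fringe=0, n_tokens=20)
        win = partition_windows(seq, spec)[0]
        eye = np.eye(8)
        q, k, _ = build_qkv(win, eye, eye)
        assert q.shape == k.shape

    def test_identity_projection_zero_context_recovers_base(self, rng):
        seq = rng.standard_normal((20, 8))
        spec = WindowSpec(window=8, stride=6, fringe=2, n_tokens=20)
        win = partition_windows(seq, spec)[1]
        eye = np.eye(8)
        q, _, _ = build_qkv(win, eye, eye)
        assert np.allclose(q[1:], win.base)


class TestWindowAttention:
    CFG = AttentionConfig(n_heads=2, depth=1, feature_dim=8, ffn_expansion=2)

    def test_rows_are_convex_combinations(self, rng):
        q = rng.standard_normal((5, 8))
        kv = np.tile(rng.standard_normal(8), (7, 1))
        out = window_attention(q, kv, kv, self.CFG)
        assert np.allclose(out, kv[0])  # identical V rows: output equals v

    def test_matches_dense_attention_oracle(self, rng):
        """Single whole-sequence window, zero fringe, reference formula."""
        q = rng.standard_normal((16, 8))
        k = rng.standard_normal((16, 8))
        cfg = AttentionConfig(n_heads=1, depth=1, feature_dim=8, ffn_expansion=2)
        out = window_attention(q, k, k, cfg)
        scores = q @ k.T / np.sqrt(8)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        assert np.abs(out - p @ k).max() < 1e-5

    def test_raw_di_scaling_divides_by_dimension(self, rng):
        q = rng.standard_normal((4, 8))
        k = rng.standard_normal((6, 8))
        cfg = AttentionConfig(n_heads=1, depth=1, feature_dim=8,
                              raw_di_scaling=True)
        out = window_attention(q, k, k, cfg)
        p = softmax(q @ k.T / 8.0)
        assert np.allclose(out, p @ k)

    def test_nonfinite_rejected(self):
        bad = np.full((3, 8), np.inf)
        with pytest.raises(ValueError):
            window_attention(bad, bad, bad, self.CFG)


class TestFuseWindows:
    def test_hand_mean(self):
        fused = fuse_windows(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert np.allclose(fused.fo, [1.0, 1.0])

    def test_equal_windows_fuse_to_themselves(self, rng):
        c = rng.standard_normal(8)
        fused = fuse_windows(np.tile(c, (5, 1)))
        assert np.allclose(fused.fo, c)

    def test_order_invariance(self, rng):
        cs = rng.standard_normal((6, 8))
        a = fuse_windows(cs)
        b = fuse_windows(cs[::-1])
        assert np.allclose(a.fo, b.fo)
        assert np.allclose(a.fo_norm, b.fo_norm)

    def test_normalized_output_standardized(self, rng):
        fused = fuse_windows(rng.standard_normal((5, 64)))
        assert abs(fused.fo_norm.mean()) < 1e-10
        assert abs(fused.fo_norm.std() - 1.0) < 1e-3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fuse_windows(np.zeros((0, 8)))


class TestFusedWindowTransformer:
    SPEC = WindowSpec(window=8, stride=6, fringe=2, n_tokens=20)
    CFG = AttentionConfig(n_heads=2, depth=2, feature_dim=12, ffn_expansion=2)

    def _model(self, dtype=np.float64):
        return FusedWindowTransformer(self.SPEC, self.CFG,
                                      np.random.default_rng(0), dtype)

    def test_deterministic_under_fixed_weights(self, rng):
        m = self._model()
        x = rng.standard_normal((2, 20, 12))
        assert np.array_equal(m.forward(x), m.forward(x))

    def test_output_dimension_contract(self, rng):
        out = self._model().forward(rng.standard_normal((3, 20, 12)))
        assert out.shape == (3, 12)

    def test_context_token_receives_gradient(self, rng):
        """The shared auxiliary/context token is genuinely learnable."""
        m = self._model()
        x = rng.standard_normal((2, 20, 12))
        out = m.forward(x)
        m.zero_grad()
        m.backward(np.ones_like(out))
        assert np.abs(m.context_token.grad).max() > 0

    def test_single_window_matches_dense_attention(self, rng):
        """One window covering the whole sequence with L=0: the first
        block's attention equals brute-force dense attention with the
        context token prepended."""
        spec = WindowSpec(window=16, stride=5, fringe=0, n_tokens=16)
        cfg = AttentionConfig(n_heads=1, depth=1, feature_dim=8, ffn_expansion=2)
        m = FusedWindowTransformer(spec, cfg, np.random.default_rng(1), np.float64)
        x = rng.standard_normal((1, 16, 8))
        m.forward(x)
        block = m.blocks[0]
        # oracle: rows = [context ; ln(x)] with the block's own projections
        z = np.concatenate([np.broadcast_to(m.context_token.value, (1, 8)),
                            x[0]], axis=0)
        mean = z.mean(-1, keepdims=True)
        zn = (z - mean) / np.sqrt(z.var(-1, keepdims=True) + 1e-5)
        q = zn @ block.mha.w_q.weight.value.T + block.mha.w_q.bias.value
        kv = zn @ block.mha.w_kv.weight.value.T + block.mha.w_kv.bias.value
        scores = q @ kv.T / np.sqrt(8)
        e = np.exp(scores - scores.max(1, keepdims=True))
        p = e / e.sum(1, keepdims=True)
        oracle = p @ kv
        got = block.mha.last_attention[0, 0] @ kv
        assert np.abs(got - oracle).max() < 1e-5

    def test_gradient_matches_finite_difference(self, rng):
        m = self._model()
        x = rng.standard_normal((1, 20, 12))
        probe = np.random.default_rng(5).standard_normal((1, 12))
        m.zero_grad()
        out = m.forward(x)
        gx = m.backward(probe)
        for idx in [(0, 0, 0), (0, 7, 3), (0, 19, 11)]:
            eps = 1e-6
            orig = x[idx]
            x[idx] = orig + eps
            fp = float((m.forward(x) * probe).sum())
            x[idx] = orig - eps
            fm = float((m.forward(x) * probe).sum())
            x[idx] = orig
            assert abs((fp - fm) / (2 * eps) - gx[idx]) < 1e-6
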