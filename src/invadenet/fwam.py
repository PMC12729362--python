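"""Fused window attention over the token sequence.

The 448-row token matrix is split into F = (T - W)/S + 1 windows of W
tokens with stride S; each window sees a fringe of L neighbouring tokens on
both sides (keys/values only) and a learnable context token shared across
windows at initialization.  Queries are the context token plus the W base
tokens; keys and values are the context token, left fringe, base and right
fringe under a single shared projection.  After multi-head scaled
dot-product attention, per-window context outputs are fused by an
unweighted arithmetic mean followed by layer normalization.

The stand-alone functions (`partition_windows`, `build_qkv`,
`window_attention`, `fuse_windows`) define the per-window semantics on
plain arrays; `FusedWindowTransformer` is the trainable, batched stack of
transformer blocks built on the same construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import LayerNorm, Linear, Module, MultiHeadAttention, Param, ReLU, softmax

__all__ = [
    "WindowSpec",
    "AttentionConfig",
    "WindowTokens",
    "FusedFeature",
    "WindowConfigError",
    "partition_windows",
    "build_qkv",
    "window_attention",
    "fuse_windows",
    "FusedWindowTransformer",
]


class WindowConfigError(ValueError):
    """Window geometry does not tile the sequence exactly."""


@dataclass(frozen=True)
class WindowSpec:
    """Window length W, stride S and per-side fringe length L over a
    sequence of T tokens; the window count F = (T - W)/S + 1 must be
    integral — non-divisible configurations are rejected, never silently
    truncated."""

    window: int
    stride: int
    fringe: int
    n_tokens: int = 448

    def __post_init__(self) -> None:
        if not 1 <= self.window <= self.n_tokens:
            raise WindowConfigError(
                f"window={self.window} outside [1, {self.n_tokens}]"
            )
        if self.stride < 1:
            raise WindowConfigError("stride must be >= 1")
        if self.fringe < 0:
            raise WindowConfigError("fringe must be >= 0")
        if (self.n_tokens - self.window) % self.stride != 0:
            raise WindowConfigError(
                f"(T - W) = {self.n_tokens - self.window} not divisible by "
                f"S = {self.stride}: window count would not be integral"
            )

    @property
    def n_windows(self) -> int:
        return (self.n_tokens - self.window) // self.stride + 1

    def base_indices(self) -> np.ndarray:
        """(F, W) token indices of each window's base."""
        starts = np.arange(self.n_windows) * self.stride
        return starts[:, None] + np.arange(self.window)[None, :]

    def fringe_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(F, L) left and right fringe indices, edge-clamped."""
        starts = np.arange(self.n_windows) * self.stride
        left = starts[:, None] - self.fringe + np.arange(self.fringe)[None, :]
        right = starts[:, None] + self.window + np.arange(self.fringe)[None, :]
        clip = lambda a: np.clip(a, 0, self.n_tokens - 1)
        return clip(left), clip(right)


@dataclass(frozen=True)
class AttentionConfig:
    n_heads: int = 8
    depth: int = 3
    feature_dim: int = 784
    ffn_expansion: int = 6
    raw_di_scaling: bool = False
    learned_window_weights: bool = False

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.feature_dim % self.n_heads:
            raise ValueError(
                f"n_heads={self.n_heads} must divide feature_dim={self.feature_dim}"
            )

    @property
    def d_head(self) -> int:
        return self.feature_dim // self.n_heads


@dataclass
class WindowTokens:
    """One window's token groups: base x_i (W, N), fringes a_i/b_i (L, N),
    context c_i (1, N)."""

    base: np.ndarray
    left_fringe: np.ndarray
    right_fringe: np.ndarray
    context: np.ndarray
    base_indices: np.ndarray


def partition_windows(
    seq: np.ndarray, spec: WindowSpec, context: np.ndarray | None = None
) -> list[WindowTokens]:
    """Split a (T, N) token matrix into F windows with edge-clamped fringes.

    ``context`` (1, N) is the shared learnable context/auxiliary vector; it
    defaults to zeros for inspection purposes.
    """
    seq = np.asarray(seq)
    if seq.ndim != 2:
        raise ValueError(f"expected (T, N) tokens, got {seq.shape}")
    if seq.shape[0] != spec.n_tokens:
        raise ValueError(
            f"sequence length {seq.shape[0]} != spec.n_tokens {spec.n_tokens}"
        )
    n = seq.shape[1]
    ctx = np.zeros((1, n), seq.dtype) if context is None else np.asarray(context).reshape(1, n)
    base_idx = spec.base_indices()
    left_idx, right_idx = spec.fringe_indices()
    return [
        WindowTokens(
            base=seq[base_idx[i]],
            left_fringe=seq[left_idx[i]],
            right_fringe=seq[right_idx[i]],
            context=ctx.copy(),
            base_indices=base_idx[i],
        )
        for i in range(spec.n_windows)
    ]


def build_qkv(
    win: WindowTokens, w_q: np.ndarray, w_k: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Q from {c_i, x_i} (1+W rows); K = V from {c_i, a_i, x_i, b_i}
    (1+W+2L rows), sharing one projection."""
    rows_q = np.vstack([win.context, win.base])
    rows_kv = np.vstack([win.context, win.left_fringe, win.base, win.right_fringe])
    q = rows_q @ np.asarray(w_q).T
    kv = rows_kv @ np.asarray(w_k).T
    return q, kv, kv


def window_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, cfg: AttentionConfig
) -> np.ndarray:
    """Multi-head scaled dot-product attention on already-projected rows:
    per head softmax(Q Kᵀ / sqrt(d_i)) V, heads concatenated."""
    for name, a in (("Q", q), ("K", k), ("V", v)):
        if not np.isfinite(a).all():
            raise ValueError(f"non-finite entries in {name}")
    h, d = cfg.n_heads, cfg.d_head
    if q.shape[1] != cfg.feature_dim:
        raise ValueError(f"feature dim {q.shape[1]} != config {cfg.feature_dim}")
    qh = q.reshape(q.shape[0], h, d).transpose(1, 0, 2)
    kh = k.reshape(k.shape[0], h, d).transpose(1, 0, 2)
    vh = v.reshape(v.shape[0], h, d).transpose(1, 0, 2)
    scale = d if cfg.raw_di_scaling else np.sqrt(d)
    p = softmax(qh @ kh.transpose(0, 2, 1) / scale, axis=-1)
    out = p @ vh
    return out.transpose(1, 0, 2).reshape(q.shape[0], h * d)


@dataclass
class FusedFeature:
    """Mean-fused window representation: ``fo`` is the plain arithmetic mean
    of the per-window context outputs (pre-normalization); ``fo_norm`` is the
    layer-normalized variant fed to the classifier head."""

    fo: np.ndarray
    fo_norm: np.ndarray
    per_window: np.ndarray  # (F, N), retained for inspection


def fuse_windows(window_outputs: np.ndarray | list[np.ndarray],
                 eps: float = 1e-5) -> FusedFeature:
    """Unweighted arithmetic mean of the F per-window context vectors,
    followed by (parameter-free) layer normalization."""
    cs = np.asarray(window_outputs, dtype=np.float64)
    if cs.ndim == 1:
        cs = cs[None, :]
    if cs.size == 0 or cs.shape[0] == 0:
        raise ValueError("empty window list")
    fo = cs.mean(axis=0)
    fo_norm = (fo - fo.mean()) / np.sqrt(fo.var() + eps)
    return FusedFeature(fo=fo, fo_norm=fo_norm, per_window=cs)


def _scatter_add(acc: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """acc (B, T, N) += vals (B, F, K, N) at token positions idx (F, K)."""
    b, t, n = acc.shape
    f, k = idx.shape
    flat = vals.transpose(1, 2, 0, 3).reshape(f * k, b, n)
    tmp = np.zeros((t, b, n), dtype=acc.dtype)
    np.add.at(tmp, idx.ravel(), flat)
    acc += tmp.transpose(1, 0, 2)


class _Block(Module):
    """Pre-norm transformer block with fringe-window attention, residuals
    and a two-layer feed-forward network."""

    def __init__(self, spec: WindowSpec, cfg: AttentionConfig,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        n = cfg.feature_dim
        self.spec = spec
        self.ln1 = LayerNorm(n, dtype=dtype)
        self.mha = MultiHeadAttention(n, cfg.n_heads, cfg.raw_di_scaling, rng, dtype)
        self.ln2 = LayerNorm(n, dtype=dtype)
        self.ffn1 = Linear(n, cfg.ffn_expansion * n, rng=rng, dtype=dtype)
        self.ffn_act = ReLU()
        self.ffn2 = Linear(cfg.ffn_expansion * n, n, rng=rng, dtype=dtype)
        self.base_idx = spec.base_indices()
        self.left_idx, self.right_idx = spec.fringe_indices()
        counts = np.bincount(self.base_idx.ravel(), minlength=spec.n_tokens)
        self._counts = np.maximum(counts, 1)[None, :, None]
        self._covered = (counts > 0)[None, :, None]

    def forward(self, seq: np.ndarray, ctx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, t, n = seq.shape
        f, w = self.base_idx.shape
        l = self.spec.fringe
        z = np.concatenate([ctx, seq], axis=1)
        zn = self.ln1(z)
        cn, sn = zn[:, :f], zn[:, f:]
        q_in = np.concatenate([cn[:, :, None, :], sn[:, self.base_idx]], axis=2)
        kv_parts = [cn[:, :, None, :]]
        if l > 0:
            kv_parts.append(sn[:, self.left_idx])
        kv_parts.append(sn[:, self.base_idx])
        if l > 0:
            kv_parts.append(sn[:, self.right_idx])
        kv_in = np.concatenate(kv_parts, axis=2)
        out = self.mha(q_in.reshape(b * f, 1 + w, n), kv_in.reshape(b * f, -1, n))
        out = out.reshape(b, f, 1 + w, n)
        ctx_att = ctx + out[:, :, 0]
        acc = np.zeros_like(seq)
        _scatter_add(acc, self.base_idx, out[:, :, 1:])
        seq_att = seq + np.where(self._covered, acc / self._counts, 0.0)
        z2 = np.concatenate([ctx_att, seq_att], axis=1)
        z2n = self.ln2(z2)
        ff = self.ffn2(self.ffn_act(self.ffn1(z2n)))
        z3 = z2 + ff
        return z3[:, f:], z3[:, :f]

    def backward(self, gseq: np.ndarray, gctx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b, t, n = gseq.shape
        f, w = self.base_idx.shape
        l = self.spec.fringe
        gz3 = np.concatenate([gctx, gseq], axis=1)
        gz2 = gz3 + self.ln2.backward(
            self.ffn1.backward(self.ffn_act.backward(self.ffn2.backward(gz3)))
        )
        gctx2, gseq2 = gz2[:, :f], gz2[:, f:]
        # attention residual
        gacc = np.where(self._covered, gseq2 / self._counts, 0.0)
        gout_base = gacc[:, self.base_idx]  # gather (B, F, W, N)
        gout = np.concatenate([gctx2[:, :, None, :], gout_base], axis=2)
        gq_in, gkv_in = self.mha.backward(gout.reshape(b * f, 1 + w, n))
        gq_in = gq_in.reshape(b, f, 1 + w, n)
        gkv_in = gkv_in.reshape(b, f, -1, n)
        gcn = gq_in[:, :, 0] + gkv_in[:, :, 0]
        gsn = np.zeros((b, t, n), dtype=gseq.dtype)
        _scatter_add(gsn, self.base_idx, gq_in[:, :, 1:])
        pos = 1
        if l > 0:
            _scatter_add(gsn, self.left_idx, gkv_in[:, :, pos : pos + l])
            pos += l
        _scatter_add(gsn, self.base_idx, gkv_in[:, :, pos : pos + w])
        pos += w
        if l > 0:
            _scatter_add(gsn, self.right_idx, gkv_in[:, :, pos : pos + l])
        gz1 = self.ln1.backward(np.concatenate([gcn, gsn], axis=1))
        return gseq2 + gz1[:, f:], gctx2 + gz1[:, :f]


class FusedWindowTransformer(Module):
    """Depth-many fringe-window attention blocks over a (B, T, N) token
    batch, fused to a single (B, N) feature by averaging the per-window
    context outputs and layer-normalizing."""

    def __init__(self, spec: WindowSpec, cfg: AttentionConfig,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.cfg = cfg
        n = cfg.feature_dim
        # shared learnable context/auxiliary token, instantiated per window
        self.context_token = Param(
            (rng.standard_normal((1, n)) * 0.02).astype(dtype), "fwam.context_token"
        )
        self.blocks = [_Block(spec, cfg, rng, dtype) for _ in range(cfg.depth)]
        self.ln_out = LayerNorm(n, dtype=dtype)
        if cfg.learned_window_weights:
            self.window_logits = Param(
                np.zeros(spec.n_windows, dtype=dtype), "fwam.window_logits"
            )
        else:
            self.window_logits = None
        self.last_per_window: np.ndarray | None = None
        self._cache = None

    def forward(self, seq: np.ndarray) -> np.ndarray:
        if seq.ndim != 3:
            raise ValueError(f"expected (B, T, N), got {seq.shape}")
        b = seq.shape[0]
        f = self.spec.n_windows
        ctx = np.broadcast_to(
            self.context_token.value[None], (b, f, self.cfg.feature_dim)
        ).astype(seq.dtype)
        for block in self.blocks:
            seq, ctx = block(seq, ctx)
        self.last_per_window = ctx
        if self.window_logits is not None:
            wts = softmax(self.window_logits.value)
            fo = np.einsum("bfn,f->bn", ctx, wts)
            self._cache = (ctx, wts, b, f)
        else:
            fo = ctx.mean(axis=1)
            self._cache = (None, None, b, f)
        return self.ln_out(fo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        ctx_cache, wts, b, f = self._cache
        gfo = self.ln_out.backward(gout)
        if self.window_logits is not None:
            gctx = gfo[:, None, :] * wts[None, :, None]
            raw = np.einsum("bfn,bn->f", ctx_cache, gfo)
            self.window_logits.grad += wts * (raw - (raw * wts).sum())
        else:
            gctx = np.broadcast_to(gfo[:, None, :] / f, (b, f, gfo.shape[-1])).astype(gout.dtype)
            gctx = np.ascontiguousarray(gctx)
        # only the context path feeds the fused output; the sequence output
        # of the last block is unused downstream, so its gradient starts at 0
        gseq = np.zeros((b, self.spec.n_tokens, self.cfg.feature_dim), dtype=gout.dtype)
        for block in reversed(self.blocks):
            gseq, gctx = block.backward(gseq, gctx)
        self.context_token.grad += gctx.sum(axis=(0, 1))
        self._cache = None
        return gseq
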