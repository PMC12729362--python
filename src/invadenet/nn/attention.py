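"""Multi-head scaled dot-product attention with a shared key/value projection.

The attention used by the window module projects queries with ``W_q`` and
keys with ``W_k``; the value rows are the *same* projected tensor as the
keys (K = V), which is how the classifier's window attention is defined.
A standard output projection mixes the heads back to the model width.
"""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import Linear

__all__ = ["MultiHeadAttention", "softmax"]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Module):
    """attn(Q, K, V) = softmax(Q Kᵀ / scale) V, per head, heads concatenated.

    ``scale`` is sqrt(d_head) by default; with ``raw_d_scaling`` the scores
    are divided by d_head itself (the literal printed form of the scaled
    dot-product used by the source model).
    """

    def __init__(
        self,
        dim: int,
        n_heads: int,
        raw_d_scaling: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        if dim % n_heads:
            raise ValueError(f"n_heads={n_heads} must divide feature dim={dim}")
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.raw_d_scaling = raw_d_scaling
        self.w_q = Linear(dim, dim, rng=rng, dtype=dtype)
        self.w_kv = Linear(dim, dim, rng=rng, dtype=dtype)  # shared K = V projection
        self.w_out = Linear(dim, dim, rng=rng, dtype=dtype)
        self.last_attention: np.ndarray | None = None
        self._cache = None

    @property
    def scale(self) -> float:
        return float(self.d_head if self.raw_d_scaling else np.sqrt(self.d_head))

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, n, _ = x.shape
        return x.reshape(b, n, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, n, d = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(b, n, h * d)

    def forward(self, q_in: np.ndarray, kv_in: np.ndarray) -> np.ndarray:
        """q_in: (B, n_q, dim); kv_in: (B, n_kv, dim) -> (B, n_q, dim)."""
        if not (np.isfinite(q_in).all() and np.isfinite(kv_in).all()):
            raise ValueError("non-finite attention inputs")
        q = self._split(self.w_q(q_in))           # (B, h, nq, dh)
        kv = self._split(self.w_kv(kv_in))        # (B, h, nk, dh)
        scores = q @ kv.transpose(0, 1, 3, 2) / self.scale
        p = softmax(scores, axis=-1)              # (B, h, nq, nk)
        ctx = p @ kv                              # values are the K=V tensor
        out = self.w_out(self._merge(ctx))
        self.last_attention = p
        self._cache = (q, kv, p)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        """Returns (d q_in, d kv_in)."""
        q, kv, p = self._cache
        dctx_m = self.w_out.backward(gout)
        dctx = self._split(dctx_m)                # (B, h, nq, dh)
        dp = dctx @ kv.transpose(0, 1, 3, 2)      # (B, h, nq, nk)
        dkv_from_v = p.transpose(0, 1, 3, 2) @ dctx
        # softmax backward per row
        dscores = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
        dscores /= self.scale
        dq = dscores @ kv
        dkv_from_k = dscores.transpose(0, 1, 3, 2) @ q
        dq_in = self.w_q.backward(self._merge(dq))
        dkv_in = self.w_kv.backward(self._merge(dkv_from_k + dkv_from_v))
        self._cache = None
        return dq_in, dkv_in
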