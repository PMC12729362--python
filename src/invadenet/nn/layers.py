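"""Layers used by the invasion classifier: 3D convolution (standard,
depthwise and pointwise via ``groups``), batch/layer normalization, spatial
max-pooling, ReLU and dense projections.

Array layout for volumetric data is ``(batch, channel, phase, height,
width)``; the phase axis plays the role of depth so 3D kernels span the
contrast-enhancement time course.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Param, fan_in_normal

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "MaxPoolHW",
    "ReLU",
    "Linear",
    "LayerNorm",
    "set_training",
]


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected int or length-3 tuple, got {v!r}")
    return t


class Conv3d(Module):
    """3D convolution over (phase, height, width) via im2col + GEMM.

    ``groups=1`` is a dense convolution; ``groups=in_channels`` (with
    ``out_channels == in_channels``) is a depthwise convolution.  Padding
    defaults to "same" for stride 1 (odd kernels).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding="same",
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        if padding == "same":
            self.padding = tuple(k // 2 for k in self.kernel)
        else:
            self.padding = _triple(padding)
        if groups != 1:
            if groups != in_channels:
                raise ValueError("groups must be 1 (dense) or in_channels (depthwise)")
            if out_channels != in_channels:
                raise ValueError("depthwise convolution requires out == in channels")
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        kd, kh, kw = self.kernel
        cin_g = in_channels // groups
        fan_in = cin_g * kd * kh * kw
        self.weight = Param(
            fan_in_normal(rng, (out_channels, cin_g, kd, kh, kw), fan_in, dtype),
            "conv.weight",
        )
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "conv.bias") if bias else None
        #: first-layer convolutions may skip the input gradient entirely
        self.input_grad = True
        self._cache = None

    # -- helpers -----------------------------------------------------------
    def _im2col(self, x: np.ndarray) -> np.ndarray:
        pd, ph, pw = self.padding
        sd, sh, sw = self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        cols = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        return cols[:, :, ::sd, ::sh, ::sw], xp.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N,{self.in_channels},D,H,W) input, got {x.shape}"
            )
        cols, xp_shape = self._im2col(x)
        n, _, do, ho, wo = cols.shape[:5]
        kd, kh, kw = self.kernel
        if self.groups == 1:
            k3 = self.in_channels * kd * kh * kw
            cols_m = np.ascontiguousarray(
                cols.transpose(0, 2, 3, 4, 1, 5, 6, 7)
            ).reshape(n * do * ho * wo, k3)
            wm = self.weight.value.reshape(self.out_channels, k3)
            out = cols_m @ wm.T
            out = out.reshape(n, do, ho, wo, self.out_channels).transpose(0, 4, 1, 2, 3)
            self._cache = (cols_m, x.shape, xp_shape, (n, do, ho, wo))
        else:  # depthwise
            w = self.weight.value[:, 0]
            out = np.einsum("ncdhwxyz,cxyz->ncdhw", cols, w, optimize=True)
            self._cache = (cols, x.shape, xp_shape, (n, do, ho, wo))
        if self.bias is not None:
            out += self.bias.value.reshape(1, -1, 1, 1, 1)
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cache, x_shape, xp_shape, (n, do, ho, wo) = self._cache
        kd, kh, kw = self.kernel
        sd, sh, sw = self.stride
        pd, ph, pw = self.padding
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=(0, 2, 3, 4))
        if self.groups == 1:
            cols_m = cache
            k3 = self.in_channels * kd * kh * kw
            g_m = np.ascontiguousarray(gout.transpose(0, 2, 3, 4, 1)).reshape(
                n * do * ho * wo, self.out_channels
            )
            self.weight.grad += (g_m.T @ cols_m).reshape(self.weight.value.shape)
            if not self.input_grad:
                self._cache = None
                return None
            dcols_m = g_m @ self.weight.value.reshape(self.out_channels, k3)
            dcols = dcols_m.reshape(n, do, ho, wo, self.in_channels, kd, kh, kw)
            dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
        else:
            cols = cache
            w = self.weight.value[:, 0]
            self.weight.grad[:, 0] += np.einsum(
                "ncdhw,ncdhwxyz->cxyz", gout, cols, optimize=True
            )
            if not self.input_grad:
                self._cache = None
                return None
            dcols = np.einsum("ncdhw,cxyz->ncdhwxyz", gout, w, optimize=True)
        # col2im scatter-add over kernel offsets
        dxp = np.zeros(xp_shape, dtype=gout.dtype)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    dxp[
                        :,
                        :,
                        i : i + sd * do : sd,
                        j : j + sh * ho : sh,
                        k : k + sw * wo : sw,
                    ] += dcols[:, :, :, :, :, i, j, k]
        d, h, w_ = x_shape[2:]
        self._cache = None
        return dxp[:, :, pd : pd + d, ph : ph + h, pw : pw + w_]


class BatchNorm3d(Module):
    """Per-channel batch normalization over (batch, phase, height, width)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.training = True
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(1, -1, 1, 1, 1)) * inv.reshape(1, -1, 1, 1, 1)
        out = self.gamma.value.reshape(1, -1, 1, 1, 1) * xhat
        out += self.beta.value.reshape(1, -1, 1, 1, 1)
        self._cache = (xhat, inv, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        axes = (0, 2, 3, 4)
        m = gout.shape[0] * gout.shape[2] * gout.shape[3] * gout.shape[4]
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = self.gamma.value.reshape(1, -1, 1, 1, 1)
        if not self.training:
            self._cache = None
            return gout * g * inv.reshape(1, -1, 1, 1, 1)
        dxhat = gout * g
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = inv.reshape(1, -1, 1, 1, 1) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._cache = None
        return dx


class MaxPoolHW(Module):
    """Non-overlapping 2x2 max pool over the two spatial axes only.

    The phase axis is left intact so temporal resolution survives until the
    token reshape.  Ties share the gradient equally (a valid subgradient).
    """

    def __init__(self, factor: int = 2) -> None:
        self.factor = factor
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.factor
        n, c, d, h, w = x.shape
        if h % f or w % f:
            raise ValueError(f"spatial dims {h}x{w} not divisible by pool {f}")
        xr = x.reshape(n, c, d, h // f, f, w // f, f)
        out = xr.max(axis=(4, 6))
        mask = xr == out[:, :, :, :, None, :, None]
        counts = mask.sum(axis=(4, 6), keepdims=True)
        self._cache = (mask, counts, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        mask, counts, shape = self._cache
        g = gout[:, :, :, :, None, :, None] * mask / counts
        self._cache = None
        return g.reshape(shape)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout * self._mask
        self._mask = None
        return g


class Linear(Module):
    """Dense projection applied to the last axis."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(
            fan_in_normal(rng, (out_features, in_features), in_features, dtype),
            "linear.weight",
        )
        self.bias = Param(np.zeros(out_features, dtype=dtype), "linear.bias") if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        y = x @ self.weight.value.T
        if self.bias is not None:
            y += self.bias.value
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        gm = gout.reshape(-1, self.out_features)
        xm = x.reshape(-1, self.in_features)
        self.weight.grad += gm.T @ xm
        if self.bias is not None:
            self.bias.grad += gm.sum(axis=0)
        self._cache = None
        return gout @ self.weight.value


class LayerNorm(Module):
    """Normalization over the last (feature) axis with learnable scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32) -> None:
        self.dim = dim
        self.eps = eps
        self.gamma = Param(np.ones(dim, dtype=dtype), "ln.gamma")
        self.beta = Param(np.zeros(dim, dtype=dtype), "ln.beta")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        axes = tuple(range(gout.ndim - 1))
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        dxhat = gout * self.gamma.value
        mean_dxhat = dxhat.mean(axis=-1, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=-1, keepdims=True)
        self._cache = None
        return inv * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


def set_training(module: Module, flag: bool) -> None:
    """Recursively toggle train/eval behaviour (batch-norm statistics)."""
    stack = [module]
    seen: set[int] = set()
    while stack:
        mod = stack.pop()
        if id(mod) in seen:
            continue
        seen.add(id(mod))
        if hasattr(mod, "training"):
            mod.training = flag
        for attr in mod.__dict__.values():
            if isinstance(attr, Module):
                stack.append(attr)
            elif isinstance(attr, (list, tuple)):
                stack.extend(a for a in attr if isinstance(a, Module))
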