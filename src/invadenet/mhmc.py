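"""Multiscale 3D convolution token extractor.

Three parallel dual-layer convolution branches with cubic kernels 1, 3 and 5
read the (224, 224, 5) phase stack and emit token rows at three receptive
fields.  Per branch: layer 1 is a standard 3D convolution + batch norm +
ReLU + 2x2 spatial max-pool; layer 2 is a depthwise 3D convolution with
spatial stride 2 followed by a 1x1x1 pointwise convolution (+ batch norm +
ReLU) and a second 2x2 max-pool — a x8 spatial reduction, 224 -> 28, so
each token carries 28*28 = 784 features.  Kernels span the phase axis (zero
padded), the temporal extent survives both layers (Grad-CAM slices it), and
is collapsed by a mean at the final reshape; the token rows of a branch are
its layer-2 output channels.  Branch outputs are concatenated along the
token axis in kernel order (1, 3, 5): 64 + 128 + 256 = 448 tokens by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BatchNorm3d, Conv3d, MaxPoolHW, Module, ReLU

__all__ = [
    "BranchConfig",
    "TokenSequence",
    "TokenBranch",
    "MultiScaleTokenizer",
    "DEFAULT_BRANCHES",
]


@dataclass(frozen=True)
class BranchConfig:
    """One convolution pathway of the token extractor."""

    kernel_size: int
    mid_channels: int  # layer-1 output channels
    out_tokens: int  # layer-2 output channels == token rows contributed
    spatial_reduction: int = 8
    use_bn2: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size not in (1, 3, 5):
            raise ValueError("kernel_size must be one of {1, 3, 5}")
        if self.out_tokens <= 0 or self.mid_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.spatial_reduction != 8:
            raise ValueError("the two-layer pipeline realizes a fixed x8 reduction")


#: defaults sized so that token rows total 448: larger kernels carry more
#: context channels.
DEFAULT_BRANCHES: tuple[BranchConfig, ...] = (
    BranchConfig(kernel_size=1, mid_channels=16, out_tokens=64),
    BranchConfig(kernel_size=3, mid_channels=32, out_tokens=128),
    BranchConfig(kernel_size=5, mid_channels=64, out_tokens=256),
)


@dataclass
class TokenSequence:
    """A (tokens, features) matrix; the default extractor yields 448 x 784."""

    tokens: np.ndarray

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens)
        if self.tokens.ndim != 2:
            raise ValueError(f"TokenSequence must be 2D, got {self.tokens.shape}")
        if not np.isfinite(self.tokens).all():
            raise ValueError("TokenSequence entries must be finite")

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[0]

    @property
    def n_features(self) -> int:
        return self.tokens.shape[1]


class TokenBranch(Module):
    """One dual-layer 3D convolution pathway: (B, 1, T, H, W) ->
    (B, out_tokens, (H/8)*(W/8))."""

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        self.cfg = cfg
        k = cfg.kernel_size
        self.conv1 = Conv3d(1, cfg.mid_channels, k, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm3d(cfg.mid_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.pool1 = MaxPoolHW()
        self.dwconv = Conv3d(cfg.mid_channels, cfg.mid_channels, k,
                             stride=(1, 2, 2), groups=cfg.mid_channels,
                             rng=rng, dtype=dtype)
        self.pwconv = Conv3d(cfg.mid_channels, cfg.out_tokens, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm3d(cfg.out_tokens, dtype=dtype) if cfg.use_bn2 else None
        self.relu2 = ReLU()
        self.pool2 = MaxPoolHW()
        # Grad-CAM hooks: post-activation layer-2 feature map and its gradient
        self.record_activations = False
        self.last_activation: np.ndarray | None = None
        self.last_activation_grad: np.ndarray | None = None
        self._shape_cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (B, 1, T, H, W), got {x.shape}")
        h = self.pool1(self.relu1(self.bn1(self.conv1(x))))
        h = self.pwconv(self.dwconv(h))
        if self.bn2 is not None:
            h = self.bn2(h)
        h = self.relu2(h)
        if self.record_activations:
            self.last_activation = h.copy()
        h = self.pool2(h)
        b, c, t, hh, ww = h.shape
        self._shape_cache = (b, c, t, hh, ww)
        # collapse the phase axis by a mean, flatten spatial into features
        return h.mean(axis=2).reshape(b, c, hh * ww)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, c, t, hh, ww = self._shape_cache
        g = gout.reshape(b, c, 1, hh, ww) / t
        g = np.broadcast_to(g, (b, c, t, hh, ww)).astype(gout.dtype)
        g = self.pool2.backward(g)
        g = self.relu2.backward(g)
        if self.record_activations:
            self.last_activation_grad = g.copy()
        if self.bn2 is not None:
            g = self.bn2.backward(g)
        g = self.dwconv.backward(self.pwconv.backward(g))
        g = self.bn1.backward(self.relu1.backward(self.pool1.backward(g)))
        return self.conv1.backward(g)  # None when conv1.input_grad is off

    def depthwise_separable_params(self) -> int:
        n = self.dwconv.weight.size + self.pwconv.weight.size
        if self.dwconv.bias is not None:
            n += self.dwconv.bias.size + self.pwconv.bias.size
        return n

    def dense_equivalent_params(self) -> int:
        """Parameter count of the dense 3D convolution layer 2 replaces."""
        k = self.cfg.kernel_size
        return (self.cfg.mid_channels * k**3 + 1) * self.cfg.out_tokens


class MultiScaleTokenizer(Module):
    """Concatenation of the three branch token blocks in kernel order."""

    def __init__(self, branches: tuple[BranchConfig, ...] = DEFAULT_BRANCHES,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng(0)
        self.branches = [TokenBranch(cfg, rng, dtype) for cfg in branches]
        self._split_sizes = [cfg.out_tokens for cfg in branches]

    @property
    def n_tokens(self) -> int:
        return sum(self._split_sizes)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, T, H, W) -> (B, n_tokens, (H/8)*(W/8))."""
        outs = [branch(x) for branch in self.branches]
        dims = {o.shape[2] for o in outs}
        if len(dims) != 1:
            raise ValueError(f"branch feature dims disagree: {dims}")
        return np.concatenate(outs, axis=1)

    @property
    def input_grad(self) -> bool:
        return self.branches[0].conv1.input_grad

    @input_grad.setter
    def input_grad(self, flag: bool) -> None:
        for branch in self.branches:
            branch.conv1.input_grad = flag

    def backward(self, gout: np.ndarray) -> np.ndarray | None:
        gx = None
        start = 0
        for branch, size in zip(self.branches, self._split_sizes):
            g = branch.backward(gout[:, start : start + size])
            if g is not None:
                gx = g if gx is None else gx + g
            start += size
        return gx
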