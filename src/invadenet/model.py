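"""Full invasion classifier: multiscale conv tokenizer -> fused window
attention -> sigmoid head, plus the two single-module ablation variants and
checkpoint plumbing.

The default full-scale configuration reproduces the published architecture
contract — 448 x 784 tokens from a 224 x 224 x 5 input and a trainable
parameter budget of ~27.9 million — while ``desk_model_config`` returns a
structurally identical scaled-down model for phantom-cohort experiments on
a single CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .fwam import AttentionConfig, FusedWindowTransformer, WindowSpec
from .head import ClassifierHead
from .mhmc import DEFAULT_BRANCHES, BranchConfig, MultiScaleTokenizer
from .nn import LayerNorm, Linear, Module, Param, set_training
from .preprocess import phase_projection_matrix

__all__ = [
    "ModelConfig",
    "InvasionNet",
    "default_model_config",
    "desk_model_config",
    "config_hash",
    "save_checkpoint",
    "load_checkpoint",
]

VARIANTS = ("full", "mhmc_only", "fwam_only")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "full"
    input_side: int = 224
    n_phases: int = 5
    branches: tuple[BranchConfig, ...] = DEFAULT_BRANCHES
    window: tuple[int, int, int] = (64, 48, 8)  # (W, S, L)
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    patch_size: int = 56  # tokenizer patch edge for the fwam_only variant
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.input_side % 8:
            raise ValueError("input_side must be divisible by the x8 reduction")
        side = self.input_side // 8
        if self.variant != "fwam_only" and self.attention.feature_dim != side * side:
            raise ValueError(
                f"attention feature_dim {self.attention.feature_dim} != "
                f"(input_side/8)^2 = {side * side}"
            )

    @property
    def n_tokens(self) -> int:
        if self.variant == "fwam_only":
            return self.n_phases * (self.input_side // self.patch_size) ** 2
        return sum(b.out_tokens for b in self.branches)

    @property
    def feature_dim(self) -> int:
        return self.attention.feature_dim

    def window_spec(self) -> WindowSpec:
        w, s, l = self.window
        return WindowSpec(window=w, stride=s, fringe=l, n_tokens=self.n_tokens)


def default_model_config(variant: str = "full", **overrides) -> ModelConfig:
    """Published-scale configuration: 224 input, 448 x 784 tokens, windows
    W=64/S=48/L=8 (9 windows), 3 attention blocks with 8 heads."""
    cfg = ModelConfig(variant=variant)
    if variant == "fwam_only":  # 80 patch tokens need their own window grid
        cfg = replace(cfg, window=(16, 8, 4))
    return replace(cfg, **overrides)


def desk_model_config(variant: str = "full", **overrides) -> ModelConfig:
    """Scaled-down configuration for CPU phantom experiments: 32 x 32 input,
    112 x 16 tokens, 9 windows, 2 attention blocks."""
    cfg = ModelConfig(
        variant=variant,
        input_side=32,
        branches=(
            BranchConfig(kernel_size=1, mid_channels=6, out_tokens=16),
            BranchConfig(kernel_size=3, mid_channels=8, out_tokens=32),
            BranchConfig(kernel_size=5, mid_channels=12, out_tokens=64),
        ),
        window=(16, 12, 4) if variant != "fwam_only" else (16, 8, 4),
        attention=AttentionConfig(n_heads=4, depth=2, feature_dim=16, ffn_expansion=2),
        patch_size=8,
    )
    return replace(cfg, **overrides)


class _PhaseAdapter(Module):
    """Learnable 1x1 projection mapping a deviating phase count onto the
    canonical grid; initialized to linear interpolation over phase
    position."""

    def __init__(self, t_in: int, t_out: int, dtype=np.float32) -> None:
        self.t_in, self.t_out = t_in, t_out
        self.weight = Param(
            phase_projection_matrix(t_in, t_out).astype(dtype), "phase_adapter.weight"
        )
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return np.einsum("st,bcthw->bcshw", self.weight.value, x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += np.einsum("bcshw,bcthw->st", gout, x)
        self._cache = None
        return np.einsum("st,bcshw->bcthw", self.weight.value, gout)


class _PatchTokenizer(Module):
    """ViT-style linear patch embedding used by the attention-only ablation:
    each phase is cut into patch_size^2 patches, flattened and projected to
    the token feature width."""

    def __init__(self, side: int, patch: int, n_phases: int, dim: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if side % patch:
            raise ValueError("patch size must divide the image side")
        self.side, self.patch, self.n_phases = side, patch, n_phases
        self.grid = side // patch
        self.embed = Linear(patch * patch, dim, rng=rng, dtype=dtype)

    def _patchify(self, x: np.ndarray) -> np.ndarray:
        b = x.shape[0]
        g, p = self.grid, self.patch
        xr = x[:, 0].reshape(b, self.n_phases, g, p, g, p)
        return np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)).reshape(
            b, self.n_phases * g * g, p * p
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return self.embed(self._patchify(x))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, _, t, h, w = self._shape
        g, p = self.grid, self.patch
        gp = self.embed.backward(gout)
        gp = gp.reshape(b, t, g, g, p, p).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(gp).reshape(b, 1, t, h, w)


class _MeanPoolAggregator(Module):
    """Token-mean pooling + layer norm, standing in for the attention stack
    in the conv-only ablation."""

    def __init__(self, dim: int, dtype=np.float32) -> None:
        self.ln = LayerNorm(dim, dtype=dtype)
        self._n = None

    def forward(self, seq: np.ndarray) -> np.ndarray:
        self._n = seq.shape[1]
        return self.ln(seq.mean(axis=1))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.ln.backward(gout)
        return np.repeat(g[:, None, :] / self._n, self._n, axis=1)


class InvasionNet(Module):
    """End-to-end classifier mapping a (B, 1, T, H, W) phase-stack batch to
    invasion probabilities (B,)."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        # the 5-point protocol occasionally yields 4 phases; the adapter for
        # that case is a fixed part of the model
        self.phase_adapter = _PhaseAdapter(cfg.n_phases - 1, cfg.n_phases, dtype)
        if cfg.variant == "fwam_only":
            self.tokenizer = _PatchTokenizer(
                cfg.input_side, cfg.patch_size, cfg.n_phases, cfg.feature_dim,
                rng, dtype,
            )
        else:
            self.tokenizer = MultiScaleTokenizer(cfg.branches, rng, dtype)
        if cfg.variant == "mhmc_only":
            self.aggregator = _MeanPoolAggregator(cfg.feature_dim, dtype)
        else:
            self.aggregator = FusedWindowTransformer(
                cfg.window_spec(), cfg.attention, rng, dtype
            )
        self.head = ClassifierHead(cfg.feature_dim, rng=rng, dtype=dtype)
        self._adapted = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 5:
            raise ValueError(f"expected (B, 1, T, H, W), got {x.shape}")
        t = x.shape[2]
        self._adapted = t != self.cfg.n_phases
        if hasattr(self.tokenizer, "input_grad"):
            self.tokenizer.input_grad = self._adapted
        if self._adapted:
            if t != self.phase_adapter.t_in:
                raise ValueError(
                    f"unsupported phase count {t}; adapt with "
                    "preprocess.adapt_phase_count first"
                )
            x = self.phase_adapter(x)
        tokens = self.tokenizer(x)
        fo = self.aggregator(tokens)
        return self.head(fo)

    def backward(self, g_yp: np.ndarray) -> np.ndarray:
        g = self.head.backward(g_yp)
        g = self.aggregator.backward(g)
        g = self.tokenizer.backward(g)
        if self._adapted:
            g = self.phase_adapter.backward(g)
        return g

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        set_training(self, False)
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        set_training(self, True)
        return np.concatenate(out)

    def parameter_count(self) -> int:
        return self.n_params()


def config_hash(cfg: ModelConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(path, model: InvasionNet) -> None:
    """Named weight map stamped with the architecture fingerprint."""
    state = model.state_dict()
    state["__config_hash__"] = np.array(config_hash(model.cfg))
    state["__config_json__"] = np.array(json.dumps(asdict(model.cfg), default=str))
    np.savez(path, **state)


def load_checkpoint(path, model: InvasionNet) -> None:
    """Refuses to load weights produced under a different architecture."""
    with np.load(path, allow_pickle=False) as data:
        stored = str(data["__config_hash__"])
        expect = config_hash(model.cfg)
        if stored != expect:
            raise ValueError(
                f"checkpoint fingerprint {stored} != model config {expect}"
            )
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.load_state_dict(state)
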