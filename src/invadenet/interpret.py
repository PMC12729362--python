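"""Gradient-weighted class activation maps per contrast phase.

Grad-CAM on the token extractor: gradients of the class logit are pooled
over space and phase into per-channel weights, the weighted layer-2
activation map is ReLU-rectified, sliced along the phase axis, bilinearly
upsampled to the input resolution and min-max normalized per phase.  The
per-window attention matrices of the fused-attention stack are exported
alongside for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as sk_resize

from .head import PROB_EPS
from .mhmc import MultiScaleTokenizer
from .model import InvasionNet
from .nn import set_training

__all__ = ["SaliencyMap", "grad_cam", "overlay", "attention_maps"]


@dataclass
class SaliencyMap:
    """One phase's [0, 1] heatmap at input resolution."""

    heatmap: np.ndarray
    target_layer: str
    class_index: int
    phase_index: int

    def __post_init__(self) -> None:
        if self.heatmap.min() < 0 or self.heatmap.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


def _branch_by_kernel(tokenizer: MultiScaleTokenizer, kernel: int):
    for branch in tokenizer.branches:
        if branch.cfg.kernel_size == kernel:
            return branch
    raise ValueError(f"no branch with kernel size {kernel}")


def grad_cam(
    model: InvasionNet,
    sample: np.ndarray,
    branch_kernel: int = 3,
    class_index: int = 1,
    normalize_per_phase: bool = True,
) -> list[SaliencyMap]:
    """Per-phase saliency maps for one (1, T, H, W) or (T, H, W) sample.

    ``class_index`` 1 explains the invasive logit, 0 the non-invasive one
    (negated gradient).  The default target layer is the last convolution
    of the mid-scale (k=3) branch.
    """
    if not isinstance(model.tokenizer, MultiScaleTokenizer):
        raise ValueError("saliency requires the convolutional tokenizer")
    x = np.asarray(sample)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[0] != 1:
        raise ValueError(f"expected one sample (1, T, H, W) or (T, H, W), got {x.shape}")
    x = x[None]  # -> (1, 1, T, H, W)
    branch = _branch_by_kernel(model.tokenizer, branch_kernel)
    branch.record_activations = True
    set_training(model, False)
    try:
        y_p = model.forward(x)
        # seed the backward pass so the gradient taken is d(logit)/d(activation)
        sign = 1.0 if class_index == 1 else -1.0
        denom = np.clip(y_p * (1.0 - y_p), PROB_EPS, None)
        model.zero_grad()
        model.backward(sign / denom)
    finally:
        branch.record_activations = False
        set_training(model, True)
    act = branch.last_activation[0]       # (C, T', H', W')
    grad = branch.last_activation_grad[0]
    weights = grad.mean(axis=(1, 2, 3))   # global-average-pooled gradients
    cam = np.maximum(np.tensordot(weights, act, axes=(0, 0)), 0.0)  # (T', H', W')
    side = x.shape[-1]
    maps = []
    if not normalize_per_phase:
        global_max = cam.max()
    for t in range(cam.shape[0]):
        hm = sk_resize(cam[t], (side, side), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
        top = hm.max() if normalize_per_phase else global_max
        if top > 0:
            hm = (hm - hm.min()) / (top - hm.min()) if normalize_per_phase else hm / top
        else:
            hm = np.zeros_like(hm)  # constant-zero activations: defined map
        maps.append(
            SaliencyMap(
                heatmap=np.clip(hm, 0.0, 1.0),
                target_layer=f"branch_k{branch_kernel}.layer2",
                class_index=class_index,
                phase_index=t,
            )
        )
    return maps


def attention_maps(model: InvasionNet) -> np.ndarray | None:
    """Per-window attention matrices of the last attention block from the
    most recent forward pass, or None for the conv-only variant."""
    agg = model.aggregator
    blocks = getattr(agg, "blocks", None)
    if not blocks:
        return None
    return blocks[-1].mha.last_attention


def overlay(
    saliency: SaliencyMap, image: np.ndarray, alpha: float = 0.4,
    cmap: str = "jet",
) -> np.ndarray:
    """Alpha-blend the color-mapped heatmap onto the grayscale phase image;
    returns a uint8 RGB array (deterministic for fixed inputs)."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != saliency.heatmap.shape:
        raise ValueError(
            f"image {image.shape} vs heatmap {saliency.heatmap.shape}"
        )
    lo, hi = image.min(), image.max()
    gray = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    colors = colormaps[cmap](saliency.heatmap)[..., :3]
    blended = (1.0 - alpha) * gray[..., None] + alpha * colors
    return (np.clip(blended, 0, 1) * 255).round().astype(np.uint8)
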