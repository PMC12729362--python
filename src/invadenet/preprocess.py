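"""Preprocessing: key-slice selection, cohort Z-score normalization, ROI
cropping/resizing, phase-count adaptation and training-time augmentation.

The model consumes one 2D key slice per contrast phase, stacked along the
last axis: a ``PhaseStack`` of shape (H, W, T) with T = 5 canonical phases
(pre-contrast + four post-contrast acquisitions).  Normalization statistics
are pooled over all tumor voxels of all phases of the *training* cohort
only; the same (mu, sigma) is then applied to every voxel of every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize as sk_resize

__all__ = [
    "RoiBox",
    "NormStats",
    "PhaseStack",
    "AugmentPolicy",
    "NoTumorError",
    "DegenerateCohortError",
    "select_key_slice",
    "fit_norm_stats",
    "znormalize",
    "crop_and_resize",
    "adapt_phase_count",
    "phase_projection_matrix",
    "augment",
]

CANONICAL_SIDE = 224
CANONICAL_PHASES = 5


class NoTumorError(ValueError):
    """Raised when an operation requires a non-empty tumor delineation."""


class DegenerateCohortError(ValueError):
    """Raised when pooled tumor intensities carry no variance."""


@dataclass(frozen=True)
class RoiBox:
    """0-based half-open rectangular region [row_start, row_stop) x
    [col_start, col_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError(f"empty or inverted ROI box: {self}")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError(f"negative ROI coordinates: {self}")

    def validate_within(self, height: int, width: int) -> None:
        if self.row_stop > height or self.col_stop > width:
            raise ValueError(
                f"ROI {self} exceeds image bounds ({height}, {width})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)


@dataclass(frozen=True)
class NormStats:
    """Global tumor-region intensity statistics of the training cohort."""

    mu: float
    sigma: float
    n_voxels: int = 0
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DegenerateCohortError(
                f"pooled tumor intensity sigma must be > 0, got {self.sigma}"
            )


@dataclass
class PhaseStack:
    """One patient's multiphase key-slice image, (H, W, T), phase last."""

    values: np.ndarray
    normalized: bool = False
    selected_slices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"PhaseStack needs (H, W, T), got {self.values.shape}")
        if self.values.shape[2] < 1:
            raise ValueError("PhaseStack needs at least one phase")

    @property
    def n_phases(self) -> int:
        return self.values.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


def select_key_slice(
    volume_per_phase: list[np.ndarray], tumor_mask_per_phase: list[np.ndarray]
) -> PhaseStack:
    """Pick, per phase, the axial slice with the largest in-slice tumor area.

    Volumes are (n_slices, H, W); ties resolve to the lowest slice index.
    """
    if len(volume_per_phase) != len(tumor_mask_per_phase):
        raise ValueError("volume/mask phase counts differ")
    slices, indices = [], []
    for phase, (vol, mask) in enumerate(zip(volume_per_phase, tumor_mask_per_phase)):
        vol = np.asarray(vol)
        mask = np.asarray(mask).astype(bool)
        if vol.shape != mask.shape:
            raise ValueError(
                f"phase {phase}: volume {vol.shape} vs mask {mask.shape}"
            )
        areas = mask.reshape(mask.shape[0], -1).sum(axis=1)
        if areas.max() == 0:
            raise NoTumorError(f"phase {phase}: no tumor delineated in mask")
        idx = int(np.argmax(areas))  # argmax returns the lowest index on ties
        slices.append(vol[idx].astype(np.float64))
        indices.append(idx)
    return PhaseStack(np.stack(slices, axis=-1), selected_slices=tuple(indices))


def fit_norm_stats(
    training_samples: list[tuple[PhaseStack, np.ndarray]],
    sample_ids: list[str] | None = None,
) -> NormStats:
    """Pool mean/SD over all tumor voxels of all phases of the training set.

    ``training_samples`` pairs each stack with a 2D tumor mask; validation
    and test samples must never be passed here.
    """
    if not training_samples:
        raise ValueError("need at least one training sample")
    pooled = []
    for stack, mask in training_samples:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != stack.spatial_shape:
            raise ValueError(
                f"mask {mask.shape} does not match stack {stack.spatial_shape}"
            )
        if mask.any():
            pooled.append(stack.values[mask, :].ravel())
    if not pooled:
        raise NoTumorError("no sample has a non-empty tumor region")
    voxels = np.concatenate(pooled)
    sigma = float(voxels.std())
    if sigma == 0.0:
        raise DegenerateCohortError("constant tumor intensity across cohort")
    ids = tuple(sample_ids) if sample_ids is not None else ()
    return NormStats(mu=float(voxels.mean()), sigma=sigma,
                     n_voxels=int(voxels.size), sample_ids=ids)


def znormalize(stack: PhaseStack, stats: NormStats) -> PhaseStack:
    """S_norm = (S_raw - mu) / sigma applied to every voxel of every phase."""
    out = (stack.values - stats.mu) / stats.sigma
    return PhaseStack(out, normalized=True, selected_slices=stack.selected_slices)


def crop_and_resize(
    stack: PhaseStack, roi: RoiBox, target_side: int = CANONICAL_SIDE
) -> PhaseStack:
    """Crop the bladder ROI and bilinearly resize to target_side squared."""
    h, w = stack.spatial_shape
    roi.validate_within(h, w)
    crop = stack.values[roi.row_start : roi.row_stop, roi.col_start : roi.col_stop, :]
    out = sk_resize(
        crop,
        (target_side, target_side, crop.shape[2]),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return PhaseStack(out, normalized=stack.normalized,
                      selected_slices=stack.selected_slices)


def phase_projection_matrix(t_in: int, t_out: int = CANONICAL_PHASES) -> np.ndarray:
    """Fixed (t_out, t_in) projection mapping t_in phases onto the canonical
    grid by linear interpolation over normalized phase position.

    Used as the inference-time default of the 1x1 phase-adaptation
    convolution; a model may replace it with learned weights.
    """
    if t_in < 2:
        raise ValueError("phase adaptation needs at least 2 phases")
    src = np.linspace(0.0, 1.0, t_in)
    dst = np.linspace(0.0, 1.0, t_out)
    proj = np.zeros((t_out, t_in))
    for i, t in enumerate(dst):
        j = int(np.clip(np.searchsorted(src, t, side="right") - 1, 0, t_in - 2))
        w = (t - src[j]) / (src[j + 1] - src[j])
        proj[i, j] = 1.0 - w
        proj[i, j + 1] = w
    return proj


def adapt_phase_count(
    stack: PhaseStack,
    canonical_t: int = CANONICAL_PHASES,
    projection: np.ndarray | None = None,
) -> PhaseStack:
    """Map a T-phase stack to the canonical phase count with a 1x1 projection
    (a per-pixel linear map across the phase axis); identity when T already
    matches."""
    t = stack.n_phases
    if t < 2:
        raise ValueError("phase adaptation needs at least 2 phases")
    if t == canonical_t and projection is None:
        return stack
    proj = projection if projection is not None else phase_projection_matrix(t, canonical_t)
    proj = np.asarray(proj, dtype=np.float64)
    if proj.shape != (canonical_t, t):
        raise ValueError(f"projection must be ({canonical_t}, {t}), got {proj.shape}")
    out = stack.values @ proj.T
    return PhaseStack(out, normalized=stack.normalized,
                      selected_slices=stack.selected_slices)


@dataclass(frozen=True)
class AugmentPolicy:
    """Stochastic training-time augmentation; every transform is applied with
    its own probability and identical geometric parameters across phases."""

    p_rotate: float = 0.5
    max_rotate_deg: float = 15.0
    p_scale: float = 0.5
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_translate: float = 0.5
    max_translate_px: float = 10.0
    p_mosaic: float = 0.2
    p_rician: float = 0.3
    rician_sigma: float = 0.1
    p_gaussian: float = 0.3
    gaussian_sigma: float = 0.05

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(p_rotate=0, p_scale=0, p_translate=0, p_mosaic=0,
                   p_rician=0, p_gaussian=0)


def _affine(stack_values: np.ndarray, angle_deg: float, scale: float,
            shift: tuple[float, float]) -> np.ndarray:
    """One rigid+scale transform about the image center, identical per phase."""
    h, w, t = stack_values.shape
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    mat = rot / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ (center + np.asarray(shift))
    out = np.empty_like(stack_values)
    for p in range(t):
        out[:, :, p] = ndi.affine_transform(
            stack_values[:, :, p], mat, offset=offset, order=1, mode="nearest"
        )
    return out


def _mosaic(values: np.ndarray, donors: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    """Quadrant mosaic: each quadrant sourced from self or a donor stack."""
    h, w, _ = values.shape
    hh, hw = h // 2, w // 2
    pool = [values] + [d for d in donors if d.shape == values.shape]
    out = values.copy()
    quads = [(slice(0, hh), slice(0, hw)), (slice(0, hh), slice(hw, w)),
             (slice(hh, h), slice(0, hw)), (slice(hh, h), slice(hw, w))]
    for q in quads:
        src = pool[int(rng.integers(len(pool)))]
        out[q[0], q[1], :] = src[q[0], q[1], :]
    return out


def augment(
    stack: PhaseStack,
    policy: AugmentPolicy,
    seed: int | np.random.Generator,
    mosaic_pool: list[PhaseStack] | None = None,
) -> PhaseStack:
    """Seeded augmentation; all phases of one sample share the same spatial
    transform (temporal coherence), so enhancement kinetics are preserved."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = stack.values
    angle, scale, shift = 0.0, 1.0, (0.0, 0.0)
    apply_geom = False
    if policy.p_rotate > 0 and rng.random() < policy.p_rotate:
        angle = float(rng.uniform(-policy.max_rotate_deg, policy.max_rotate_deg))
        apply_geom = True
    if policy.p_scale > 0 and rng.random() < policy.p_scale:
        scale = float(rng.uniform(*policy.scale_range))
        apply_geom = True
    if policy.p_translate > 0 and rng.random() < policy.p_translate:
        shift = tuple(rng.uniform(-policy.max_translate_px, policy.max_translate_px, 2))
        apply_geom = True
    if apply_geom:
        values = _affine(values, angle, scale, shift)
    if policy.p_mosaic > 0 and rng.random() < policy.p_mosaic:
        donors = [s.values for s in (mosaic_pool or [])]
        values = _mosaic(values, donors, rng)
    if policy.p_rician > 0 and rng.random() < policy.p_rician:
        from .phantom import add_rician_noise  # local import avoids a cycle

        values = add_rician_noise(values, policy.rician_sigma, rng)
    if policy.p_gaussian > 0 and rng.random() < policy.p_gaussian:
        values = values + rng.normal(0.0, policy.gaussian_sigma, values.shape)
    return PhaseStack(np.asarray(values), normalized=stack.normalized,
                      selected_slices=stack.selected_slices)
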