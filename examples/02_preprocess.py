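"""Preprocess one patient: cohort Z-score normalization, ROI crop + resize,
and phase-count adaptation.

Normalization statistics (mu, sigma) pool all tumor voxels over all phases
of the *training* samples only, then standardize every voxel of every
split with the same constants.
"""

from invadenet.phantom import PhantomConfig, simulate_cohort
from invadenet.preprocess import (
    PhaseStack,
    adapt_phase_count,
    crop_and_resize,
    fit_norm_stats,
    znormalize,
)

cohort = simulate_cohort(PhantomConfig(n_patients=12, image_size=64, seed=3))
train, held_out = cohort[:9], cohort[9:]

stats = fit_norm_stats(
    [(PhaseStack(s.phases), s.tumor_mask) for s in train],
    sample_ids=[s.patient_id for s in train],
)
print(f"training tumor statistics: mu={stats.mu:.2f}, sigma={stats.sigma:.2f} "
      f"({stats.n_voxels} voxels from {len(stats.sample_ids)} patients)")

s = held_out[0]
stack = znormalize(PhaseStack(s.phases), stats)
print(f"\n{s.patient_id}: raw range [{s.phases.min():.1f}, {s.phases.max():.1f}] "
      f"-> normalized [{stack.values.min():.2f}, {stack.values.max():.2f}]")

crop = crop_and_resize(stack, s.roi, target_side=32)
print(f"ROI {s.roi.shape} cropped and resized to {crop.values.shape[:2]}, "
      f"{crop.n_phases} phases")

canonical = adapt_phase_count(crop)
print(f"after phase adaptation: {canonical.n_phases} phases "
      f"(input had {s.n_phases_actual})")
# Model input is always (32, 32, 5) here — or (224, 224, 5) at full scale —
# regardless of the acquired phase count.
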