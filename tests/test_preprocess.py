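"""Preprocessing: key-slice selection, normalization, cropping, phase
adaptation and augmentation."""

import numpy as np
import pytest

from invadenet.preprocess import (
    AugmentPolicy,
    DegenerateCohortError,
    NormStats,
    NoTumorError,
    PhaseStack,
    RoiBox,
    adapt_phase_count,
    augment,
    crop_and_resize,
    fit_norm_stats,
    phase_projection_matrix,
    select_key_slice,
    znormalize,
)


class TestKeySliceSelection:
    def _volume(self, areas, n=4, side=8):
        vol = np.random.default_rng(0).random((n, side, side))
        mask = np.zeros((n, side, side), bool)
        for i, a in enumerate(areas):
            mask[i].flat[:a] = True
        return vol, mask

    def test_selects_largest_tumor_area(self):
        vol, mask = self._volume([0, 5, 9, 2])
        stack = select_key_slice([vol], [mask])
        assert stack.selected_slices == (2,)
        assert np.array_equal(stack.values[:, :, 0], vol[2])

    def test_tie_resolves_to_lowest_slice(self):
        vol, mask = self._volume([0, 7, 7, 3])
        assert select_key_slice([vol], [mask]).selected_slices == (1,)

    def test_empty_mask_signals_no_tumor(self):
        vol, mask = self._volume([0, 0, 0, 0])
        with pytest.raises(NoTumorError):
            select_key_slice([vol], [mask])

    def test_shape_mismatch_rejected(self):
        vol, mask = self._volume([1, 2, 3, 4])
        with pytest.raises(ValueError):
            select_key_slice([vol], [mask[:, :4]])


class TestNormStats:
    def test_hand_pooled_mean(self):
        values = np.zeros((4, 4, 5))
        values[0, 0, :] = 1.0
        values[0, 1, :] = 3.0
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[0, 1] = True
        stats = fit_norm_stats([(PhaseStack(values), mask)])
        assert stats.mu == pytest.approx(2.0)
        assert stats.sigma == pytest.approx(1.0)
        assert stats.n_voxels == 10

    def test_constant_tumor_is_degenerate(self):
        values = np.full((4, 4, 5), 7.0)
        mask = np.ones((4, 4), bool)
        with pytest.raises(DegenerateCohortError):
            fit_norm_stats([(PhaseStack(values), mask)])

    def test_stats_independent_of_other_splits(self, rng):
        train = [(PhaseStack(rng.random((6, 6, 5))), rng.random((6, 6)) > 0.5)]
        s1 = fit_norm_stats(train, sample_ids=["a"])
        _ = rng.random((6, 6, 5))  # "test" data that must not matter
        s2 = fit_norm_stats(train, sample_ids=["a"])
        assert (s1.mu, s1.sigma, s1.sample_ids) == (s2.mu, s2.sigma, s2.sample_ids)


class TestZNormalize:
    def test_formula(self):
        stack = PhaseStack(np.full((2, 2, 5), 140.0))
        out = znormalize(stack, NormStats(mu=100.0, sigma=20.0))
        assert np.allclose(out.values, 2.0)
        assert out.normalized

    def test_voxel_at_mean_maps_to_zero(self):
        stack = PhaseStack(np.full((2, 2, 5), 100.0))
        assert np.allclose(znormalize(stack, NormStats(100.0, 20.0)).values, 0.0)

    def test_defining_voxels_standardized(self, rng):
        values = rng.random((8, 8, 5)) * 50 + 100
        mask = np.ones((8, 8), bool)
        stats = fit_norm_stats([(PhaseStack(values), mask)])
        out = znormalize(PhaseStack(values), stats)
        assert out.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert out.values.std() == pytest.approx(1.0, abs=1e-10)

    def test_sigma_zero_rejected(self):
        with pytest.raises(DegenerateCohortError):
            NormStats(mu=0.0, sigma=0.0)


class TestCropResize:
    def test_output_shape_is_canonical(self, rng):
        stack = PhaseStack(rng.random((100, 120, 5)))
        out = crop_and_resize(stack, RoiBox(10, 90, 20, 110), target_side=224)
        assert out.values.shape == (224, 224, 5)

    def test_identity_when_roi_matches_target(self, rng):
        stack = PhaseStack(rng.random((50, 50, 3)))
        out = crop_and_resize(stack, RoiBox(0, 32, 0, 32), target_side=32)
        assert np.allclose(out.values, stack.values[:32, :32], atol=1e-12)

    def test_constant_image_preserved(self):
        stack = PhaseStack(np.full((40, 40, 5), 3.5))
        out = crop_and_resize(stack, RoiBox(5, 35, 5, 35), target_side=24)
        assert np.allclose(out.values, 3.5)

    def test_roi_outside_bounds_rejected(self, rng):
        stack = PhaseStack(rng.random((30, 30, 5)))
        with pytest.raises(ValueError):
            crop_and_resize(stack, RoiBox(0, 31, 0, 10))

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            RoiBox(10, 10, 0, 5)
        with pytest.raises(ValueError):
            RoiBox(-1, 10, 0, 5)


class TestPhaseAdaptation:
    def test_canonical_count_passthrough(self, rng):
        stack = PhaseStack(rng.random((8, 8, 5)))
        assert adapt_phase_count(stack) is stack

    def test_four_phases_adapted_to_five(self, rng):
        stack = PhaseStack(rng.random((8, 8, 4)))
        out = adapt_phase_count(stack)
        assert out.values.shape == (8, 8, 5)

    def test_duplication_projection_applied_exactly(self, rng):
        """A hand-specified phase-duplication matrix is honoured."""
        stack = PhaseStack(rng.random((4, 4, 4)))
        proj = np.zeros((5, 4))
        proj[[0, 1, 2, 3, 4], [0, 1, 1, 2, 3]] = 1.0  # duplicate phase 1
        out = adapt_phase_count(stack, projection=proj)
        assert np.allclose(out.values[:, :, 2], stack.values[:, :, 1])
        assert np.allclose(out.values[:, :, 4], stack.values[:, :, 3])

    def test_interpolation_matrix_rows_sum_to_one(self):
        proj = phase_projection_matrix(4, 5)
        assert proj.shape == (5, 4)
        assert np.allclose(proj.sum(axis=1), 1.0)

    def test_single_phase_rejected(self, rng):
        with pytest.raises(ValueError):
            adapt_phase_count(PhaseStack(rng.random((4, 4, 1))))


class TestAugment:
    def test_zero_probability_policy_is_identity(self, rng):
        stack = PhaseStack(rng.random((16, 16, 5)), normalized=True)
        out = augment(stack, AugmentPolicy.identity(), seed=3)
        assert np.array_equal(out.values, stack.values)

    def test_same_seed_same_output(self, rng):
        stack = PhaseStack(rng.random((16, 16, 5)), normalized=True)
        policy = AugmentPolicy()
        a = augment(stack, policy, seed=9)
        b = augment(stack, policy, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_full_rotation_is_near_identity(self, rng):
        from invadenet.preprocess import _affine

        values = rng.random((16, 16, 5))
        rotated = _affine(values, 360.0, 1.0, (0.0, 0.0))
        assert np.allclose(rotated, values, atol=1e-7)

    def test_temporal_coherence_on_phase_constant_stack(self, rng):
        """All phases share one spatial transform: a stack whose phases are
        identical stays phase-identical after geometric augmentation."""
        frame = rng.random((20, 20))
        stack = PhaseStack(np.repeat(frame[:, :, None], 5, axis=2), normalized=True)
        policy = AugmentPolicy(p_rotate=1.0, p_scale=1.0, p_translate=1.0,
                               p_mosaic=0, p_rician=0, p_gaussian=0)
        out = augment(stack, policy, seed=2)
        for p in range(1, 5):
            assert np.allclose(out.values[:, :, p], out.values[:, :, 0])

    def test_noise_augmentations_change_values(self, rng):
        stack = PhaseStack(rng.random((16, 16, 5)) + 1.0, normalized=True)
        policy = AugmentPolicy(p_rotate=0, p_scale=0, p_translate=0, p_mosaic=0,
                               p_rician=1.0, p_gaussian=1.0)
        out = augment(stack, policy, seed=4)
        assert not np.array_equal(out.values, stack.values)
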