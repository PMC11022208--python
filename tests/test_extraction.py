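"""Morphology, multi-level Otsu, collecting-system extraction, Dice,
sliding-window fusion and augmentations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uroscope import (LabelMap, StructuringElement, Volume, balanced_crop,
                      dice, dilate, extract_collecting_system, intensity_shift,
                      make_phantom, otsu_thresholds, random_affine,
                      random_smooth, sliding_window_predict)
from uroscope.extraction import _window_starts
from uroscope.phantom import PhantomSpec

from oracles import exhaustive_otsu3, otsu3_objective


def binary_map(arr):
    return LabelMap(arr.astype(np.uint8), (1, 1, 1),
                    label_semantics={0: "background", 1: "kidney"})


class TestDilate:
    def test_single_voxel_grows_to_element_box(self):
        m = np.zeros((15, 15, 15))
        m[7, 7, 7] = 1
        out = dilate(binary_map(m), (5, 9, 9))
        assert out.data.sum() == 5 * 9 * 9

    def test_empty_and_full_masks_are_fixed_points(self):
        empty = dilate(binary_map(np.zeros((6, 6, 6))))
        assert empty.data.sum() == 0
        full = dilate(binary_map(np.ones((6, 6, 6))))
        assert full.data.all()

    def test_even_element_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            StructuringElement((4, 9, 9))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_extensive_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((10, 10, 10)) < 0.08
        b = a | (rng.random((10, 10, 10)) < 0.05)
        da = dilate(binary_map(a), (3, 3, 3)).data.astype(bool)
        db = dilate(binary_map(b), (3, 3, 3)).data.astype(bool)
        assert (da | a).sum() == da.sum()          # output contains input
        assert (da & ~db).sum() == 0               # monotone in mask inclusion

    def test_translation_equivariant(self):
        m = np.zeros((12, 12, 12))
        m[4, 4, 4] = 1
        d1 = dilate(binary_map(m), (3, 3, 3)).data
        d2 = dilate(binary_map(np.roll(m, 2, axis=2)), (3, 3, 3)).data
        np.testing.assert_array_equal(np.roll(d1, 2, axis=2), d2)


class TestOtsu:
    def test_perfectly_separated_clusters(self):
        vals = np.repeat([0.0, 100.0, 200.0], 3)
        t1, t2 = otsu_thresholds(vals, 3)
        groups = np.digitize(vals, [t1, t2])
        np.testing.assert_array_equal(groups, np.repeat([0, 1, 2], 3))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            otsu_thresholds(np.full(100, 5.0), 3)

    def test_attains_exhaustive_search_optimum(self):
        # ties between equal-variance threshold pairs are legitimate; the
        # attained objective must match the brute-force optimum
        for trial in range(10):
            rng = np.random.default_rng(trial)
            locs = np.sort(rng.uniform(0, 100, 3))
            comp = rng.integers(0, 3, 800)
            vals = rng.normal(locs[comp], rng.uniform(1, 8, 3)[comp])
            thr = otsu_thresholds(vals, 3)
            best_obj, _ = exhaustive_otsu3(vals)
            attained = otsu3_objective(vals, thr)
            assert attained >= best_obj - 1e-6 * abs(best_obj)


class TestExtraction:
    def test_noiseless_phantom_recovered_exactly(self):
        truth = make_phantom(PhantomSpec(grid_shape=(64, 64, 64), noise_sd=0.0,
                                         rng_seed=0))
        kidney = binary_map(truth.labels.data > 0)
        out = extract_collecting_system(truth.ct, kidney)
        np.testing.assert_array_equal(out.data, (truth.labels.data == 2).astype(np.uint8))

    def test_output_subset_of_dilated_mask(self):
        truth = make_phantom(PhantomSpec(grid_shape=(64, 64, 64), rng_seed=1))
        kidney = binary_map(truth.labels.data > 0)
        out = extract_collecting_system(truth.ct, kidney)
        dil = dilate(kidney).data.astype(bool)
        assert not np.any(out.data.astype(bool) & ~dil)

    def test_empty_kidney_mask_rejected(self):
        ct = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="empty"):
            extract_collecting_system(ct, binary_map(np.zeros((8, 8, 8))))

    def test_misaligned_shapes_rejected(self):
        ct = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="aligned"):
            extract_collecting_system(ct, binary_map(np.ones((6, 6, 6))))


class TestDice:
    def test_identical_disjoint_and_half_overlap(self):
        a = np.zeros((4, 4, 4))
        a[:2] = 1
        assert dice(binary_map(a), binary_map(a)) == 1.0
        b = np.zeros((4, 4, 4))
        b[2:] = 1
        assert dice(binary_map(a), binary_map(b)) == 0.0
        c = np.zeros((1, 1, 8))
        c[0, 0, :4] = 1
        d = np.zeros((1, 1, 8))
        d[0, 0, 2:6] = 1
        assert dice(binary_map(c), binary_map(d)) == 0.5

    def test_both_empty_defined_as_one(self):
        z = binary_map(np.zeros((3, 3, 3)))
        assert dice(z, z) == 1.0

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = binary_map(rng.random((6, 6, 6)) < 0.3)
        b = binary_map(rng.random((6, 6, 6)) < 0.3)
        d_ab, d_ba = dice(a, b), dice(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(binary_map(np.zeros((3, 3, 3))), binary_map(np.zeros((4, 4, 4))))


class TestSlidingWindow:
    def test_window_offsets_snap_to_boundary(self):
        assert _window_starts(256, 128, 64) == [0, 64, 128]
        assert _window_starts(100, 40, 20) == [0, 20, 40, 60]
        assert _window_starts(90, 40, 20) == [0, 20, 40, 50]

    def test_constant_predictor_gives_constant_scores(self):
        vol = Volume(np.random.default_rng(0).random((12, 12, 12)))
        out = sliding_window_predict(vol, lambda p: np.full_like(p, 0.7),
                                     patch=(8, 8, 8), overlap=0.5)
        np.testing.assert_allclose(out.data, 0.7, atol=1e-12)

    def test_identity_predictor_reproduces_input(self):
        vol = Volume(np.random.default_rng(1).random((16, 12, 10)))
        out = sliding_window_predict(vol, lambda p: p, patch=(8, 6, 5), overlap=0.5)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_affine_predictor_has_no_seams_on_constant_input(self):
        vol = Volume(np.full((12, 12, 12), 0.4))
        out = sliding_window_predict(vol, lambda p: 0.3 * p + 0.1,
                                     patch=(8, 8, 8), overlap=0.5)
        assert np.ptp(out.data) < 1e-12

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            sliding_window_predict(Volume(np.zeros((8, 8, 8))), lambda p: p,
                                   patch=(16, 8, 8))


class TestAugment:
    def test_intensity_shift_bounds_and_determinism(self):
        patch = np.random.default_rng(0).random((8, 8, 8))
        out1 = intensity_shift(patch, np.random.default_rng(42))
        out2 = intensity_shift(patch, np.random.default_rng(42))
        np.testing.assert_array_equal(out1, out2)
        assert np.all(np.abs(out1 - patch) <= 0.026 + 1e-12)

    def test_affine_and_smooth_are_seeded(self):
        patch = np.random.default_rng(0).random((10, 10, 10))
        a1 = random_affine(patch, np.random.default_rng(7))
        a2 = random_affine(patch, np.random.default_rng(7))
        np.testing.assert_array_equal(a1, a2)
        s1 = random_smooth(patch, np.random.default_rng(7))
        s2 = random_smooth(patch, np.random.default_rng(7))
        np.testing.assert_array_equal(s1, s2)
        assert s1.std() < patch.std()  # smoothing reduces variance

    def test_balanced_crop_alternates_center_classes(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((20, 20, 20), dtype=np.uint8)
        labels[8:14, 8:14, 8:14] = 1
        image = rng.random((20, 20, 20))
        crops = balanced_crop(image, labels, crop_shape=(8, 8, 8), n_crops=16,
                              rng=np.random.default_rng(3))
        assert len(crops) == 16
        centers = [lab[4, 4, 4] for _, lab in crops]
        assert centers[0::2] == [1] * 8 and centers[1::2] == [0] * 8

    def test_all_background_volume_warns_and_degrades(self, caplog):
        labels = np.zeros((12, 12, 12), dtype=np.uint8)
        image = np.zeros((12, 12, 12))
        with caplog.at_level("WARNING"):
            crops = balanced_crop(image, labels, crop_shape=(6, 6, 6), n_crops=4,
                                  rng=np.random.default_rng(0))
        assert len(crops) == 4
        assert any("unbalanced" in r.message for r in caplog.records)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError, match="crop"):
            balanced_crop(np.zeros((6, 6, 6)), np.zeros((6, 6, 6), dtype=int),
                          crop_shape=(8, 8, 8))
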