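import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from slideprep import metrics as M
from tests import oracles as O


def random_mask(rng, shape=(16, 16), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)


class TestIoU:
    def test_identical_and_disjoint(self, rng):
        m = random_mask(rng)
        m[0, 0] = 1
        assert M.iou(m, m) == 1.0
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = 1
        b[3, 3] = 1
        assert M.iou(a, b) == 0.0
        assert M.iou(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0

    def test_shifted_block_enumeration(self):
        a = np.zeros((5, 5), np.uint8)
        b = np.zeros((5, 5), np.uint8)
        a[1:4, 1:4] = 1
        b[1:4, 2:5] = 1
        assert M.iou(a, b) == pytest.approx(0.5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(Exception):
            M.iou(np.zeros((3, 3)), np.zeros((4, 4)))


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        m[5, 5] = 1
        assert M.hausdorff(m, m) == 0.0

    def test_single_pixels_euclidean(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert M.hausdorff(a, b) == pytest.approx(5.0)

    def test_empty_mask_gives_nan(self):
        m = np.zeros((4, 4), np.uint8)
        n = m.copy()
        n[1, 1] = 1
        assert math.isnan(M.hausdorff(m, n))


class TestPerimeterRatio:
    def test_identity_and_empty(self):
        m = np.zeros((6, 6), np.uint8)
        m[2:5, 2:5] = 1
        assert M.perimeter_ratio(m, m) == 1.0
        assert M.perimeter_ratio(np.zeros_like(m), m) == 0.0
        assert math.isnan(M.perimeter_ratio(m, np.zeros_like(m)))

    def test_two_squares_double_boundary(self):
        g = np.zeros((12, 12), np.uint8)
        g[1:4, 1:4] = 1  # 8 boundary pixels
        p = np.zeros((12, 12), np.uint8)
        p[1:4, 1:4] = 1
        p[7:10, 7:10] = 1  # 16 boundary pixels
        assert M.perimeter_ratio(p, g) == pytest.approx(2.0)


class TestCompDiff:
    def test_checkerboard_connectivity(self):
        m = np.zeros((2, 2), np.uint8)
        m[0, 0] = m[1, 1] = 1
        from slideprep.segregate import count_components
        assert count_components(m, 8) == 1
        assert count_components(m, 4) == 2

    def test_symmetry_and_values(self, rng):
        a = random_mask(rng)
        b = random_mask(rng)
        assert M.comp_diff(a, b) == M.comp_diff(b, a)


class TestOracleEquivalence:
    """Brute-force agreement on batches of random masks (<= 1e-9)."""

    def test_binary_metrics_match_oracles(self, rng):
        for _ in range(100):
            a = random_mask(rng)
            b = random_mask(rng)
            assert M.iou(a, b) == pytest.approx(O.iou_oracle(a, b), abs=1e-9)
            assert M.comp_diff(a, b, 8) == O.comp_diff_oracle(a, b, 8)
            assert M.comp_diff(a, b, 4) == O.comp_diff_oracle(a, b, 4)
            hd_o = O.hausdorff_oracle(a, b)
            hd = M.hausdorff(a, b)
            if math.isnan(hd_o):
                assert math.isnan(hd)
            else:
                assert hd == pytest.approx(hd_o, abs=1e-9)
            pr_o = O.perimeter_ratio_oracle(a, b)
            pr = M.perimeter_ratio(a, b)
            if math.isnan(pr_o):
                assert math.isnan(pr)
            else:
                assert pr == pytest.approx(pr_o, abs=1e-9)

    def test_multiclass_dice_matches_oracle(self, rng):
        for _ in range(100):
            a = rng.integers(0, 4, (12, 12))
            b = rng.integers(0, 4, (12, 12))
            classes = [1, 2, 3]
            assert M.multiclass_dice(a, b, classes) == pytest.approx(
                O.multiclass_dice_oracle(a, b, classes), abs=1e-9)

    def test_ari_matches_oracle_and_sklearn(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            ours = M.adjusted_rand_index(a, b)
            assert ours == pytest.approx(O.ari_oracle(list(a), list(b)),
                                         abs=1e-9)
            assert ours == pytest.approx(adjusted_rand_score(a, b), abs=1e-9)


class TestLabelingMetrics:
    def test_dice_identical_and_disjoint(self):
        a = np.zeros((4, 4), int)
        a[:2] = 1
        assert M.multiclass_dice(a, a.copy()) == 1.0
        b = np.zeros((4, 4), int)
        b[2:] = 1
        assert M.multiclass_dice(a, b) == 0.0

    def test_dice_mixed_two_class_example(self):
        # class 1 perfect; class 2 half-overlapping equal areas -> 0.75
        a = np.zeros((4, 8), int)
        b = np.zeros((4, 8), int)
        a[0, :4] = 1
        b[0, :4] = 1
        a[2, 0:4] = 2
        b[2, 2:6] = 2
        assert M.multiclass_dice(a, b, [1, 2]) == pytest.approx(0.75)

    def test_ari_hand_example_and_permutation_invariance(self, rng):
        assert M.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == \
            pytest.approx(-0.5)
        a = rng.integers(0, 3, 20)
        b = rng.integers(0, 3, 20)
        perm = {0: 2, 1: 0, 2: 1}
        b2 = np.array([perm[x] for x in b])
        assert M.adjusted_rand_index(a, b) == pytest.approx(
            M.adjusted_rand_index(a, b2), abs=1e-12)
        np.testing.assert_allclose(M.adjusted_rand_index(a, a), 1.0)


class TestImageMetrics:
    def test_ssim_self_is_exactly_one(self, rng):
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        assert M.ssim(img, img.copy()) == 1.0

    def test_ssim_constant_images_closed_form(self):
        mx, my = 100.0, 140.0
        a = np.full((24, 24, 3), mx)
        b = np.full((24, 24, 3), my)
        c1 = (0.01 * 255) ** 2
        expect = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
        assert M.ssim(a, b) == pytest.approx(expect, abs=1e-9)

    def test_ssim_symmetric(self, rng):
        a = rng.integers(0, 255, (24, 24, 3), dtype=np.uint8)
        b = rng.integers(0, 255, (24, 24, 3), dtype=np.uint8)
        assert M.ssim(a, b) == pytest.approx(M.ssim(b, a), abs=1e-12)

    def test_mi_self_equals_marginal_entropy(self, rng):
        img = rng.integers(0, 255, (32, 32), dtype=np.uint8)
        mi = M.mutual_information(img, img.copy())
        hist, _ = np.histogram(img.astype(float), bins=64, range=(0, 255))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log(p)).sum())
        assert mi == pytest.approx(entropy, abs=1e-9)

    def test_mi_constant_image_zero_and_symmetry(self, rng):
        const = np.full((16, 16), 42, np.uint8)
        other = rng.integers(0, 255, (16, 16), dtype=np.uint8)
        assert M.mutual_information(const, other) == pytest.approx(0.0, abs=1e-9)
        assert M.mutual_information(other, const) >= -1e-9
        a = rng.integers(0, 255, (16, 16), dtype=np.uint8)
        assert M.mutual_information(a, other) == pytest.approx(
            M.mutual_information(other, a), abs=1e-12)


class TestMorphology:
    def test_disc_circularity(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disc = (((yy - 25) ** 2 + (xx - 25) ** 2) <= 400).astype(int)
        feats = M.morphology_features(disc)
        assert len(feats) == 1
        assert 0.9 <= feats[0].circularity <= 1.05
        assert feats[0].solidity > 0.95  # rasterized convex object

    def test_rectangle_aspect_ratio(self):
        m = np.zeros((60, 60), int)
        m[10:20, 10:50] = 1
        f = M.morphology_features(m)[0]
        assert f.aspect_ratio == pytest.approx(4.0, rel=0.01)
        assert f.extent == pytest.approx(1.0, abs=1e-9)

    def test_standardization_zero_mean_unit_sd(self, rng):
        labels = np.zeros((64, 64), int)
        labels[2:12, 2:12] = 1
        labels[20:26, 20:40] = 2
        labels[40:60, 40:52] = 3
        yy, xx = np.mgrid[0:64, 0:64]
        labels[((yy - 50) ** 2 + (xx - 12) ** 2) <= 36] = 4
        mat = M.standardize_features(M.morphology_features(labels))
        assert np.abs(mat.mean(axis=0)).max() < 1e-9
        assert np.abs(mat.std(axis=0) - 1).max() < 1e-9

    def test_cells_outside_tissue_centroid_rule(self):
        tissue = np.zeros((30, 30), np.uint8)
        tissue[:, :15] = 1
        cells = np.zeros((30, 30), int)
        cells[2:6, 2:6] = 1        # inside
        cells[10:14, 20:24] = 2    # outside
        cells[20:24, 12:19] = 3    # straddles, centroid col 15 -> outside
        assert M.cells_outside_tissue(cells, tissue) == 2
        cells[20:24, 12:19] = 0
        cells[20:24, 9:18] = 3     # centroid col 13 -> inside
        assert M.cells_outside_tissue(cells, tissue) == 1


class TestOverlayExtraction:
    def test_threshold_bounds(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[0, 0] = (200, 10, 10)
        img[0, 1] = (150, 10, 10)
        assert M.red_threshold(img)[0, 0] == 1
        assert M.red_threshold(img)[0, 1] == 0

    def test_red_rings_become_filled_discs(self):
        img = np.full((128, 128, 3), 255, np.uint8)
        centers = [(30, 30), (30, 90), (90, 30), (90, 90)]
        yy, xx = np.mgrid[0:128, 0:128]
        for cy, cx in centers:
            d = np.hypot(yy - cy, xx - cx)
            ring = (d >= 5) & (d <= 7)
            img[ring] = (220, 5, 5)
        mask = M.extract_overlay_markers(img, radius_range=(4, 9))
        from slideprep.segregate import count_components
        assert count_components(mask, 8) == 4
        for cy, cx in centers:
            assert mask[cy, cx] == 1  # interior filled

    def test_no_red_pixels_empty(self):
        img = np.full((32, 32, 3), 255, np.uint8)
        assert M.extract_overlay_markers(img).sum() == 0
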