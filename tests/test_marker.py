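import numpy as np
import pytest

from slideprep.marker import (AugmentConfig, LossConfig, MarkerSegmenter,
                              TrainConfig, augment, build_sampling_plan,
                              classify_difficulty, crossval_split, dice_loss,
                              focal_loss, hough_baseline, total_loss)
from slideprep.synthetic import (ConfigError, SyntheticSpec, generate_sample)


class TestLosses:
    def test_dice_perfect_overlap_is_zero(self):
        m = np.zeros((5, 5))
        m[:2, :5] = 1  # |M| = 10
        assert dice_loss(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_dice_double_empty_is_zero(self):
        z = np.zeros((4, 4))
        assert dice_loss(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_dice_disjoint_five_pixel_masks(self):
        p = np.zeros((5, 5))
        g = np.zeros((5, 5))
        p[0, :5] = 1
        g[4, :5] = 1
        assert dice_loss(p, g) == pytest.approx(1 - 1 / 11, abs=1e-12)

    def test_focal_single_pixel_hand_value(self):
        # y=1, p=0.5: 0.95 * 0.5^3 * (-log 0.5)
        p = np.array([[0.5]])
        y = np.array([[1.0]])
        expected = 0.95 * 0.125 * -np.log(0.5)
        assert focal_loss(p, y) == pytest.approx(expected, abs=1e-9)

    def test_focal_vanishes_for_confident_correct(self):
        p = np.full((4, 4), 1.0 - 1e-7)
        y = np.ones((4, 4))
        assert focal_loss(p, y) < 1e-5

    def test_focal_gamma0_alpha_half_is_half_bce(self, rng):
        p = rng.uniform(0.1, 0.9, (6, 6))
        y = (rng.random((6, 6)) > 0.5).astype(float)
        cfg = LossConfig(alpha=0.5, gamma=0.0)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert focal_loss(p, y, cfg) == pytest.approx(0.5 * bce, abs=1e-9)

    def test_total_loss_is_exact_convex_combination(self, rng):
        p = rng.uniform(0, 1, (8, 8))
        y = (rng.random((8, 8)) > 0.6).astype(float)
        cfg = LossConfig()
        expect = 0.9 * dice_loss(p, y, cfg) + 0.1 * focal_loss(p, y, cfg)
        assert total_loss(p, y, cfg) == pytest.approx(expect, abs=1e-12)
        # all-dice case from the mixing weight
        ones_pred = np.zeros((4, 4))
        ones_gold = np.ones((4, 4))
        ld = dice_loss(ones_pred, ones_gold, cfg)
        lf = focal_loss(np.full((4, 4), 1e-6), ones_gold, cfg)
        assert total_loss(np.full((4, 4), 1e-6), ones_gold, cfg) == \
            pytest.approx(0.9 * ld + 0.1 * lf, abs=1e-12)


class TestDifficulty:
    @pytest.mark.parametrize("factor,expected", [
        (0.85, "hard"), (0.0, "easy"), (0.5, "moderate"),
        (0.8, "moderate"), (0.81, "hard"), (0.3, "easy"), (0.29, "easy"),
    ])
    def test_cutoffs(self, factor, expected):
        assert classify_difficulty(factor) == expected

    def test_sampling_plan_multiplicities(self):
        corpus = [{"image": None, "mask": None, "overlap_factor": f}
                  for f in (0.9, 0.95, 0.1)]
        plan = build_sampling_plan(corpus, TrainConfig(seed=0))
        assert len(plan) == 7  # 2 hard x3 + 1 easy
        assert sorted(plan).count(0) == 3 and sorted(plan).count(2) == 1

    def test_sampling_plan_seeded_determinism(self):
        corpus = [{"overlap_factor": f} for f in (0.9, 0.5, 0.1, 0.2)]
        a = build_sampling_plan(corpus, TrainConfig(seed=5))
        b = build_sampling_plan(corpus, TrainConfig(seed=5))
        assert a == b

    def test_empty_corpus_rejected(self):
        with pytest.raises(ConfigError):
            build_sampling_plan([], TrainConfig())


class TestAugment:
    def test_identity_config_leaves_pair_unchanged(self, rng, easy_sample):
        img, mask = easy_sample.image, easy_sample.markers.mask
        out_img, out_mask = augment(img, mask, AugmentConfig.identity(), rng)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_mask, mask)

    def test_geometric_transform_shared_by_image_and_mask(self, rng,
                                                          easy_sample):
        img, mask = easy_sample.image, easy_sample.markers.mask
        cfg = AugmentConfig(flip_lr_prob=0, flip_ud_prob=0,
                            scale_range=(0.8, 0.8), rotation_range=(7, 7),
                            brightness_range=(1, 1), blur_sigma_range=(0, 0))
        out_img, out_mask = augment(img, mask, cfg, rng)
        # dark marker rings must still coincide with the transformed mask
        dark = out_img.mean(axis=2) < 150
        overlap = (dark & (out_mask > 0)).sum() / max(out_mask.sum(), 1)
        assert overlap > 0.3
        assert out_mask.sum() < mask.sum()  # scaled down

    def test_double_flip_is_identity(self, easy_sample):
        img, mask = easy_sample.image, easy_sample.markers.mask
        cfg = AugmentConfig(flip_lr_prob=1.0, flip_ud_prob=0.0,
                            scale_range=(1, 1), rotation_range=(0, 0),
                            brightness_range=(1, 1), blur_sigma_range=(0, 0))
        r1 = augment(img, mask, cfg, np.random.default_rng(0))
        r2 = augment(r1[0], r1[1], cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(r2[0], img)
        np.testing.assert_array_equal(r2[1], mask)

    def test_drawn_scale_within_configured_range(self):
        cfg = AugmentConfig()
        rng = np.random.default_rng(0)
        for _ in range(50):
            rng2 = np.random.default_rng(int(rng.integers(1 << 30)))
            rng2.random()
            rng2.random()  # flip draws
            s = rng2.uniform(*cfg.scale_range)
            assert 0.8 <= s <= 1.0


class TestTrainingBasics:
    def test_empty_corpus_raises(self):
        with pytest.raises(ConfigError):
            MarkerSegmenter().fit([])

    def test_markerless_corpus_raises(self, rng):
        img = rng.integers(0, 255, (128, 128, 3), dtype=np.uint8)
        with pytest.raises(ConfigError):
            MarkerSegmenter().fit([(img, np.zeros((128, 128), np.uint8))])

    def test_short_training_deterministic_and_saves(self, tmp_path):
        sample = generate_sample(SyntheticSpec(seed=2, size=128,
                                               markers_per_side=8,
                                               marker_radius=3.5))
        tcfg = TrainConfig(epochs=3, crop_size=64, seed=7, tile_size=128)
        a = MarkerSegmenter(train_config=tcfg).fit([sample])
        b = MarkerSegmenter(train_config=tcfg).fit([sample])
        np.testing.assert_array_equal(a.loss_trace_, b.loss_trace_)
        for (pa, _), (pb, _) in zip(a.net_.params(), b.net_.params()):
            np.testing.assert_array_equal(pa, pb)
        a.save(tmp_path / "m.npz")
        back = MarkerSegmenter.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.predict_proba(sample.image),
                                      a.predict_proba(sample.image))

    def test_config_dump_exposes_stated_defaults(self):
        dump = MarkerSegmenter().config_dump()
        assert dump["loss"] == {"alpha": 0.95, "gamma": 3.0, "lam": 0.9,
                                "epsilon": 1.0, "binarize_threshold": 0.5}
        assert dump["train"]["learning_rate"] == 1e-4
        assert (dump["train"]["beta1"], dump["train"]["beta2"]) == (0.5, 0.999)
        assert dump["train"]["hard_multiplier"] == 3
        assert dump["train"]["moderate_multiplier"] == 2
        assert dump["augment"]["scale_range"] == [0.8, 1.0]
        assert dump["augment"]["rotation_range"] == [-10.0, 10.0]
        assert dump["augment"]["brightness_range"] == [0.5, 1.2]
        assert dump["augment"]["blur_sigma_range"] == [0.0, 1.0]
        assert dump["net"]["encoder_widths"] == [32, 64, 128, 256]


class TestPredictTiling:
    def test_constant_network_invariant_to_tiling(self, rng):
        from slideprep.nn import NetConfig, SegNet
        est = MarkerSegmenter(train_config=TrainConfig(tile_size=64))
        est.net_ = SegNet(NetConfig(encoder_widths=(4, 4, 4, 4),
                                    decoder_widths=(4, 4, 4, 4), seed=0))
        for p, _ in est.net_.params():
            p[...] = 0  # output is 0.5 everywhere, spatially consistent
        img = rng.integers(0, 255, (160, 160, 3), dtype=np.uint8)
        prob = est.predict_proba(img, tile_size=64, overlap=16)
        np.testing.assert_allclose(prob, 0.5, atol=1e-7)
        assert prob.shape == (160, 160)


class TestHoughBaseline:
    def test_blank_image_no_circles(self):
        img = np.full((128, 128, 3), 240, np.uint8)
        res = hough_baseline(img)
        assert len(res.circles) == 0 and res.mask.sum() == 0

    def test_clean_undeformed_frame_recall(self):
        spec = SyntheticSpec(seed=6, deform_amplitude=0.0, center_jitter=0.0,
                             radius_jitter=0.0, n_tissue_blobs=0,
                             stain_noise_density=0.0)
        s = generate_sample(spec)
        res = hough_baseline(s.image)
        centers = np.array([c.center for c in s.markers.circles])
        found = 0
        for c in centers:
            for d in res.circles:
                if np.hypot(c[0] - d.center[0], c[1] - d.center[1]) <= spec.marker_radius:
                    found += 1
                    break
        assert found / len(centers) >= 0.9


class TestCrossval:
    def test_twelve_fold_properties(self):
        corpus = list(range(24))
        folds = crossval_split(corpus, k=12, seed=1)
        assert len(folds) == 12
        tests = [tuple(te) for _, te in folds]
        assert all(len(te) == 2 for te in tests)
        flat = [i for te in tests for i in te]
        assert sorted(flat) == corpus  # disjoint cover
        assert crossval_split(corpus, k=12, seed=1) == folds  # seeded

    def test_small_corpus_rejected(self):
        with pytest.raises(ConfigError):
            crossval_split(list(range(5)), k=12)
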