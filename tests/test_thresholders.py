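"""Threshold selectors against independent brute-force oracles."""

import numpy as np
import pytest

from lesionsemble import thresholders as T
from lesionsemble import synthetic

from conftest import brute_force_kapur, brute_force_otsu, random_test_images


def disc_image(low=40.0, high=220.0, size=56, radius=12):
    rr, cc = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    disc = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    return np.where(disc, low, high).astype(float), disc.astype(np.uint8)


class TestHistogram:
    def test_uniform_image(self):
        counts, probs = T.histogram(np.full((56, 56), 10.0))
        assert counts[10] == 3136 and counts.sum() == 3136
        assert probs[10] == 1.0

    def test_two_level(self):
        counts, probs = T.histogram(np.array([[0.0, 0.0], [255.0, 255.0]]))
        assert probs[0] == 0.5 and probs[255] == 0.5

    def test_probabilities_sum_to_one(self):
        img = np.random.default_rng(0).uniform(0, 255, (30, 30))
        _, probs = T.histogram(img)
        assert abs(probs.sum() - 1.0) < 1e-9


class TestApplyThreshold:
    def test_extremes(self):
        img = np.random.default_rng(1).uniform(10, 200, (8, 8))
        assert T.apply_threshold(img, 255).all()
        assert not T.apply_threshold(img, 5).any()

    def test_pointwise_on_ramp(self):
        img = np.tile(np.arange(256, dtype=float), (2, 1))
        mask = T.apply_threshold(img, 127)
        assert np.array_equal(mask, (img <= 127).astype(np.uint8))

    def test_bright_polarity_is_complement(self):
        img = np.random.default_rng(2).uniform(0, 255, (8, 8))
        dark = T.apply_threshold(img, 100, "dark")
        bright = T.apply_threshold(img, 100, "bright")
        assert np.array_equal(dark + bright, np.ones_like(dark))

    def test_monotone_in_threshold(self):
        img = np.random.default_rng(3).uniform(0, 255, (16, 16))
        prev = T.apply_threshold(img, 40)
        for th in (80, 120, 200):
            cur = T.apply_threshold(img, th)
            assert np.all(prev <= cur)
            prev = cur


class TestOtsu:
    def test_two_spike_histogram_smallest_tie(self):
        img = np.concatenate([np.full(50, 50.0), np.full(50, 200.0)])
        counts, _ = T.histogram(img.reshape(10, 10))
        assert T.otsu_threshold(counts) == 50

    def test_two_clusters_threshold_between(self):
        rng = np.random.default_rng(4)
        img = np.clip(np.concatenate([
            rng.normal(60, 10, 500), rng.normal(180, 10, 500)
        ]), 0, 255)
        counts, _ = T.histogram(img.reshape(20, 50))
        th = T.otsu_threshold(counts)
        # all thresholds in the empty inter-cluster gap tie; the smallest-th
        # rule lands on the gap's left edge, next to the low cluster
        assert th == brute_force_otsu(img)
        assert 60 < th < 140


    def test_uniform_degenerate(self):
        counts, _ = T.histogram(np.full((8, 8), 99.0))
        assert T.otsu_threshold(counts) == 99

    def test_matches_brute_force(self):
        for img in random_test_images(20, seed=5):
            counts, _ = T.histogram(img)
            assert T.otsu_threshold(counts) == brute_force_otsu(img)


class TestKapur:
    def test_two_spike_histogram(self):
        img = np.concatenate([np.full(50, 50.0), np.full(50, 200.0)])
        counts, _ = T.histogram(img.reshape(10, 10))
        assert 50 <= T.kapur_threshold(counts) <= 199

    def test_uniform_degenerate(self):
        counts, _ = T.histogram(np.full((8, 8), 42.0))
        assert T.kapur_threshold(counts) == 42

    def test_matches_brute_force(self):
        for img in random_test_images(20, seed=6):
            counts, _ = T.histogram(img)
            assert T.kapur_threshold(counts) == brute_force_kapur(img)


class TestGrayFeature:
    def test_disc_plateau_midpoint(self):
        img, disc = disc_image(40.0, 220.0)
        th = T.gray_feature_threshold(img)
        # feature is constant over th in [40, 219]; midpoint of that run
        assert th == 129
        assert np.array_equal(T.apply_threshold(img, th), disc)

    def test_two_level_plateau_spans_gap(self):
        img = np.where(np.arange(256).reshape(16, 16) < 128, 30.0, 170.0)
        th = T.gray_feature_threshold(img)
        assert 30 <= th < 170

    def test_uniform_falls_back(self):
        img = np.full((16, 16), 90.0)
        assert T.gray_feature_threshold(img) == 90  # Otsu degenerate value


class TestCrossEntropyDistance:
    def test_zero_for_exact_two_level_split(self):
        img, disc = disc_image()
        assert T.cross_entropy_distance(img, disc) == 0.0

    def test_nonnegative_on_random_masks(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(1, 255, (20, 20))
        for _ in range(20):
            mask = (rng.random((20, 20)) < 0.4).astype(np.uint8)
            if 0 < mask.sum() < mask.size:
                assert T.cross_entropy_distance(img, mask) >= -1e-12

    def test_hand_computed_tiny_example(self):
        img = np.array([[1.0, 2.0], [2.0, 3.0]])
        mask = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        # class means: fg 1, bg 7/3; Dist = sum I ln(I/S)
        expected = (1 * np.log(1 / 1.0)
                    + 2 * 2 * np.log(2 / (7 / 3))
                    + 3 * np.log(3 / (7 / 3)))
        assert T.cross_entropy_distance(img, mask) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_mask_is_infinite(self):
        img = np.random.default_rng(8).uniform(0, 255, (8, 8))
        assert T.cross_entropy_distance(img, np.zeros((8, 8), np.uint8)) == np.inf
        assert T.cross_entropy_distance(img, np.ones((8, 8), np.uint8)) == np.inf


class TestHarrisHawks:
    def test_finds_exact_split_of_two_level_image(self):
        img, disc = disc_image(40.0, 220.0)
        for seed in (0, 1, 2):
            th = T.hho_threshold(img, seed=seed)
            mask = T.apply_threshold(img, th)
            assert np.array_equal(mask, disc)
            assert T.cross_entropy_distance(img, mask) == 0.0

    def test_deterministic_given_seed(self):
        img = np.random.default_rng(9).uniform(0, 255, (32, 32))
        assert T.hho_threshold(img, seed=123) == T.hho_threshold(img, seed=123)

    def test_matches_exhaustive_on_few_level_image(self):
        rng = np.random.default_rng(10)
        levels = np.array([30.0, 90.0, 150.0, 210.0])
        img = levels[rng.integers(0, 4, size=(40, 40))]
        exhaustive = min(
            T.cross_entropy_distance(img, T.apply_threshold(img, th))
            for th in range(256)
        )
        for seed in (0, 1, 2):
            th = T.hho_threshold(img, seed=seed)
            fit = T.cross_entropy_distance(img, T.apply_threshold(img, th))
            assert fit <= exhaustive + 1e-9

    def test_rejects_bad_parameters(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError):
            T.hho_threshold(img, pop=1)


def test_thresholds_recover_clean_synthetic_lesion():
    """All four selectors segment an artefact-free lesion fixture well."""
    spec = synthetic.FixtureSpec(seed=21, supersample=1)
    img, truth = synthetic.generate(spec)
    counts, _ = T.histogram(img)
    from lesionsemble.evaluation import dice
    for th in (T.otsu_threshold(counts), T.kapur_threshold(counts),
               T.gray_feature_threshold(img), T.hho_threshold(img, seed=0)):
        assert dice(T.apply_threshold(img, th), truth) > 0.95
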