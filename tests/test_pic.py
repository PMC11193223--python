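"""Entropy, bokeh reintroduction, AIC/SIC curves, aggregation, random control."""

import numpy as np
import pytest

from medsal import (
    LinearModelHandle,
    PICCurve,
    SaliencyMap,
    aggregate_pic,
    blur_baseline,
    compute_pic_curve,
    image_entropy,
    normalized_information_level,
    random_saliency,
    reintroduce_pixels,
)
from medsal.pic import default_sigma


class TestImageEntropy:
    def test_constant_image_zero_bits(self):
        assert image_entropy(np.full((16, 16, 1), 0.37)).bits == 0.0

    def test_two_equal_levels_one_bit(self):
        img = np.zeros((16, 16, 1))
        img[:8] = 1.0
        assert abs(image_entropy(img).bits - 1.0) < 1e-12

    def test_uniform_256_levels_eight_bits(self):
        centers = (np.arange(256) + 0.5) / 256
        img = centers.reshape(16, 16, 1)
        assert abs(image_entropy(img, bins=256).bits - 8.0) < 1e-12

    def test_bounded_by_log2_bins(self, rng):
        e = image_entropy(rng.uniform(size=(32, 32, 1)), bins=64)
        assert 0 <= e.bits <= 6.0

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            image_entropy(np.full((4, 4, 1), 0.5), bins=1)


class TestBlurBaseline:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32, 1), 0.4)
        np.testing.assert_allclose(blur_baseline(img, 8.0), img, atol=1e-12)

    def test_blur_reduces_entropy_on_phantoms(self, phantoms):
        for s in phantoms[:50]:
            assert (
                image_entropy(blur_baseline(s.image, 8.0)).bits
                <= image_entropy(s.image).bits
            )

    def test_extreme_sigma_flattens(self, phantoms):
        for s in phantoms[:5]:
            b = blur_baseline(s.image, float(s.image.shape[1]))
            assert b.max() - b.min() <= 0.05

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            blur_baseline(np.full((8, 8, 1), 0.5), 0.0)


class TestReintroducePixels:
    def test_endpoints_bit_exact(self, phantoms):
        s = phantoms[0]
        blurred = blur_baseline(s.image, 8.0)
        sal = random_saliency(64, 64, seed=0)
        np.testing.assert_array_equal(
            reintroduce_pixels(s.image, blurred, sal, 0.0).pixels, blurred
        )
        np.testing.assert_array_equal(
            reintroduce_pixels(s.image, blurred, sal, 1.0).pixels, s.image
        )

    def test_hand_built_ranking_restores_exact_pixels(self):
        original = np.arange(16, dtype=float).reshape(4, 4, 1) / 16
        blurred = np.full((4, 4, 1), 0.5)
        ranks = np.array(
            [[9, 1, 2, 15], [3, 4, 5, 6], [7, 8, 0, 10], [11, 12, 13, 14]], dtype=float
        )
        bokeh = reintroduce_pixels(original, blurred, SaliencyMap(ranks / 16, "m"), 0.25)
        top4 = ranks >= 12  # values 12,13,14,15
        np.testing.assert_array_equal(bokeh.pixels[top4], original[top4])
        np.testing.assert_array_equal(bokeh.pixels[~top4], blurred[~top4])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reintroduce_pixels(
                np.full((4, 4, 1), 0.5), np.full((8, 8, 1), 0.5),
                SaliencyMap(np.zeros((4, 4)), "m"), 0.5,
            )


class TestInformationLevel:
    def test_anchors_and_midpoint(self):
        assert normalized_information_level(2.0, 2.0, 6.0) == 0.0
        assert normalized_information_level(6.0, 2.0, 6.0) == 1.0
        assert normalized_information_level(4.0, 2.0, 6.0) == 0.5

    def test_degenerate_falls_back_to_fraction(self):
        assert normalized_information_level(1.0, 3.0, 2.0, fraction_reintroduced=0.4) == 0.4


class TestPICCurve:
    def test_sic_is_one_at_full_image(self, fixture_model, holdout_samples):
        s = holdout_samples[0]
        sal = random_saliency(64, 64, seed=3)
        curve = compute_pic_curve(fixture_model, s.image, s.label, sal, "SIC")
        assert curve.x[-1] == 1.0 and curve.y[-1] == 1.0

    def test_constant_model_aic_is_flat_indicator(self, rng):
        model = LinearModelHandle(np.zeros((3, 16, 16, 1)), biases=np.array([0.0, 1.0, 0.0]))
        img = rng.uniform(size=(16, 16, 1))
        sal = random_saliency(16, 16, seed=0)
        for label, expect in ((1, 1.0), (0, 0.0)):
            curve = compute_pic_curve(model, img, label, sal, "AIC")
            assert set(curve.y) == {expect}
            assert abs(curve.auc - expect) < 1e-12

    def test_aic_at_full_image_equals_correctness(self, fixture_model, holdout_samples):
        from medsal import gradcam

        for s in holdout_samples[:20]:
            sal = gradcam(fixture_model, s.image, s.label, fixture_model.last_conv_layer)
            curve = compute_pic_curve(fixture_model, s.image, s.label, sal, "AIC")
            correct = float(fixture_model.predict(s.image[None])[0].argmax() == s.label)
            assert curve.y[-1] == correct

    def test_information_level_monotone_in_fraction(self, fixture_model, phantoms):
        s = phantoms[1]
        blurred = blur_baseline(s.image, default_sigma(64))
        sal = random_saliency(64, 64, seed=1)
        h_o = image_entropy(s.image).bits
        h_b = image_entropy(blurred).bits
        infos = []
        for f in (0.0, 0.1, 0.3, 0.6, 1.0):
            bok = reintroduce_pixels(s.image, blurred, sal, f)
            infos.append(
                normalized_information_level(image_entropy(bok.pixels).bits, h_b, h_o, f)
            )
        assert all(a <= b + 1e-12 for a, b in zip(infos, infos[1:]))

    def test_fractions_must_span_unit_interval(self, fixture_model, holdout_samples):
        s = holdout_samples[0]
        with pytest.raises(ValueError):
            compute_pic_curve(fixture_model, s.image, s.label,
                              random_saliency(64, 64, 0), "AIC", fractions=(0.0, 0.5))

    def test_auc_matches_trapezoid_invariant(self):
        curve = PICCurve(x=[0.0, 0.4, 1.0], y=[0.2, 0.6, 1.0], mode="SIC")
        assert abs(curve.auc - np.trapezoid(curve.y, curve.x)) < 1e-9

    def test_nonmonotone_x_rejected(self):
        with pytest.raises(ValueError):
            PICCurve(x=[0.0, 0.5, 0.5], y=[0, 1, 1], mode="AIC")


class TestAggregatePIC:
    def _curve_at_bin_centers(self, n_bins, values, mode="SIC"):
        centers = (np.arange(n_bins) + 0.5) / n_bins
        x = np.concatenate([[0.0], centers, [1.0]])
        y = np.concatenate([[values[0]], values, [values[-1]]])
        return PICCurve(x=x, y=y, mode=mode)

    def test_single_aligned_curve_reproduced(self, rng):
        curve = self._curve_at_bin_centers(10, rng.uniform(size=10))
        agg = aggregate_pic([curve], n_bins=10)
        np.testing.assert_array_equal(agg.x, curve.x)
        np.testing.assert_array_equal(agg.y, curve.y)
        assert abs(agg.auc - curve.auc) < 1e-9

    def test_two_identical_curves_reproduced(self, rng):
        curve = self._curve_at_bin_centers(8, rng.uniform(size=8))
        agg = aggregate_pic([curve, curve], n_bins=8)
        np.testing.assert_allclose(agg.y, curve.y)

    def test_binned_medians_match_brute_force(self, rng):
        curves = []
        for _ in range(10):
            x = np.sort(rng.uniform(0.01, 0.99, size=6))
            curves.append(
                PICCurve(x=np.concatenate([[0.0], x, [1.0]]),
                         y=rng.uniform(size=8), mode="SIC")
            )
        n_bins = 5
        agg = aggregate_pic(curves, n_bins=n_bins, statistic="median")
        xs = np.concatenate([c.x for c in curves])
        ys = np.concatenate([c.y for c in curves])
        for b in range(n_bins):
            lo, hi = b / n_bins, (b + 1) / n_bins
            sel = ys[(xs > 0) & (xs < 1) & (xs >= lo) & (xs < hi)]
            if sel.size:
                assert abs(agg.y[1 + b] - np.median(sel)) < 1e-12

    def test_counts_sum_to_total_points(self, rng):
        curves = [self._curve_at_bin_centers(4, rng.uniform(size=4)) for _ in range(3)]
        agg = aggregate_pic(curves, n_bins=4)
        assert agg.counts.sum() == sum(len(c.x) for c in curves)

    def test_mixed_modes_rejected(self):
        a = PICCurve(x=[0.0, 1.0], y=[0.0, 1.0], mode="AIC")
        b = PICCurve(x=[0.0, 1.0], y=[0.0, 1.0], mode="SIC")
        with pytest.raises(ValueError):
            aggregate_pic([a, b])


class TestRandomSaliency:
    def test_seed_reproducible(self):
        np.testing.assert_array_equal(
            random_saliency(32, 32, seed=5).values, random_saliency(32, 32, seed=5).values
        )

    def test_different_seeds_differ_almost_everywhere(self):
        a = random_saliency(32, 32, seed=1).values
        b = random_saliency(32, 32, seed=2).values
        assert (a != b).mean() >= 0.99

    def test_mean_near_half(self):
        assert 0.45 <= random_saliency(64, 64, seed=9).values.mean() <= 0.55
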