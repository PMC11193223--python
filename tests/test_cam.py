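"""CAM-family operators: GradCAM, GradCAM++, ScoreCAM."""

import numpy as np
import pytest
from skimage.transform import resize

from medsal import gradcam, gradcam_pp, minmax_normalize, scorecam
from medsal.adapter import ModelHandle


class StubLayerModel(ModelHandle):
    """Handle with prescribed layer activations/gradients and logits.

    Lets the CAM closed-form cases (uniform gradients, sign patterns,
    singleton channels) be constructed exactly.
    """

    def __init__(self, acts, grads, image_shape=(16, 16, 1), logit_fn=None):
        self.acts = np.asarray(acts, dtype=float)
        self.grads = np.asarray(grads, dtype=float)
        self.num_classes = 3
        self.image_shape = image_shape
        self.gradient_calls = 0
        # default scoring: mean intensity decides class-0 logit
        self.logit_fn = logit_fn or (
            lambda batch: np.stack(
                [batch.mean(axis=(1, 2, 3)), 0 * batch.mean(axis=(1, 2, 3)),
                 0 * batch.mean(axis=(1, 2, 3))], axis=1
            )
        )

    def logits(self, images):
        return self.logit_fn(np.asarray(images, dtype=float))

    def input_gradients(self, images, class_index, of="logit"):
        self.gradient_calls += 1
        raise AssertionError("gradient entry point invoked")

    @property
    def conv_layer_names(self):
        return ["conv"]

    def layer_output(self, images, layer):
        return self.acts[None]

    def layer_activations_and_gradients(self, image, class_index, layer):
        self.gradient_calls += 1
        return self.acts, self.grads


def upsampled_norm(arr, shape):
    return minmax_normalize(
        resize(np.maximum(arr, 0), shape, order=1, mode="edge",
               anti_aliasing=False, preserve_range=True)
    )


@pytest.fixture()
def image16(rng):
    return rng.uniform(0.2, 0.8, size=(16, 16, 1))


class TestGradCAM:
    def test_single_channel_positive_gradient_collapses(self, rng, image16):
        acts = rng.uniform(size=(4, 4, 1))
        grads = np.full((4, 4, 1), 0.5)
        model = StubLayerModel(acts, grads)
        sal = gradcam(model, image16, 0, "conv")
        np.testing.assert_allclose(sal.values, upsampled_norm(acts[..., 0], (16, 16)))

    def test_nonpositive_weights_give_zero_map(self, rng, image16):
        acts = rng.uniform(size=(4, 4, 3))
        grads = -np.ones((4, 4, 3))  # all channel weights negative
        sal = gradcam(StubLayerModel(acts, grads), image16, 0, "conv")
        np.testing.assert_array_equal(sal.values, np.zeros((16, 16)))

    def test_matches_literal_recomputation(self, fixture_model, holdout_samples):
        s = holdout_samples[0]
        layer = fixture_model.last_conv_layer
        sal = gradcam(fixture_model, s.image, s.label, layer)
        acts, grads = fixture_model.layer_activations_and_gradients(s.image, s.label, layer)
        raw = np.maximum((acts * grads.mean(axis=(0, 1))).sum(axis=-1), 0)
        np.testing.assert_allclose(sal.values, upsampled_norm(raw, s.image.shape[:2]))

    def test_non_spatial_layer_rejected(self, fixture_model, holdout_samples):
        with pytest.raises(KeyError):
            gradcam(fixture_model, holdout_samples[0].image, 0, "dense")


class TestGradCAMpp:
    def test_uniform_positive_gradient_single_channel(self, rng, image16):
        acts = rng.uniform(0.1, 1.0, size=(4, 4, 1))
        grads = np.full((4, 4, 1), 0.3)
        sal = gradcam_pp(StubLayerModel(acts, grads), image16, 0, "conv")
        np.testing.assert_allclose(
            sal.values, upsampled_norm(acts[..., 0], (16, 16)), atol=1e-12
        )

    def test_nonpositive_gradients_give_zero_map(self, rng, image16):
        acts = rng.uniform(size=(4, 4, 2))
        grads = -rng.uniform(0.1, 1.0, size=(4, 4, 2))
        sal = gradcam_pp(StubLayerModel(acts, grads), image16, 0, "conv")
        np.testing.assert_array_equal(sal.values, np.zeros((16, 16)))

    def test_matches_independent_alpha_formula(self, fixture_model, holdout_samples):
        s = holdout_samples[1]
        layer = fixture_model.last_conv_layer
        sal = gradcam_pp(fixture_model, s.image, s.label, layer)
        acts, g = fixture_model.layer_activations_and_gradients(s.image, s.label, layer)
        # literal transcription of the closed form, channel by channel
        K = acts.shape[-1]
        raw = np.zeros(acts.shape[:2])
        for k in range(K):
            gk, ak = g[..., k], acts[..., k]
            denom = 2 * gk**2 + (ak * gk**3).sum()
            alpha = np.where(np.abs(denom) > 1e-12, gk**2 / np.where(denom == 0, 1, denom), 0)
            w = (alpha * np.maximum(gk, 0)).sum()
            raw += w * ak
        np.testing.assert_allclose(
            sal.values, upsampled_norm(raw, s.image.shape[:2]), rtol=1e-5, atol=1e-12
        )


class TestScoreCAM:
    def test_singleton_channel_ignores_score(self, rng, image16):
        acts = rng.uniform(size=(4, 4, 1))
        sal = scorecam(StubLayerModel(acts, np.zeros((4, 4, 1))), image16, 0, "conv")
        np.testing.assert_allclose(sal.values, upsampled_norm(acts[..., 0], (16, 16)))

    def test_equal_scores_give_uniform_weighting(self, rng, image16):
        acts = rng.uniform(size=(4, 4, 3))
        # constant-logit model: every masked forward scores identically
        model = StubLayerModel(acts, np.zeros((4, 4, 3)),
                               logit_fn=lambda b: np.zeros((len(b), 3)))
        sal = scorecam(model, image16, 0, "conv")
        np.testing.assert_allclose(sal.values, upsampled_norm(acts.mean(axis=-1), (16, 16)))

    def test_matches_unbatched_brute_force(self, fixture_model, holdout_samples):
        s = holdout_samples[2]
        layer = fixture_model.last_conv_layer
        sal = scorecam(fixture_model, s.image, s.label, layer, batch_size=5)
        acts = fixture_model.layer_output(s.image, layer)[0]
        base = fixture_model.predict(np.zeros_like(s.image)[None])[0, s.label]
        scores, valid = [], []
        for k in range(acts.shape[-1]):
            a = acts[..., k]
            if a.max() <= a.min():
                continue
            mask = resize(minmax_normalize(a), s.image.shape[:2], order=1,
                          mode="edge", anti_aliasing=False, preserve_range=True)
            p = fixture_model.predict((s.image * mask[..., None])[None])[0, s.label]
            scores.append(p - base)
            valid.append(k)
        w = np.zeros(acts.shape[-1])
        e = np.exp(np.array(scores) - max(scores))
        w[valid] = e / e.sum()
        np.testing.assert_allclose(
            sal.values, upsampled_norm(acts @ w, s.image.shape[:2]), atol=1e-12
        )

    def test_gradient_free(self, fixture_model, holdout_samples):
        s = holdout_samples[0]
        before = fixture_model.gradient_calls
        scorecam(fixture_model, s.image, s.label, fixture_model.last_conv_layer)
        assert fixture_model.gradient_calls == before


class TestMapContract:
    def test_maps_bounded_and_aligned(self, fixture_model, holdout_samples):
        s = holdout_samples[3]
        layer = fixture_model.last_conv_layer
        for op in (gradcam, gradcam_pp, scorecam):
            sal = op(fixture_model, s.image, s.label, layer)
            assert sal.values.shape == s.image.shape[:2]
            assert sal.values.min() >= 0 and sal.values.max() <= 1

    def test_argmax_stable_under_normalize_order(self, fixture_model, holdout_samples):
        s = holdout_samples[3]
        layer = fixture_model.last_conv_layer
        acts, grads = fixture_model.layer_activations_and_gradients(s.image, s.label, layer)
        raw = np.maximum((acts * grads.mean(axis=(0, 1))).sum(axis=-1), 0)
        H, W = s.image.shape[:2]
        a = upsampled_norm(raw, (H, W))
        b = resize(minmax_normalize(np.maximum(raw, 0)), (H, W), order=1,
                   mode="edge", anti_aliasing=False, preserve_range=True)
        pa = np.unravel_index(a.argmax(), a.shape)
        pb = np.unravel_index(b.argmax(), b.shape)
        stride = H // raw.shape[0]
        assert abs(pa[0] - pb[0]) <= stride and abs(pa[1] - pb[1]) <= stride
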