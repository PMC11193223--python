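"""Class-activation-map attribution: GradCAM, GradCAM++, ScoreCAM.

All three weight the channels of a convolutional feature layer into a coarse
localization heatmap, differing only in how the per-channel weights are
obtained: spatial-mean gradients (GradCAM), closed-form higher-order
gradient coefficients (GradCAM++), or confidence scores of channel-masked
inputs (ScoreCAM — gradient-free by construction).  Maps are ReLU'd,
bilinearly upsampled to the input resolution and min-max normalized to
[0, 1].
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .adapter import ModelHandle, validate_image
from .maps import SaliencyMap, minmax_normalize


def _upsample(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    return resize(arr, shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def _finalize(raw: np.ndarray, shape: tuple[int, int], method: str, meta: dict) -> SaliencyMap:
    up = _upsample(np.maximum(raw, 0.0), shape)
    return SaliencyMap(minmax_normalize(up), method, signed=False, meta=meta)


def gradcam(model: ModelHandle, image: np.ndarray, class_index: int, layer: str) -> SaliencyMap:
    """Channel weights = spatial mean of the class-score gradient at the layer."""
    image = validate_image(image)
    acts, grads = model.layer_activations_and_gradients(image, class_index, layer)
    weights = grads.mean(axis=(0, 1))  # (K,)
    raw = acts @ weights  # (h', w')
    return _finalize(raw, image.shape[:2], "gradcam", {"weights": weights})


def gradcam_pp(model: ModelHandle, image: np.ndarray, class_index: int, layer: str) -> SaliencyMap:
    """GradCAM++ pixelwise-weighted channel importance.

    Uses the standard closed form for the exponential-score formulation in
    which higher-order derivatives reduce to powers of the first gradient:
    ``alpha = g^2 / (2 g^2 + sum_spatial(A * g^3))`` with zero where the
    denominator vanishes, and ``w_k = sum_spatial(alpha * relu(g))``.
    """
    image = validate_image(image)
    acts, g = model.layer_activations_and_gradients(image, class_index, layer)
    g2 = g * g
    g3 = g2 * g
    denom = 2.0 * g2 + np.sum(acts * g3, axis=(0, 1), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    weights = np.sum(alpha * np.maximum(g, 0.0), axis=(0, 1))  # (K,)
    raw = acts @ weights
    return _finalize(raw, image.shape[:2], "gradcam++", {"weights": weights})


def scorecam(
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    layer: str,
    batch_size: int = 16,
    baseline: np.ndarray | None = None,
) -> SaliencyMap:
    """Confidence-score channel weighting; uses only forward passes.

    Each activation channel, min-max normalized and upsampled, masks the
    input; the channel's score is the class probability of the masked input
    minus that of the baseline, and weights are the softmax over those
    scores.  Constant channels are skipped with weight zero.
    """
    image = validate_image(image)
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if baseline is None:
        baseline = np.zeros_like(image)
    acts = model.layer_output(image, layer)[0]  # (h', w', K)
    K = acts.shape[-1]
    H, W = image.shape[:2]

    valid = [k for k in range(K) if acts[..., k].max() > acts[..., k].min()]
    masked = np.empty((len(valid), H, W, image.shape[2]))
    for j, k in enumerate(valid):
        mask = _upsample(minmax_normalize(acts[..., k]), (H, W))
        masked[j] = image * mask[..., None]

    base_p = float(model.predict(baseline[None])[0, class_index])
    scores = np.empty(len(valid))
    for start in range(0, len(valid), batch_size):
        probs = model.predict(masked[start : start + batch_size])
        scores[start : start + batch_size] = probs[:, class_index] - base_p

    weights = np.zeros(K)
    if valid:
        e = np.exp(scores - scores.max())
        weights[valid] = e / e.sum()
    raw = acts @ weights
    return _finalize(raw, (H, W), "scorecam", {"weights": weights, "scores": scores})
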