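"""Performance Information Curves: the quantitative saliency evaluation layer.

Starting from a fully blurred copy of an image, pixels ranked most salient
by a method are incrementally restored ("bokeh" images).  Each composite is
scored by its normalized information level — Shannon entropy of its
intensity histogram, rescaled between the blurred and original entropies —
and by the model's performance on it: classification correctness (AIC) or
the softmax score of the originally predicted class relative to its score on
the original image (SIC).  Curves are aggregated across images by binning
and summarized by trapezoidal AUC.  A uniform-random saliency map provides
the control baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .adapter import ModelHandle, validate_image
from .maps import SaliencyMap

#: fraction-of-pixels-restored schedule used for curve sampling
DEFAULT_FRACTIONS = (
    0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.07, 0.10, 0.13, 0.21, 0.34, 0.5, 0.75, 1.0,
)

#: blur strength: 16 px at 224x224, scaled proportionally to image height
def default_sigma(height: int) -> float:
    return 16.0 * height / 224.0


@dataclass
class EntropyValue:
    """Shannon entropy of an intensity histogram, in bits."""

    bits: float
    bins: int


def image_entropy(image: np.ndarray, bins: int = 256) -> EntropyValue:
    """Histogram entropy H = -sum p_i log2 p_i over ``bins`` equal-width bins.

    The histogram spans [0, 1] with density normalization; densities are
    converted to probability masses by multiplying with the bin width.
    Multi-channel images are pooled into a single histogram.
    """
    image = validate_image(image)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    density, edges = np.histogram(image.ravel(), bins=bins, range=(0.0, 1.0), density=True)
    p = density * np.diff(edges)
    p = p[p > 0]
    return EntropyValue(bits=float(-(p * np.log2(p)).sum()), bins=bins)


def compression_entropy(image: np.ndarray, bins: int = 256) -> EntropyValue:
    """Alternative estimator: zlib-compressed size of the quantized image.

    Returned on the same object for interface parity; ``bits`` is the
    compressed length in bits per pixel.  Provided for comparison only —
    the histogram estimator is the default everywhere.
    """
    import zlib

    image = validate_image(image)
    q = np.clip((image * (bins - 1)).round(), 0, bins - 1).astype(np.uint8)
    nbytes = len(zlib.compress(q.tobytes(), level=9))
    return EntropyValue(bits=8.0 * nbytes / q.size, bins=bins)


def blur_baseline(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with reflective boundaries, clipped to [0, 1]."""
    image = validate_image(image)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = np.empty_like(image)
    for c in range(image.shape[-1]):
        out[..., c] = gaussian_filter(image[..., c], sigma=sigma, mode="reflect")
    return np.clip(out, 0.0, 1.0)


@dataclass
class BokehImage:
    """Blurred image with the top-salient pixels restored from the original."""

    pixels: np.ndarray
    fraction_reintroduced: float
    information_level: float = float("nan")


def reintroduce_pixels(
    original: np.ndarray,
    blurred: np.ndarray,
    saliency: SaliencyMap,
    fraction: float,
) -> BokehImage:
    """Restore the ``round(fraction * H * W)`` top-|saliency| pixels.

    Ranking uses |value| so signed maps are handled; ties break in
    row-major order.  All channels of a selected pixel are restored.
    """
    original = validate_image(original)
    blurred = validate_image(blurred)
    if original.shape != blurred.shape:
        raise ValueError("original and blurred shapes differ")
    if saliency.values.shape != original.shape[:2]:
        raise ValueError("saliency shape does not match image")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    n = original.shape[0] * original.shape[1]
    k = int(round(fraction * n))
    keep = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(-saliency.magnitude.ravel(), kind="stable")
        keep[order[:k]] = True
    keep = keep.reshape(original.shape[:2])[..., None]
    pixels = np.where(keep, original, blurred)
    return BokehImage(pixels=pixels, fraction_reintroduced=fraction)


def normalized_information_level(
    bokeh_entropy: float, blurred_entropy: float, original_entropy: float,
    fraction_reintroduced: float | None = None,
) -> float:
    """(H_bokeh - H_blur) / (H_orig - H_blur), clipped to [0, 1].

    If the original is no more entropic than its blur (degenerate image),
    falls back to the pixel fraction restored.
    """
    if original_entropy <= blurred_entropy:
        return float(fraction_reintroduced if fraction_reintroduced is not None else 0.0)
    x = (bokeh_entropy - blurred_entropy) / (original_entropy - blurred_entropy)
    return float(np.clip(x, 0.0, 1.0))


@dataclass
class PICCurve:
    """Sampled (information level, performance) pairs with trapezoidal AUC."""

    x: np.ndarray
    y: np.ndarray
    mode: str
    auc: float = field(init=False)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.mode not in ("AIC", "SIC"):
            raise ValueError("mode must be 'AIC' or 'SIC'")
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise ValueError("curve needs >= 2 (x, y) points")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        self.auc = float(np.trapezoid(self.y, self.x))


def compute_pic_curve(
    model: ModelHandle,
    image: np.ndarray,
    label: int,
    saliency: SaliencyMap,
    mode: str = "AIC",
    fractions=DEFAULT_FRACTIONS,
    sigma: float | None = None,
    x_axis: str = "entropy",
    bins: int = 256,
) -> PICCurve:
    """Build one AIC or SIC curve for one image and saliency map.

    AIC performance is the 0/1 indicator that the model classifies the
    bokeh image as ``label``.  SIC performance is the softmax probability
    the bokeh image gives to the class the model predicts on the *original*
    image, divided by that class's probability on the original, clipped to
    [0, 1].  ``x_axis='fraction'`` replaces the entropy-based information
    level by the raw fraction of pixels restored.
    """
    image = validate_image(image)
    fractions = sorted(float(f) for f in fractions)
    if fractions[0] != 0.0 or fractions[-1] != 1.0:
        raise ValueError("fractions must include 0 and 1")
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    if x_axis not in ("entropy", "fraction"):
        raise ValueError("x_axis must be 'entropy' or 'fraction'")
    if sigma is None:
        sigma = default_sigma(image.shape[0])
    blurred = blur_baseline(image, sigma)
    h_orig = image_entropy(image, bins).bits
    h_blur = image_entropy(blurred, bins).bits

    bokehs = [reintroduce_pixels(image, blurred, saliency, f) for f in fractions]
    batch = np.stack([b.pixels for b in bokehs])
    probs = model.predict(batch)
    # the fraction-1 bokeh IS the original image; using its row as the SIC
    # reference makes the self-normalized score exactly 1 there
    probs_orig = probs[fractions.index(1.0)]
    ref_class = int(np.argmax(probs_orig))
    ref_prob = float(probs_orig[ref_class])

    xs, ys = [], []
    for b, p in zip(bokehs, probs):
        if x_axis == "entropy":
            h_b = image_entropy(b.pixels, bins).bits
            x = normalized_information_level(h_b, h_blur, h_orig, b.fraction_reintroduced)
        else:
            x = b.fraction_reintroduced
        b.information_level = x
        if mode == "AIC":
            y = float(np.argmax(p) == label)
        else:
            y = float(np.clip(p[ref_class] / ref_prob, 0.0, 1.0)) if ref_prob > 0 else 0.0
        xs.append(x)
        ys.append(y)

    # sort by x, deduplicate keeping the max performance per x
    by_x: dict[float, float] = {}
    for x, y in zip(xs, ys):
        by_x[x] = max(y, by_x.get(x, -np.inf))
    xs_sorted = sorted(by_x)
    return PICCurve(
        x=np.array(xs_sorted), y=np.array([by_x[x] for x in xs_sorted]), mode=mode
    )


@dataclass
class AggregatedPIC:
    """Binned aggregate of many PIC curves of the same mode."""

    x: np.ndarray
    y: np.ndarray
    counts: np.ndarray
    mode: str
    auc: float
    interpolated_bins: list[int]


def aggregate_pic(
    curves: list[PICCurve], n_bins: int = 20, statistic: str = "median"
) -> AggregatedPIC:
    """Pool all curve points, bin by x over [0, 1], aggregate y per bin.

    Points at exactly x=0 and x=1 pin the curve endpoints; empty interior
    bins are linearly interpolated and flagged.  AUC is the trapezoid over
    the resulting [0, 1] curve.
    """
    if not curves:
        raise ValueError("need at least one curve")
    modes = {c.mode for c in curves}
    if len(modes) > 1:
        raise ValueError(f"mixed curve modes: {modes}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    agg = np.median if statistic == "median" else np.mean
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")

    xs = np.concatenate([c.x for c in curves])
    ys = np.concatenate([c.y for c in curves])

    at0, at1 = ys[xs == 0.0], ys[xs == 1.0]
    y0 = float(agg(at0)) if at0.size else np.nan
    y1 = float(agg(at1)) if at1.size else np.nan

    interior = (xs > 0.0) & (xs < 1.0)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    binned = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    idx = np.minimum((xs[interior] * n_bins).astype(int), n_bins - 1)
    for b in range(n_bins):
        sel = ys[interior][idx == b]
        counts[b] = sel.size
        if sel.size:
            binned[b] = agg(sel)

    x_full = np.concatenate([[0.0], centers, [1.0]])
    y_full = np.concatenate([[y0], binned, [y1]])
    empty = np.flatnonzero(np.isnan(y_full))
    known = np.flatnonzero(~np.isnan(y_full))
    if known.size == 0:
        raise ValueError("no points to aggregate")
    y_full[empty] = np.interp(x_full[empty], x_full[known], y_full[known])
    interpolated = [int(i) - 1 for i in empty if 0 < i < n_bins + 1]

    auc = float(np.trapezoid(y_full, x_full))
    return AggregatedPIC(
        x=x_full, y=y_full,
        counts=np.concatenate([[at0.size], counts, [at1.size]]),
        mode=curves[0].mode, auc=auc, interpolated_bins=interpolated,
    )


def random_saliency(height: int, width: int, seed: int = 0) -> SaliencyMap:
    """i.i.d. Uniform(0, 1) control map, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return SaliencyMap(rng.uniform(size=(height, width)), "random", signed=False,
                       meta={"seed": seed})
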