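"""Region-ranked attribution (XRAI) over integrated-gradients maps.

Pixel attributions (positive part of IG summed over black and white
baselines) are pooled over an oversegmentation of the image, and segments
are selected greedily by attribution density over their not-yet-selected
pixels.  The output map encodes selection order: earlier-selected regions
receive strictly higher values.  ``fast_xrai_mask`` thresholds any saliency
map into its top-area-fraction binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import felzenszwalb

from .adapter import ModelHandle, validate_image
from .gradients import PathSpec, black_baseline, integrated_gradients, white_baseline
from .maps import SaliencyMap, minmax_normalize

DEFAULT_SCALES = (50.0, 100.0, 150.0, 250.0)
MIN_SEGMENT_PX = 20


@dataclass
class SegmentSet:
    """Oversegmentation: possibly-overlapping pixel-index sets covering the image."""

    segments: list[np.ndarray]  # flat pixel indices into H*W
    shape: tuple[int, int]
    scales: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        n = self.shape[0] * self.shape[1]
        covered = np.zeros(n, dtype=bool)
        for seg in self.segments:
            if seg.size == 0:
                raise ValueError("empty segment")
            covered[seg] = True
        if not covered.all():
            raise ValueError("segments do not cover the image")


@dataclass
class RegionRanking:
    """Greedy selection order: (segment, marginal gain, cumulative area fraction)."""

    order: list[tuple[np.ndarray, float, float]]


def oversegment(
    image: np.ndarray,
    scales=DEFAULT_SCALES,
    min_size: int = MIN_SEGMENT_PX,
    sigma: float = 0.8,
) -> SegmentSet:
    """Felzenszwalb graph segmentation at several scales; segments overlap across scales."""
    image = validate_image(image)
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    gray = image.mean(axis=-1)
    segments: list[np.ndarray] = []
    for s in scales:
        labels = felzenszwalb(gray, scale=s, sigma=sigma, min_size=min_size)
        for lab in np.unique(labels):
            segments.append(np.flatnonzero(labels.ravel() == lab))
    return SegmentSet(segments=segments, shape=image.shape[:2], scales=scales)


def _region_attribution(model, image, class_index, path: PathSpec | None) -> np.ndarray:
    """Positive part of IG summed over black and white baselines, per pixel."""
    steps = path.steps if path is not None else 64
    total = np.zeros(image.shape[:2])
    for make_baseline in (black_baseline, white_baseline):
        spec = PathSpec(baseline=make_baseline(image), steps=steps)
        ig = integrated_gradients(model, image, class_index, path=spec)
        total += ig.meta["attributions"].sum(axis=-1)
    return np.maximum(total, 0.0)


def _greedy_rank(attr2d: np.ndarray, segset: SegmentSet) -> RegionRanking:
    """Repeatedly pick the segment with the highest attribution density over
    its not-yet-selected pixels; deterministic first-index tie-break."""
    flat = attr2d.ravel()
    n = flat.size
    selected = np.zeros(n, dtype=bool)
    remaining = list(enumerate(segset.segments))
    order = []
    covered = 0
    while covered < n and remaining:
        best = None
        for j, (idx, seg) in enumerate(remaining):
            new = seg[~selected[seg]]
            if new.size == 0:
                continue
            gain = flat[new].sum() / new.size
            if best is None or gain > best[0]:
                best = (gain, j, idx, new)
        if best is None:
            break
        gain, j, idx, new = best
        order.append((new, float(gain), (covered + new.size) / n))
        selected[new] = True
        covered += new.size
        remaining.pop(j)
    return RegionRanking(order=order)


def xrai(
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    path: PathSpec | None = None,
    segments: SegmentSet | None = None,
) -> SaliencyMap:
    """Region-ranked saliency encoding both density and selection order.

    Each selected region receives its attribution density (gain), capped so
    that values strictly decrease with selection order; a vanishing
    order-encoding term keeps the decrease strict even through zero-gain
    regions.  The piecewise-constant map is min-max normalized to [0, 1].
    """
    image = validate_image(image)
    if segments is None:
        segments = oversegment(image)
    if segments.shape != image.shape[:2]:
        raise ValueError("segment set shape does not match image")
    attr2d = _region_attribution(model, image, class_index, path)
    ranking = _greedy_rank(attr2d, segments)
    values = np.zeros(image.shape[:2]).ravel()
    max_gain = max((g for _, g, _ in ranking.order), default=0.0)
    tiny = 1e-6 * max_gain if max_gain > 0 else 1e-6
    cum_before, cap = 0.0, np.inf
    for new, gain, cum_after in ranking.order:
        cap = min(gain, cap)
        values[new] = cap + (1.0 - cum_before) * tiny
        cum_before = cum_after
    values = values.reshape(image.shape[:2])
    return SaliencyMap(
        minmax_normalize(values),
        "xrai",
        signed=False,
        meta={"ranking": ranking, "pixel_attribution": attr2d},
    )


def fast_xrai_mask(saliency: SaliencyMap, top_fraction: float) -> np.ndarray:
    """Binary mask of the top ``top_fraction`` of pixels by saliency rank.

    Area is exactly ``round(top_fraction * H * W)``; ties break in row-major
    order.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    values = saliency.magnitude
    n = values.size
    k = int(round(top_fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        order = np.argsort(-values.ravel(), kind="stable")
        mask[order[:k]] = True
    return mask.reshape(values.shape)


def fast_xrai(
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    path: PathSpec | None = None,
    scale: float = 100.0,
    top_fraction: float = 0.3,
) -> SaliencyMap:
    """Single-scale XRAI reduced to its top-area-fraction binary mask."""
    image = validate_image(image)
    segset = oversegment(image, scales=(scale,))
    full = xrai(model, image, class_index, path=path, segments=segset)
    mask = fast_xrai_mask(full, top_fraction)
    return SaliencyMap(
        mask.astype(float),
        "fast_xrai",
        signed=False,
        meta={"top_fraction": top_fraction, "scale": scale},
    )
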