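"""Pixel-level gradient and path-integration attribution operators.

Four operators share the adapter contract: vanilla gradient, integrated
gradients along a straight path, SmoothGrad averaging over noisy copies, and
a guided (adaptive-path) variant of integrated gradients that defers
high-gradient pixels to late in the path to suppress noise.

All path methods report their completeness gap — the absolute difference
between the summed attributions and the score difference between input and
baseline — in ``SaliencyMap.meta``; for exact Riemann integration the gap
tends to zero as the step count grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adapter import ModelHandle, validate_image
from .maps import SaliencyMap, channel_reduce


@dataclass
class PathSpec:
    """Integration path from a baseline image to the input.

    ``guided_fraction`` only applies to the guided path: the fraction of
    not-yet-final pixels moved toward the input at each step (the lowest
    |gradient| ones move first).
    """

    baseline: np.ndarray
    steps: int = 64
    path_kind: str = "straight"
    guided_fraction: float = 0.1

    def __post_init__(self):
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.path_kind not in ("straight", "guided"):
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        if not 0 < self.guided_fraction <= 1:
            raise ValueError("guided_fraction must lie in (0, 1]")


def black_baseline(image: np.ndarray) -> np.ndarray:
    return np.zeros_like(np.asarray(image, dtype=float))


def white_baseline(image: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(image, dtype=float))


def vanilla_gradient(
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    of: str = "logit",
    signed: bool = False,
) -> SaliencyMap:
    """Gradient of the class score w.r.t. the input pixels.

    The display map is the per-pixel max-|value| channel reduction; the
    signed per-channel tensor is kept in ``meta["attributions"]``.
    """
    image = validate_image(image)
    grad = model.input_gradients(image, class_index, of=of)[0]
    values = grad.sum(axis=-1) if signed else channel_reduce(grad)
    return SaliencyMap(values, "vanilla", signed=signed, meta={"attributions": grad})


def _completeness_gap(model, image, baseline, class_index, attr_sum) -> float:
    sx = float(model.logits(image)[0, class_index])
    s0 = float(model.logits(baseline)[0, class_index])
    return abs(attr_sum - (sx - s0))


def integrated_gradients(
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    path: PathSpec | None = None,
    of: str = "logit",
    batch_size: int = 64,
) -> SaliencyMap:
    """Straight-path integrated gradients with a midpoint Riemann sum.

    Attribution per pixel is
    ``(x - x0) * mean_k grad(x0 + ((k + 1/2)/steps)(x - x0))`` for
    ``k = 0..steps-1``; the midpoint rule keeps the completeness gap
    |sum(attr) - (S(x) - S(x0))| (reported in ``meta["completeness_gap"]``)
    second-order small in 1/steps.
    """
    image = validate_image(image)
    if path is None:
        path = PathSpec(baseline=black_baseline(image))
    if path.path_kind != "straight":
        raise ValueError("integrated_gradients requires a straight path")
    baseline = np.asarray(path.baseline, dtype=float)
    if baseline.shape != image.shape:
        raise ValueError("baseline shape must match image shape")
    delta = image - baseline
    alphas = (np.arange(path.steps) + 0.5) / path.steps  # segment midpoints
    grad_sum = np.zeros_like(image)
    for start in range(0, path.steps, batch_size):
        chunk = alphas[start : start + batch_size]
        points = baseline[None] + chunk[:, None, None, None] * delta[None]
        grad_sum += model.input_gradients(points, class_index, of=of).sum(axis=0)
    attr = delta * grad_sum / path.steps
    gap = _completeness_gap(model, image[None], baseline[None], class_index, float(attr.sum()))
    return SaliencyMap(
        channel_reduce(attr),
        "integrated_gradients",
        signed=False,
        meta={"attributions": attr, "completeness_gap": gap, "steps": path.steps},
    )


def smoothgrad(
    base_method,
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    n_samples: int = 16,
    noise_sigma: float | None = None,
    seed: int = 0,
    **base_kwargs,
) -> SaliencyMap:
    """Average of ``base_method`` maps over noisy copies of the input.

    Noise is i.i.d. Gaussian per pixel, clipped back to [0, 1]; sigma
    defaults to 0.15 × the input's intensity range.  Fully reproducible
    given ``seed``.
    """
    image = validate_image(image)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_sigma is None:
        noise_sigma = 0.15 * float(image.max() - image.min())
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    acc = None
    base = None
    for _ in range(n_samples):
        noisy = np.clip(image + rng.normal(0.0, noise_sigma, size=image.shape), 0.0, 1.0)
        m = base_method(model, noisy, class_index, **base_kwargs)
        base = m
        acc = m.values if acc is None else acc + m.values
    values = acc / n_samples
    return SaliencyMap(
        values,
        f"smoothgrad[{base.method}]",
        signed=base.signed,
        meta={"n_samples": n_samples, "noise_sigma": noise_sigma, "seed": seed},
    )


def _lowest_gradient_subset(g, remaining, k, shape):
    mag = np.where(remaining, np.abs(g), np.inf)
    order = np.argsort(mag, axis=None, kind="stable")[:k]
    move = np.zeros(shape, dtype=bool)
    move.flat[order] = True
    return move


def guided_ig(
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    path: PathSpec | None = None,
    of: str = "logit",
) -> SaliencyMap:
    """Adaptive-path integrated gradients.

    At each step the current point moves toward the input only along the
    ``guided_fraction`` of not-yet-final pixels with the smallest gradient
    magnitude, so high-gradient (noisy) directions are integrated late and
    over short segments.  Attributions accumulate gradient × pixel movement;
    the path terminates exactly at the input, and with ``guided_fraction=1``
    the construction reduces to the straight path.
    """
    image = validate_image(image)
    if path is None:
        path = PathSpec(baseline=black_baseline(image), steps=200, path_kind="guided")
    if path.path_kind != "guided":
        raise ValueError("guided_ig requires path_kind='guided'")
    baseline = np.asarray(path.baseline, dtype=float)
    if baseline.shape != image.shape:
        raise ValueError("baseline shape must match image shape")
    steps, frac = path.steps, path.guided_fraction
    z = baseline.copy()
    attr = np.zeros_like(image)
    eps = 1e-12
    for i in range(steps):
        g = model.input_gradients(z[None], class_index, of=of)[0]
        remaining = np.abs(image - z) > eps
        n_rem = int(remaining.sum())
        if n_rem == 0:
            break
        steps_left = steps - i
        dist = np.abs(image - z)
        if i == steps - 1:
            move, share = remaining, 1.0
        else:
            k = max(1, int(np.ceil(frac * n_rem)))
            move = _lowest_gradient_subset(g, remaining, k, image.shape)
            # pace the path by L1 length: each step absorbs an equal share of
            # the remaining distance, concentrated on the selected pixels
            # (share reduces to 1/steps_left when every pixel moves)
            budget = dist.sum() / steps_left
            moved_l1 = dist[move].sum()
            share = min(1.0, budget / moved_l1) if moved_l1 > 0 else 1.0
        delta = np.where(move, (image - z) * share, 0.0)
        if frac >= 1.0:
            # all pixels move: the straight path, integrated exactly as
            # integrated_gradients does (single midpoint evaluation)
            g_mid = model.input_gradients((z + 0.5 * delta)[None], class_index, of=of)[0]
            attr += g_mid * delta
        else:
            # selection used the gradient at z; accumulate the segment with a
            # subdivided midpoint rule — large shares (late, high-gradient
            # jumps) get proportionally more evaluations so the completeness
            # gap stays small
            m = max(4, int(np.ceil(32 * share)))
            dsub = delta / m
            pts = z[None] + (np.arange(m) + 0.5)[:, None, None, None] * dsub[None]
            g_sub = model.input_gradients(pts, class_index, of=of)
            attr += g_sub.sum(axis=0) * dsub
        z += delta
    gap = _completeness_gap(model, image[None], baseline[None], class_index, float(attr.sum()))
    return SaliencyMap(
        channel_reduce(attr),
        "guided_ig",
        signed=False,
        meta={
            "attributions": attr,
            "completeness_gap": gap,
            "steps": steps,
            "guided_fraction": frac,
        },
    )
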