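"""Saliency-map container and shared array helpers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SaliencyMap:
    """Per-pixel relevance scores for one image/class/method.

    ``values`` is the H×W display map.  Gradient methods may carry sign
    (``signed=True``); region and CAM methods are non-negative.  ``meta``
    holds method-specific diagnostics such as the integrated-gradients
    completeness gap or the signed per-channel attribution tensor.
    """

    values: np.ndarray
    method: str
    signed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"saliency map must be 2-D, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency map contains non-finite values")
        if not self.signed and self.values.min() < 0:
            raise ValueError("unsigned saliency map has negative values")

    @property
    def magnitude(self) -> np.ndarray:
        """|values| — the ranking key used by bokeh reintroduction."""
        return np.abs(self.values)


def channel_reduce(tensor: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, C) attribution tensor to H×W by max |value| per pixel."""
    return np.max(np.abs(tensor), axis=-1)


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; an all-constant array maps to all zeros."""
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)
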