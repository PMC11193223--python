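"""End-to-end evaluation pipeline, overlay rendering, and method registry.

``run_evaluation`` ties the pieces together: for every (image, method) pair
it computes an attribution map, AIC and SIC curves, and (when a lesion mask
is available) the mass-in-mask localization score, then aggregates curves
per method and emits a self-describing JSON summary plus CSV/PNG artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import cam, gradients, pic, xrai
from .adapter import CNNModelHandle, ModelHandle
from .maps import SaliencyMap, minmax_normalize
from .phantoms import PhantomSample, load_dataset, mass_in_mask

ALL_METHODS = (
    "vanilla",
    "ig",
    "smoothgrad-ig",
    "guided-ig",
    "gradcam",
    "gradcam++",
    "scorecam",
    "xrai",
    "fast-xrai",
    "random",
)


def compute_saliency(
    method: str,
    model: ModelHandle,
    image: np.ndarray,
    class_index: int,
    layer: str | None = None,
    seed: int = 0,
    ig_steps: int = 64,
    guided_steps: int = 200,
    guided_fraction: float = 0.1,
    smoothgrad_samples: int = 16,
    baseline: str = "black",
    top_fraction: float = 0.3,
    scales=xrai.DEFAULT_SCALES,
) -> SaliencyMap:
    """Dispatch one registered attribution method by name."""
    if method not in ALL_METHODS:
        raise KeyError(f"unknown method {method!r}; registered: {ALL_METHODS}")
    make_baseline = (
        gradients.white_baseline if baseline == "white" else gradients.black_baseline
    )
    if method == "vanilla":
        return gradients.vanilla_gradient(model, image, class_index)
    if method == "ig":
        spec = gradients.PathSpec(baseline=make_baseline(image), steps=ig_steps)
        return gradients.integrated_gradients(model, image, class_index, path=spec)
    if method == "smoothgrad-ig":
        spec = gradients.PathSpec(baseline=make_baseline(image), steps=ig_steps)
        return gradients.smoothgrad(
            gradients.integrated_gradients, model, image, class_index,
            n_samples=smoothgrad_samples, seed=seed, path=spec,
        )
    if method == "guided-ig":
        spec = gradients.PathSpec(
            baseline=make_baseline(image), steps=guided_steps,
            path_kind="guided", guided_fraction=guided_fraction,
        )
        return gradients.guided_ig(model, image, class_index, path=spec)
    layer = layer or getattr(model, "last_conv_layer", None)
    if method == "gradcam":
        return cam.gradcam(model, image, class_index, layer)
    if method == "gradcam++":
        return cam.gradcam_pp(model, image, class_index, layer)
    if method == "scorecam":
        return cam.scorecam(model, image, class_index, layer)
    if method == "xrai":
        spec = gradients.PathSpec(baseline=make_baseline(image), steps=ig_steps)
        return xrai.xrai(model, image, class_index, path=spec,
                         segments=xrai.oversegment(image, scales=scales))
    if method == "fast-xrai":
        spec = gradients.PathSpec(baseline=make_baseline(image), steps=ig_steps)
        return xrai.fast_xrai(model, image, class_index, path=spec,
                              top_fraction=top_fraction)
    # random control, seeded per image
    return pic.random_saliency(image.shape[0], image.shape[1], seed=seed)


# ---- overlay rendering ------------------------------------------------

@dataclass
class OverlayPanel:
    """Colormapped saliency alpha-blended on the base image."""

    rgb: np.ndarray  # (H, W, 3) uint8
    method: str = ""
    has_contour: bool = False


def render_overlay(
    image: np.ndarray,
    saliency: SaliencyMap,
    mask: np.ndarray | None = None,
    alpha: float = 0.6,
    colormap: str = "inferno",
    method: str = "",
) -> OverlayPanel:
    """Blend a saliency heatmap over the grayscale base.

    Per-pixel blend weight is ``alpha * normalized saliency``, so zero
    saliency leaves the base untouched.  When a mask is given its boundary
    is drawn in red.
    """
    from matplotlib import colormaps
    from scipy.ndimage import binary_erosion

    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        base = image.mean(axis=-1)
    else:
        base = image
    if saliency.values.shape != base.shape:
        raise ValueError("saliency and image shapes differ")
    norm = minmax_normalize(saliency.magnitude)
    cmap = colormaps[colormap]
    heat = cmap(norm)[..., :3]
    base_rgb = np.repeat(base[..., None], 3, axis=-1)
    a = (alpha * norm)[..., None]
    out = (1 - a) * base_rgb + a * heat
    has_contour = False
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != base.shape:
            raise ValueError("mask and image shapes differ")
        contour = mask & ~binary_erosion(mask)
        out[contour] = [1.0, 0.0, 0.0]
        has_contour = bool(contour.any())
    rgb = np.clip(out * 255, 0, 255).astype(np.uint8)
    return OverlayPanel(rgb=rgb, method=method or saliency.method, has_contour=has_contour)


def save_overlay_png(panel: OverlayPanel, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray(panel.rgb).save(path)


# ---- full pipeline ----------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of one evaluation run (embedded in the summary)."""

    methods: tuple[str, ...] = ("gradcam", "random")
    layer: str | None = None
    n_images: int | None = None
    fractions: tuple[float, ...] = pic.DEFAULT_FRACTIONS
    sigma: float | None = None
    x_axis: str = "entropy"
    n_bins: int = 20
    statistic: str = "median"
    ig_steps: int = 64
    seed: int = 0
    data_dir: str | None = None
    model_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        self.methods = tuple(self.methods)
        for m in self.methods:
            if m not in ALL_METHODS:
                raise KeyError(f"unknown method {m!r}; registered: {ALL_METHODS}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_evaluation(
    config: RunConfig,
    samples: list[PhantomSample] | None = None,
    model: ModelHandle | None = None,
) -> dict:
    """Run attribution + PIC + localization for every (image, method) pair.

    Returns (and optionally writes) a JSON-serializable summary with
    per-method aggregated AIC/SIC AUCs, localization medians, per-image
    records, failure counts, and the full resolved configuration.
    """
    if samples is None:
        if config.data_dir is None:
            raise ValueError("no samples given and no data_dir configured")
        samples = load_dataset(config.data_dir)
    if model is None:
        if config.model_path is None:
            raise ValueError("no model given and no model_path configured")
        model = CNNModelHandle.load(config.model_path)
    if config.n_images is not None:
        samples = samples[: config.n_images]
    layer = config.layer or getattr(model, "last_conv_layer", None)

    per_method: dict[str, dict] = {m: {"aic": [], "sic": [], "mass": []} for m in config.methods}
    records = []
    failures = 0
    for i, s in enumerate(samples):
        for method in config.methods:
            try:
                sal = compute_saliency(
                    method, model, s.image, s.label, layer=layer,
                    seed=config.seed + i, ig_steps=config.ig_steps,
                )
                curve_kw = dict(
                    fractions=config.fractions, sigma=config.sigma, x_axis=config.x_axis
                )
                aic = pic.compute_pic_curve(model, s.image, s.label, sal, "AIC", **curve_kw)
                sic = pic.compute_pic_curve(model, s.image, s.label, sal, "SIC", **curve_kw)
                rec = {
                    "image_id": i, "method": method, "label": s.label,
                    "aic_auc": aic.auc, "sic_auc": sic.auc,
                }
                if s.mask is not None and sal.magnitude.sum() > 0:
                    rec["mass_in_mask"] = mass_in_mask(sal, s.mask)
                    per_method[method]["mass"].append(rec["mass_in_mask"])
                per_method[method]["aic"].append(aic)
                per_method[method]["sic"].append(sic)
                records.append(rec)
            except Exception as exc:  # noqa: BLE001 — skip image, count failure
                failures += 1
                records.append({"image_id": i, "method": method, "error": str(exc)})

    summary_methods = {}
    for method, acc in per_method.items():
        entry = {}
        if acc["aic"]:
            entry["aic_auc"] = pic.aggregate_pic(acc["aic"], config.n_bins, config.statistic).auc
            entry["sic_auc"] = pic.aggregate_pic(acc["sic"], config.n_bins, config.statistic).auc
            entry["n_curves"] = len(acc["aic"])
        if acc["mass"]:
            entry["mass_in_mask_median"] = float(np.median(acc["mass"]))
        summary_methods[method] = entry

    summary = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_images": len(samples),
        "methods": summary_methods,
        "records": records,
        "failures": failures,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_curve_csv(out / "curves.csv", per_method)
        _plot_aggregates(out, per_method, config)
    return summary


def _write_curve_csv(path: Path, per_method: dict) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["method", "mode", "curve_index", "information_level", "score"])
        for method, acc in per_method.items():
            for mode in ("aic", "sic"):
                for ci, curve in enumerate(acc[mode]):
                    for x, y in zip(curve.x, curve.y):
                        writer.writerow([method, mode.upper(), ci, f"{x:.6f}", f"{y:.6f}"])


def _plot_aggregates(out: Path, per_method: dict, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for mode in ("aic", "sic"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for method, acc in per_method.items():
            if not acc[mode]:
                continue
            agg = pic.aggregate_pic(acc[mode], config.n_bins, config.statistic)
            ax.plot(agg.x, agg.y, marker="o", ms=3, label=f"{method} (AUC={agg.auc:.3f})")
        ax.set_xlabel("normalized information level")
        ax.set_ylabel("accuracy" if mode == "aic" else "normalized softmax score")
        ax.set_title(f"Aggregated {mode.upper()}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"aggregated_{mode}.png", dpi=120)
        plt.close(fig)
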