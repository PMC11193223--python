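# Methods

`medsal` implements a saliency-attribution framework for convolutional image
classifiers together with the quantitative layer needed to judge the
attributions: information-level curves built from blurred/restored image
composites, and localization scoring against ground-truth lesion masks.
This note records the models, the defaults and why they are what they are,
the numerical choices, and what the synthetic phantoms do and do not show.

## The model contract

Every attribution operator sees the classifier only through a `ModelHandle`:
softmax predictions, gradients of a class score with respect to the input,
and activations/gradients of a named convolutional layer. Gradients are
taken with respect to the pre-softmax logit by default; probability-space
gradients (composed through the softmax Jacobian) are available because the
softmax-based evaluation layer operates on probabilities. Images are
channels-last `(H, W, C)`, `C ∈ {1, 3}`, intensities in `[0, 1]`.

The bundled backend is a small numpy CNN (three 3×3 conv blocks with ReLU
and 2×2 max-pooling, then a dense softmax head) with hand-written forward
and backward passes. Writing the backward pass explicitly keeps the three
gradient surfaces (input, parameters, named layer) available on any
platform, makes every operation bit-deterministic, and is fast enough for
64×64 inputs on one CPU core. Max-pooling routes gradients to the first
maximal element of each window, so ties break deterministically.

## Attribution operators

**Vanilla gradient** — `∂S_c/∂x`, displayed as the per-pixel maximum of
absolute channel values (signed tensors are kept in metadata).

**Integrated gradients** — straight-path integral from a baseline (default:
black) approximated with a midpoint Riemann sum,
`attr = (x − x0) ⊙ mean_k ∇S_c(x0 + ((k+½)/n)(x − x0))`. The midpoint rule
matters: the bundled CNN is piecewise linear, and on the trained fixture at
n=256 the left-endpoint rule leaves completeness gaps up to ~2.4% of the
score difference while the midpoint rule stays below ~0.5%. The completeness
gap `|Σ attr − (S_c(x) − S_c(x0))|` is reported in map metadata; it shrinks
monotonically (in the median) as steps grow.

**SmoothGrad** — the mean of base-method maps over `n_samples` noisy copies
`clip(x + ε, 0, 1)`, `ε ~ N(0, σ²)` i.i.d. per pixel; `σ` defaults to
0.15 × the input intensity range and the noise stream is seeded. Default
`n_samples=16` balances variance reduction against `n_samples` full
base-method evaluations.

**Guided (adaptive-path) integrated gradients** — the path moves toward the
input only along the fraction (default 0.1) of not-yet-finished pixels with
the smallest current `|∂S_c/∂x|`, so noisy high-gradient directions are
integrated late and over short segments. Step length is paced by L1 path
length (each of the default 200 steps absorbs an equal share of the
remaining distance), which makes the construction reduce *exactly* to the
straight path when the fraction is 1. Each segment is integrated with a
subdivided midpoint rule (`max(4, ⌈32·share⌉)` gradient evaluations):
selecting minimal-gradient pixels is exactly the regime where a
single-point quadrature is biased (the local slope is ~0 while the segment
still crosses activation kinks), and without subdivision completeness gaps
reached tens of percent. With it they stay within a few percent at 256
steps.

**GradCAM / GradCAM++ / ScoreCAM** — channel-weighted combinations of a
convolutional layer's activations, ReLU-rectified, bilinearly upsampled and
min–max normalized. GradCAM weights are spatial-mean gradients; GradCAM++
uses the closed-form coefficients `α = g²/(2g² + Σ A g³)` (zero where the
denominator vanishes) with `w = Σ α·relu(g)`; ScoreCAM weights are a
softmax over the class-probability scores of channel-masked inputs relative
to a baseline (default black) and touches no gradient entry point —
asserted in tests by instrumenting the adapter. Constant activation
channels carry no maskable signal and get weight zero. The layer is an
explicit argument; the bundled CNN names its final convolutional layer
`conv3`.

**XRAI** — pixel attributions are the positive part of integrated gradients
summed over black and white baselines (the dual baseline suppresses the
bias either extreme introduces alone). The image is oversegmented with
Felzenszwalb graph segmentation at several scales (default
{50, 100, 150, 250}, minimum segment 20 px; segments from different scales
overlap), and segments are selected greedily by attribution density over
their not-yet-selected pixels, ties broken by listing order. The output map
gives each selected region its attribution density, capped so values
strictly decrease with selection order, plus a vanishing
`(1 − cumulative area) · 10⁻⁶·max-gain` term that keeps the decrease strict
through zero-gain regions. An earlier draft encoded *only* the selection
order (value = 1 − cumulative area before selection); that makes the map's
mass proportional to area rather than attribution, which destroys
localization scoring (mass-in-mask collapses to the lesion-area fraction) —
the density-capped scheme preserves both the ranking contract and magnitude
semantics. "Fast XRAI 30%" is interpreted as the binary top-30%-area mask
of a single-scale run; this is a documented convention, the term has no
fixed definition.

## The evaluation layer

**Information level.** Image information content is the Shannon entropy of
the intensity histogram: 256 equal-width bins over [0, 1] with density
normalization, masses `p_i = density_i · Δ`, `H = −Σ p_i log₂ p_i`.
Multi-channel images pool into one histogram. A compression-based
estimator (zlib bits per pixel) is available behind the same interface for
comparison but is never the default.

**Bokeh images.** Evaluation starts from a Gaussian-blurred copy
(`σ = 16 px` at 224², scaled proportionally to image height; reflective
boundaries) and restores the top-`fraction` pixels by |saliency| rank
(row-major tie-break, `round(f·H·W)` pixels exactly). The x-coordinate of a
curve point is the normalized information level
`(H_bokeh − H_blur)/(H_orig − H_blur)` clipped to [0, 1], with a fallback
to the raw pixel fraction when an image is no more entropic than its blur;
a raw-fraction x-axis is also available as an option.

**AIC / SIC.** For each restoration fraction (default schedule
{0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.07, 0.10, 0.13, 0.21, 0.34, 0.5,
0.75, 1}) the model scores the bokeh image. AIC records the 0/1 indicator
that the prediction equals the ground-truth label. SIC records the softmax
probability of the class predicted on the *original* image, divided by that
class's probability on the original, clipped to [0, 1] — so SIC is exactly
1 at the full image by construction. The reference-class choice
(model-on-original rather than ground truth) makes SIC a pure faithfulness
measure, independent of whether the model is right. Curves are sorted by x,
deduplicated keeping the best score per x, and summarized by plain
trapezoidal AUC over [0, 1] with no baseline subtraction.

**Aggregation.** Points from many curves are pooled, interior x binned into
equal-width bins (default 20) and aggregated with the median (mean
available); points at exactly x=0 and x=1 pin the endpoints; empty interior
bins are linearly interpolated and flagged. The aggregate of a single
bin-aligned curve reproduces that curve and its AUC.

**Controls and localization.** A seeded i.i.d. Uniform(0,1) saliency map is
the random control. Localization is mass-in-mask: the fraction of total
absolute saliency inside the ground-truth lesion mask; a uniform map scores
the mask's area fraction, which calibrates the measure.

## The phantom fixture

Phantoms are 64×64 grayscale images: a smooth low-frequency background
(Gaussian-filtered noise mapped to [0.25, 0.40]) plus a bright localized
lesion whose *shape* carries the class — filled disc, annulus, or elongated
45° ellipse — with uniformly random center (inside a margin) and radius
(±20% around size/9, lesion area ≈ 3% of the image), lesion contrast 0.6,
pixel noise σ = 0.05, clipped to [0, 1]. Masks are the exact lesion
support. Classes are assigned round-robin (an imbalance option exists);
generation is bit-reproducible from (config, seed). The study conditions
are 1200 training + 300 held-out samples; the fixture reaches ≥99% held-out
accuracy in six epochs of Adam (lr 3·10⁻³, batch 32) in under a minute of
CPU, and a shuffled-label control stays at chance.

64×64 keeps the full suite within minutes of CPU while preserving the one
property the framework measures: spatially localized class evidence with
known ground truth. What phantoms do *not* emulate: realistic MRI/X-ray
contrast physics, texture-defined (non-geometric) pathology, anatomy-scale
context, inter-observer mask uncertainty, or class evidence distributed
across the whole field. Passing tests therefore demonstrate the
correctness and calibration of the operators and metrics — not that any
method localizes real lesions in clinical data.

On these phantoms the evaluation layer separates informative from
uninformative saliency cleanly: methods that restore the lesion first keep
the classifier correct at every information level (aggregated AIC AUC ≈ 1),
while the random control restores scattered pixels and stays wrong on
heavily blurred composites over much of the range. Localization
(mass-in-mask) separates the methods from the control by an even wider
margin. Because the phantoms are easy, differences *among* the true
methods are small on the curve metrics; ranking real methods against each
other on real data is outside what the phantom evidence supports.

## Numerical choices and degenerate inputs

- Min–max normalization maps an all-constant array to all zeros.
- GradCAM++ coefficients are zero wherever the denominator vanishes.
- All ranking operations (pixel restoration, top-fraction masks, greedy
  region selection) break ties deterministically in row-major/first-index
  order, so repeated runs are byte-identical.
- AUC is `trapezoid(y, x)` exactly as stored; curve invariants (x strictly
  increasing, endpoints present) are enforced at construction.
- Every stochastic element (phantom generation, training shuffles,
  SmoothGrad noise, random saliency) draws from an explicit seeded
  generator; the evaluation pipeline records all seeds in its summary.

## Known limitations

- Guided IG costs ~10 s per 64×64 image at default settings (the segment
  subdivision multiplies gradient evaluations several-fold); it is the most
  expensive operator by an order of magnitude.
- The greedy region loop is quadratic in the number of segments; fine for
  64–224 px images, not tuned beyond that.
- The numpy backend supports the bundled CNN architecture family only;
  other classifiers enter through their own `ModelHandle` implementation.
- Aggregated AUC values depend on the binning statistic and the x-axis
  convention; comparisons are meaningful only within one convention.
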