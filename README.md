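# medsal

Saliency attribution and quantitative evaluation for convolutional medical
image classifiers.

Deep classifiers for lesion-centred tasks (brain-tumor MRI slices, chest
X-rays) are rarely trusted on accuracy alone: clinicians want to see *where*
the model looked. `medsal` provides eight image-attribution operators behind
one framework-agnostic model contract and — the part that usually goes
missing — the quantitative layer to judge them: information-level
performance curves and localization scoring against ground-truth lesion
masks. A synthetic phantom generator and a small trainable CNN fixture make
the entire pipeline runnable on one CPU core with no external data.

## What it computes

**Attribution operators** `A_h(x, c) → H×W saliency map` for a classifier
`h` and class `c`:

- *Gradient / path methods*: Vanilla Gradient `∂S_c/∂x`; Integrated
  Gradients `(x − x₀) ⊙ ∫₀¹ ∇S_c(x₀ + α(x − x₀)) dα` (midpoint Riemann
  sum, completeness gap reported); SmoothGrad averaging over noisy copies;
  Guided IG along an adaptive path that defers high-gradient pixels.
- *Class-activation methods on a conv layer with activations `A_k`*:
  GradCAM `ReLU(Σ_k w_k A_k)` with `w_k = mean ∂S_c/∂A_k`; GradCAM++ with
  closed-form `α = g²/(2g² + ΣA g³)` coefficients; ScoreCAM, gradient-free,
  weighting channels by softmax-normalized confidence scores of
  channel-masked inputs.
- *Region-ranked*: XRAI — Felzenszwalb oversegmentation at several scales,
  greedy selection by integrated-gradients density, plus "Fast XRAI"
  top-fraction binary masks.

**Evaluation layer**: Shannon entropy of the intensity histogram
`H = −Σ pᵢ log₂ pᵢ` (256 bins) as the information measure; bokeh images
(Gaussian-blurred copy with the top-salient pixels restored); Accuracy
Information Curves (AIC: correctness vs information level) and Softmax
Information Curves (SIC: normalized softmax score of the originally
predicted class) with trapezoidal AUC; median-binned aggregation across
images; a seeded uniform-random saliency control; and mass-in-mask
localization — the fraction of total |saliency| inside the expert lesion
mask.

## Worked example

```python
import numpy as np
from medsal import (PhantomConfig, generate_phantoms, train_fixture_cnn,
                    gradcam, integrated_gradients, PathSpec,
                    compute_pic_curve, mass_in_mask)

samples = generate_phantoms(PhantomConfig(n_samples=1500, seed=7))
train, hold = samples[:1200], samples[1200:]
model = train_fixture_cnn(train, epochs=6, seed=0)

s = hold[0]                                # a held-out phantom with mask
sal = gradcam(model, s.image, s.label, model.last_conv_layer)
print("mass in mask:", round(mass_in_mask(sal, s.mask), 3))

ig = integrated_gradients(model, s.image, s.label,
                          path=PathSpec(baseline=np.zeros_like(s.image), steps=256))
print("IG completeness gap:", round(ig.meta["completeness_gap"], 4))

curve = compute_pic_curve(model, s.image, s.label, sal, mode="SIC")
print("SIC AUC:", round(curve.auc, 3))
```

Output:

```
mass in mask: 0.067
IG completeness gap: 0.0048
SIC AUC: 0.998
```

The GradCAM map concentrates 6.7% of its mass inside a lesion occupying
~3% of the image — about twice what a uniform map would score on this
phantom (medians across many phantoms are considerably higher; the
acceptance script reports them). The integrated-gradients attributions sum
to the logit difference between image and baseline within 0.005 (≈0.1% of
that difference), and the SIC AUC near 1 says the model's confidence is
already restored at low information levels on these easy phantoms.

The same pipeline is scriptable from the shell:

```bash
medsal synth --n 1500 --seed 7 --out data/
medsal train-fixture --data data/ --epochs 6 --seed 0 --out model.npz
medsal attribute --image data/disc/phantom_00000.png --model model.npz \
    --method gradcam --out overlay
medsal pic --data data/ --model model.npz --methods gradcam,scorecam,random \
    --n-images 30 --out results/
```

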