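# myoseg

Automatic segmentation of the left-ventricular (LV) myocardium from
short-axis black-blood cardiac MR slices.

On black-blood images the blood pool is dark and the myocardium is a bright,
nearly circular annulus — ideal contrast for region-based active contours,
but clinical slices carry intensity inhomogeneity (bias fields), noise, and
bright neighboring tissue (fat, chest-wall muscle) that defeat globally
homogeneous models.  `myoseg` implements a fully automatic pipeline for this
setting, aimed at researchers who need reproducible endocardial/epicardial
contours (e.g. as the region of interest for myocardial T2* analysis):

1. **Circular Hough transform (CHT) initialization.**  Edge pixels (top
   decile of gradient magnitude) vote in a (center, radius) accumulator; the
   two strongest concentric peaks give the epicardial and endocardial
   circles, each converted to an exact signed-distance level-set field
   φ = r − ‖z − c‖ (positive inside).
2. **Level-set evolution.**  Each contour is the zero level set of φ evolved
   under a region-based fitting energy (models below); the myocardium is the
   set difference of the two converged masks.
3. **Evaluation.**  Dice overlap, misclassification error (ME) and Hausdorff
   distance (HD) between contours, plus a synthetic phantom generator with
   exact ground truth.

## Models

With H_ε, δ_ε a smoothed (arctan) Heaviside/Dirac pair and c_i, c_o the
interior/exterior means, the classical Chan–Vese (CV) evolution is

    ∂φ/∂t = δ_ε(φ) [ μ div(∇φ/|∇φ|) − ν − λ_in (I − c_i)² + λ_out (I − c_o)² ].

`myoseg` provides, as scikit-learn-style estimators sharing one evolution
loop and stopping rule:

* **`ChanVese`** — the global CV baseline above.
* **`EntropyWeightedChanVese` (ECV)** — λ_in, λ_out replaced by the Shannon
  entropies E_in, E_out of the interior/exterior intensity histograms,
  recomputed every iteration: the *less* homogeneous side gets the larger
  weight, so the balance of the two fitting terms adapts itself and the
  hand-tuning of λ disappears.
* **`LocalChanVese`** — the full model.  For every grid point j in a narrow
  band around the curve, a square window Ω_j is grown from half-size
  `win_init` until its intensity entropy exceeds a threshold (homogeneous
  windows carry no boundary evidence), capped at `win_max`.  Local means
  u_j, v_j and local entropy weights E_in^j, E_out^j are computed inside
  Ω_j, and the summed local forces drive

      ∂φ/∂t = δ_ε(φ) [ −ν − Σ_j δ_ε(φ) ( E_in^j (I − u_j)² − E_out^j (I − v_j)² ) ],

  followed by convolution of φ with a Gaussian of width ξ, which replaces
  both the curvature term and signed-distance re-initialization.  A fixed
  window at half-size (H+W)/16 with unit weights (`ncv_model`) reproduces
  the fixed-window local comparator (NCV).

## Worked example

```python
import numpy as np
from myoseg import PhantomSpec, make_lv_phantom, segment_myocardium, evaluate_masks

# 128x128 black-blood phantom: +-40% bias field, noise sigma = 10
spec = PhantomSpec(bias_amplitude=0.4, noise_sigma=10.0, seed=3)
image, endo, epi, myo = make_lv_phantom(spec)

result = segment_myocardium(image)          # CHT init + two local evolutions
report = evaluate_masks(result.myo_mask, myo)
```

This prints (via the corresponding fields):

```
detected epicardial circle: (64.0, 64.0), r = 30.0 px
detected endocardial circle: (64.0, 64.0), r = 17.8 px
iterations (endo, epi): 14 9
myocardium Dice = 0.9945, ME = 0.0012, HD = 1.00 px
```

The detected circles sit within a fraction of a pixel of the true radii
(18 and 30 px); the converged annulus overlaps the ground-truth myocardium
at Dice 0.994 with a one-pixel worst-case contour distance, despite the
bias field and noise.  A global `ChanVese` run on the same initialization
reaches only ≈0.96 here — the gap is the value of the local windows.

The same pipeline is available from the shell:

```
myoseg phantom --out ph --bias-amplitude 0.4 --noise-sigma 10 --seed 3
myoseg segment ph/image.png --out seg
myoseg evaluate seg/myo_mask.png ph/myo_mask.png
myoseg compare ph/image.png --truth-myo ph/myo_mask.png
```

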