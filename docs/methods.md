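# Methods

This note documents the models implemented in `myoseg`, the parameter
defaults and the numerical choices behind them, what the synthetic phantoms
do and do not emulate, and the known limitations.

## Problem setting

A short-axis black-blood cardiac MR slice shows the LV blood pool as a dark
disk surrounded by the bright myocardial annulus, embedded in heterogeneous
surroundings.  The task is to delineate the endocardial (inner) and
epicardial (outer) borders; the myocardium is the annulus between them.
Intensities are canonicalized to [0, 255] at load time (affine rescale;
constant images map to zero) — every intensity-scaled parameter below
assumes this range.  All coordinates are 0-based (row, col) with pixel
centers at integers.

## Initialization: circular Hough transform

Both LV borders are nearly circular, so circle detection provides a fully
automatic initialization.

* **Feature points:** pixels in the top decile of Sobel gradient magnitude
  (`edge_quantile = 0.9`, over *all* pixels so that piecewise-constant
  images keep all their edges).  A constant image has no feature points and
  detection returns nothing.
* **Accumulator:** perimeter-normalized voting at integer radius steps over
  [0.05, 0.45]·min(H, W) by default (the LV occupies a central fraction of
  a short-axis slice).
* **Peaks:** greedy non-maximum suppression in the 3-D accumulator.  A
  candidate is suppressed when its center lies within radius/2 of an
  accepted peak *and* its radius within max(2, radius/8).  The radius window
  must stay much tighter than the center window: near-duplicate peaks of one
  circle sit a few radius steps apart, while the concentric endocardial
  circle shares the center but differs strongly in radius and must survive.
  Accepted peaks are refined to sub-bin precision by the vote-weighted
  centroid of near-peak cells (±2 center px, ±3 radius steps, ≥0.9·peak):
  a ring thicker than one pixel saturates the normalized accumulator over
  several adjacent radii, and the plain argmax can land anywhere on that
  plateau (errors up to ~1.5 px; with refinement, worst-case ~0.4 px on
  noiseless rings).
* **Pairing:** the strongest peak is the epicardial circle; the strongest
  remaining peak with smaller radius whose center lies within
  `concentricity_tol` (default 5 px) is the endocardial circle.  No
  qualifying inner circle is an initialization failure — the known failure
  mode when bright fat/muscle outvotes the ventricular circles.

Each circle becomes the exact signed distance field φ = r − ‖z − c‖.

## Region entropies as adaptive weights

The homogeneity of a region is measured by the Shannon entropy of its
intensity histogram: 32 equal-width bins over [0, 255], natural logarithm
(nats), out-of-range samples clipped into the end bins.  Histograms keep the
estimator exactly checkable against counting; 32 bins (8 intensity levels
per bin) resolve tissue classes without fragmenting under noise.  Entropies
used as weights are floored at `weight_floor = 0.05`: a perfectly
homogeneous region would otherwise zero its fitting term and freeze the
evolution on ideal phantoms.  Weights are recomputed every iteration, so
they adapt as the curve moves.

## Evolution models

All models share one loop: explicit Euler update, interior-area stopping
rule, per-iteration diagnostics (area, max |Δφ|, weights).

**Global CV.**  Defaults follow the clinical preset: λ_in = λ_out = 1,
μ = 0.5·255², ν = 0.2, Δt = 0.1, with the synthetic-image preset
(μ = 0.01·255², ν = 0) available for high-contrast two-region images.
Curvature uses central differences with the gradient magnitude floored at
1e-8 (flat regions get zero curvature instead of NaN).

**Entropy-weighted CV (ECV)** replaces (λ_in, λ_out) by (E_in, E_out).  On
a two-region image this removes the manual weight choice and accelerates
convergence (the larger entropy weights speed the sweep).  On three-region
images (e.g. the LV phantom seen by the epicardial contour: dark pool +
bright annulus inside, homogeneous background outside) the global weights
misbalance the energy and ECV can fail — this is precisely the
heterogeneity failure that motivates the local model, and the test suite
exercises ECV only in its two-region domain of validity.

**Local model.**  Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `nu` | 0.05 | area (balloon) weight, clinical preset |
| `dt` | 0.05 | Euler step; low because overlapping windows sum |
| `xi` | 1.0 px | Gaussian regularization width; must exceed √dt |
| `heaviside_eps` | 1.5 px | width of the smoothed Heaviside/Dirac pair |
| `band_width` | 3 px | \|φ\| threshold defining "points near the curve" |
| `win_init` | 4 px | initial window half-size |
| `win_max` | (H+W)/16 | half-size cap (the fixed-window optimum reused as a cap) |
| `win_entropy_threshold` | 0.5 nats | window growth threshold |
| `step_cap` | 1.0 | per-pixel update limiter (below) |
| `max_iters`, `tol` | 150, 1e-3 | stopping rule (below) |

Local entropy weights E_in^j, E_out^j are computed from the window's own
interior/exterior intensities (the window-local analogue of the global
weights); windows that do not straddle the contour carry no boundary
evidence and are skipped for the iteration.  Forces from overlapping windows
are summed, not averaged.  δ_ε(φ) enters once inside the per-window force
density and once outside the bracket, as the printed gradient of the energy
has it.  The "NCV mode" comparator freezes the window at half-size
(H+W)/16 with unit weights.

## Numerical choices

* **Smoothed Heaviside.**  H_ε(t) = ½(1 + (2/π)·arctan(t/ε)), δ_ε its exact
  derivative.  The globally supported δ lets the evolution act away from the
  current contour.  Note the arctan pair has 1/t² tails: δ_ε integrates to
  1−10⁻³ only over ±1000 ε, and region means of "sharp" fields approach the
  exact constants only for |φ| ≫ 100 — relevant when constructing
  fixed-point fixtures.
* **Update limiter (`step_cap`).**  On the [0, 255] scale the summed window
  forces reach O(10⁴), so a raw Euler step overshoots by hundreds of φ
  units; the Gaussian filter then spreads the overshoot into neighbors,
  which flip back the next iteration (a persistent two-cycle).  The update
  is therefore clipped to ±1 φ-unit per pixel per iteration — about one
  pixel of interface motion for a signed-distance field.  The cap changes
  neither the zeros nor the signs of the force, hence not the fixed points;
  it bounds the rate, in the spirit of a CFL condition.
* **Narrow band.**  The band is {|φ| < band_width} united with all pixels
  4-adjacent to a sign change.  Without re-initialization φ steepens away
  from a signed-distance profile, and a pure |φ| threshold can momentarily
  lose the zero crossing; the sign-change collar guarantees a nonempty band
  whenever a contour exists.  For signed-distance fields the collar adds
  nothing.
* **Gaussian regularization.**  `scipy.ndimage.gaussian_filter`
  (truncate = 4, replicate borders, kernel normalized to 1).  It preserves
  constants to machine precision and interior linear ramps to ~1e-9, and
  strictly decreases the discrete Dirichlet energy of non-constant fields.
  It also imposes a curvature-dependent inward drift of the zero set
  (≈ ξ²κ/2 per iteration when unopposed): on a circle of radius r the
  converged contour sits ~0.3–0.5 px inside the intensity boundary at
  ξ = 1.  This is the regularizer doing its job (it replaces the length
  term); the bias shrinks with ξ and with r, and is strongest for the
  fixed-window comparator (Dice ≈0.987 vs ≥0.99 for the other models on a
  clean r = 40 disk).
* **Stopping rule.**  Relative change of the interior area ΣH_ε(φ) below
  `tol` for 5 consecutive iterations.  Global models use tol = 1e-4.  The
  capped local model fluctuates by single contested boundary pixels
  (~2·10⁻⁴ relative area on the phantom), so its tol is 1e-3 — the level at
  which the interface fluctuation is sub-pixel.  φ is clamped to ±10⁶ as a
  pure overflow guard (never active in normal runs); non-finite updates
  raise a numeric-instability error naming the offending term.
* **Degenerate inputs.**  Empty regions, one-sided fields (contour
  collapse), one-sided windows, and sub-8×8 images each raise a dedicated
  error; the CLI maps them to distinct exit codes (1 input, 2
  initialization, 3 instability, 4 collapse).

## Resolved regime for iteration-count comparisons

The default Δt on the 255 intensity scale moves the interface by multi-pixel
region flips and converges in ~10 iterations; in that regime the iteration
count is dominated by a weight-insensitive settling tail.  The CV-vs-ECV
convergence-speed experiment (`ecv_speedup_experiment`) therefore runs at
Δt = 5·10⁻⁴, where every per-pixel update is sub-pixel and the interface
speed is proportional to the fitting weights: on 96×96 bimodal disk
phantoms (means 160/60, σ = 15) CV needs ≈650–740 iterations and ECV
≈330–380 under the shared stopping rule, reproducing the directional claim
that entropy weighting converges in fewer iterations.

## Phantoms: what they emulate and what they do not

`make_lv_phantom` draws a dark blood-pool disk (30) inside a bright
myocardial annulus (150) on a mid-gray background (80) — the black-blood
contrast ordering — then applies, in order: bright distractor disks in the
background (200, never overlapping the epicardial disk; stand-ins for
peri-cardiac fat/muscle), a multiplicative linear bias field spanning
[1−a, 1+a] across columns (the simplest inhomogeneity that breaks global
region means), additive Gaussian noise, and clipping to [0, 255].
Ground-truth masks always follow the noiseless analytic geometry.  Defaults
describe the clean phantom (128×128, radii 18/30 px, no corruption);
evaluation conditions used by the tests and the acceptance script are the
clean phantom and the ±40% bias + σ = 10 noise phantom.

Not emulated: Rician noise statistics, coil-sensitivity bias-field shapes,
partial-volume edges, papillary muscles, non-circular ventricle shapes, and
multi-slice/multi-echo structure.  Passing on these phantoms demonstrates
correct mechanics and the claimed robustness orderings (local > global under
bias; entropy weighting faster on bimodal images; sub-pixel initialization
sensitivity), not clinical-grade accuracy on patient data.

## Known limitations

* Circle-based initialization assumes a roughly circular, centrally located
  ventricle; strongly eccentric or non-circular anatomies and bright
  near-heart structures can defeat the pairing step (reported as an
  initialization failure rather than silently mis-segmenting).
* The two level sets evolve independently; nesting (endocardium inside
  epicardium) is enforced by intersection after convergence rather than by
  a coupled evolution.
* The Gaussian regularizer's curvature bias (above) bounds achievable
  boundary accuracy at ~½ px for small structures at the default ξ.
* Runtime scales with band length × window area; the adaptive window keeps
  windows small near informative boundaries but grows them (to `win_max`)
  in homogeneous surroundings.
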