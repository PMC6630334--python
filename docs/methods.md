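# Methods

`seedvigor` implements a complete near-infrared hyperspectral imaging
(NIR-HSI) analysis for seed-vitality assessment, of the kind used to sort
rice seed lots by storage year and to detect non-viable (aged) seeds. This
note records the models, the numerical choices, and what the synthetic
phantom does and does not emulate.

## The measurement model

A line-scan NIR camera records raw counts `I_raw(x, y, λ)` over 256 spectral
pixels spanning 874–1734 nm at a 3.36 nm step. Two reference frames turn
counts into unitless reflectance:

    I_cal = (I_raw − I_dark) / (I_ref − I_dark)

where `I_dark` is the dark current (capped lens) and `I_ref` a near-perfect
white diffuser. References are stored as one `(samples × bands)` line and
broadcast along the scan axis — the line-scan convention; full reference
cubes are also accepted. Calibration is scale-invariant: a common gain on
all three intensities cancels. Bands outside 941–1666 nm are discarded
(poor detector signal-to-noise at the spectral edges); on the native grid
this window holds exactly 216 bands. The window endpoints are inclusive and
fixed, not estimated. Reflectance outside [0, 1] is kept, not clipped —
clipping would bias the scatter correction downstream.

## Segmentation and spectra extraction

Seeds lie on a dark plate (background reflectance well below 0.15), so a
single-band threshold segments them: pixels whose reflectance at the band
nearest 1301 nm exceeds 0.15 are foreground. Connected components under
4-connectivity become seed regions; components below `min_area = 10` px are
discarded as specks (4-connectivity and the area floor are conservative
choices against bridged neighbours and noise; the threshold and band are
the standard protocol values). Each region's pixel spectra are averaged
into one row of an m × n spectra table — the object all chemometrics
operates on.

## Pretreatments

* **SG** — Savitzky–Golay least-squares smoothing, polynomial order 3,
  window 15 points. Edges are handled by evaluating the polynomial fitted
  to the terminal window, so the band count is preserved and polynomials up
  to order 3 pass through exactly (the basis of the filter's correctness
  tests).
* **SG-D1** — the first-derivative SG variant, same order/window, reported
  in reflectance per band step (per-nm available by dividing by the
  3.36 nm step). Removes additive baselines; amplifies noise.
* **MSC** — multiplicative scatter correction. Each spectrum x is regressed
  on a reference r by ordinary least squares, x = a·r + b, and corrected to
  (x − b)/a. The reference is the mean spectrum of the calibration set,
  stored and reused for prediction-set correction (computing it on the
  whole data set would leak test information). MSC exactly inverts per-seed
  affine scatter — which is precisely the distortion the phantom plants, so
  correctness is checkable to machine precision.
* **PCA** (exploration only) — column-mean-centred SVD scores with
  explained-variance percentages, for score plots.

## Wavelength selection (SPA)

The successive projections algorithm grows a minimal-collinearity band
subset: starting from one column of the autoscaled calibration matrix, each
step projects every unselected column onto the orthogonal complement of the
selected columns' span and appends the largest projected norm (ties to the
lowest band index). Columns are autoscaled (calibration mean/sd) because
reflectance magnitudes differ across bands and the selection is norm-driven.

The free choices — starting column and subset size k — are scored by
stratified cross-validated misclassification of a reference PLS-DA model on
the calibration set only (no test leakage); the (start, k) with the lowest
mean CV error wins, ties resolved toward smaller k, then smaller start.
k ranges over 2–20 by default, bracketing the 6–11 bands such analyses
typically retain. Greedy chains are nested, so one chain of length max(k)
per start prices every k. Scanning all 216 starts is the default; a
thinned, evenly spaced start list gives near-identical selections at a
fraction of the cost and is what the bundled studies use.

If the residual column space is exhausted before k is reached the chain
reports the achievable length rather than padding with numerically null
directions.

## Classifiers

All multiclass, on the calibration/prediction protocol of a stratified
200/200 per-class split (scaled-down splits in the bundled studies).

* **PLS-DA** — NIPALS PLS2 regression of one-hot class codes on centred
  spectra, Y = X·B + F; decision is the argmax of the predicted code row.
  10 latent components by default, optionally tuned by stratified 10-fold
  CV. At full rank the fit coincides with ordinary least squares, which is
  the oracle used to test it; the first weight vector equals the dominant
  eigenvector of XᵀYYᵀX, a second independent check.
* **LS-SVM** — least-squares SVM with RBF kernel K(x, z) =
  exp(−‖x−z‖²/σ²). Training a binary machine solves one symmetric linear
  system [[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y]; the solver retries with a
  1e-10 ridge if singular, and exposes the system residual (required
  ≤ 1e-8·‖rhs‖). Multiclass is one-vs-one majority voting, vote ties broken
  by the larger summed decision value. (γ, σ²) come from a 7×7 log-spaced
  grid (γ ∈ 10⁰…10⁶, σ² ∈ 10⁻²…10⁴) scored by stratified 10-fold CV
  accuracy; score ties prefer the smaller γ, then the larger σ²
  (less overfit-prone on both axes).
* **ELM** — a single-hidden-layer network with 100 hidden sigmoid nodes.
  Input weights and biases are drawn Uniform(−1, 1) from a seed; the output
  weights are the minimum-norm least-squares solution β = pinv(H)·T against
  one-hot targets. Inputs are min-max scaled to [−1, 1] with
  calibration-set ranges (the sigmoid saturates on raw reflectance).
  When training rows do not comfortably exceed the hidden-layer width the
  network enters its interpolation regime and memorises noise; scaled-down
  studies therefore keep ≥ 2× as many training rows as hidden nodes.

Reported accuracies are trace(confusion)/total·100, to two decimals, on
both the calibration and the prediction set.

## Germination metrics

GR = GN/(GN+SN)·100: the percentage of tested seeds germinated within the
7-day test (GN germinated, SN not). VI = S·Σₜ(Gₜ/Dₜ): mean germ length S
(cm) times the day-weighted germination sum — early germination counts for
more, so VI measures vigour. A product form S·Σ Gₜ·Dₜ found in parts of the
literature is available behind a flag but rewards *late* germination and is
not the default.

## The synthetic phantom

No public dataset exists for this system, so a phantom generator emulates
the statistical structure the analysis assumes; its defaults are the
package's study conditions.

* **Grid**: 256 bands, 874 nm start, 3.36 nm step — the only grid on which
  the 941–1666 nm window holds exactly 216 bands.
* **Classes**: three viable storage years plus an artificially aged class,
  with mean reflectance ordered aged > y2015 > y2016 > y2017 (brightness
  offsets 0.65/0.52/0.46/0.40) — storage age and ageing raise NIR
  reflectance.
* **Absorption dips**: Gaussian dips (sd 6 nm) at nine wavelengths
  (968, 988, 1204, 1301, 1409, 1463, 1629, 1646, 1659 nm — water, starch
  and protein overtone bands of the kind implicated in vitality loss), base
  depth 0.05. Class identity modulates each dip by ±0.008 via sign codes
  chosen so every pair of viable classes differs at several centres and
  every centre separates at least one pair.
* **Seed-to-seed compositional variability**: each seed's depth at each
  centre is additionally jittered (sd 0.008). This matters structurally:
  with class-mean codes alone the class signal at the nine centres has rank
  ≤ 3, and no selector can be expected to keep more than ~4 dip bands.
  Individual compositional variation — the realistic situation — gives
  every absorption band full-rank within-class variance, making all nine
  centres independently informative.
* **Scatter**: per-seed affine distortion a·x + b with a ~ N(1, 0.05),
  b ~ N(0, 0.02) — exactly the model MSC inverts. An optional non-affine
  (quadratic-in-wavelength gain) stress mode exists for testing MSC's
  failure mode; it is off by default.
* **Noise**: i.i.d. Gaussian, truncated at ±4 sd (detector wells clip;
  unbounded tails are not emulated, which also makes worst-case recovery
  errors bounded). Pixel noise sd 0.01 for rendered cubes; 0.008 per band
  for directly simulated seed-mean spectra (the residual within-seed
  heterogeneity left after pixel averaging).
* **Geometry**: non-overlapping axis-aligned ellipses (semi-axes 5–9 px,
  placed by rejection sampling with a bounded attempt budget) on a
  0.05-reflectance background; raw/dark/white frames are synthesised so
  calibration recovers the phantom reflectance exactly up to the planted
  noise.
* **Germination**: germinated totals are Binomial(n, p) with class
  probabilities 0.95/0.93/0.81 for the three years (matching the reference
  germination rates) and 0 forced for aged seeds; germination days follow a
  truncated geometric delay.

The effect sizes (brightness gaps, dip code ±0.008, jitter 0.008, noise
0.008) were fixed by a signal-to-noise design argument — per-dip pairwise
d′ ≈ 1.4, so cross-validation error keeps falling until most dip bands are
included and selected-band accuracies land in the low-to-mid 90s, the
regime such studies report — and then frozen.

**What the phantom does not emulate**: optical point-spread, specular
highlights, platform motion, touching seeds, spectrally correlated noise,
germ-side orientation effects, or any claim about real rice effect sizes.
Passing tests demonstrate that the pipeline recovers planted structure
under its stated assumptions; they are not evidence about a particular
seed lot.

## Problem sizes in the bundled studies

The package's own validation runs are scaled to desk size as a deliberate
design choice: the end-to-end recovery study uses 120 seeds per class with
a 60/60 per-class calibration/prediction split, SPA scored over 16 evenly
spaced starts and k ∈ 2–16 with 5-fold CV, repeated over ten generator
seeds (medians reported). The pipeline grid tests use 60 seeds per class.
All quantities scale to the full 400-per-class protocol through the same
configuration objects.

## Known limitations

* Touching seeds are not split (no watershed); the phantom avoids contact
  by construction, as sample plates do.
* The SG edge treatment and the MSC whole-set reference are choices among
  several defensible conventions; both are documented above and fixed.
* SPA's validation-scored (start, k) search is the standard practice for
  classification use but is not the only published variant.
* The LS-SVM grid search refits one linear system per fold and grid point;
  for very large calibration sets a kernel-matrix cache per σ² would be the
  first optimisation.
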