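# Methods

## The problem and the pipeline

Optical satellite classification of salt-marsh vegetation rests on
phenology: each species traces a distinctive annual vegetation-index (VI)
curve. Because clouds, shadows and snow are masked per pixel, each pixel
carries an irregular calendar of observations; a parametric curve is fitted
to each pixel's VI series, six phenological metrics are read off the fitted
curve, and those metrics feed both a separability analysis and a
classifier. The package evaluates every combination of five indices (NDVI,
SAVI, EVI, GNDVI, WAVI) and three curve families (AG, DL, TF) on synthetic
scenes whose ground truth is known.

## Synthetic scene model

**Phenology truth.** Each class is a six-parameter template — base level,
amplitude, peak day, green-up and senescence widths, cycle shift — rendered
as a double logistic whose inflection points sit at `peak_day −
green_up_width + cycle_shift` and `peak_day + senescence_width +
cycle_shift`. A width is read as the number of days a limb takes to move
from 10% to 90% of the amplitude (logistic rate = width / (2 ln 9)).
Positive cycle shift models the lagged cordgrass cycle, negative the
advanced reed cycle. The double logistic was chosen as the generative truth
because it is the best-suited of the three families for single-season
cycles; the recovery tests therefore treat the AG and TF fits as
cross-family checks, and all claimed AG/TF behaviour is established on
series generated from the AG/TF forms directly.

**Band model.** The paper trail from a greenness value v to band
reflectances is deliberately minimal: red interpolates from a bright
dormant-soil value (0.10) to a dark full-canopy value (0.03); NIR is then
solved so that NDVI of the bands equals v exactly; blue and green are fixed
ratios of red (0.5 and 0.9). This inverse construction makes the noise-free
pipeline an identity (recomputing NDVI reproduces the truth to float
precision) while giving tide and cloud events physically distinct bands to
act on. It does not attempt radiative-transfer realism, and the fixed
blue/green ratios mean GNDVI and WAVI carry no independent information in
noise-free scenes — their value in the factorial comparison comes entirely
from how the noise mechanisms propagate through their formulas.

**Noise mechanisms.** Four, all per observation: (i) tide events multiply
NIR by an attenuation factor (default 0.5), the signature of flooding and
wet soil; (ii) omitted-cloud events add a fixed offset (default 0.08) to
blue and green while leaving the scene-classification code clear — that is
what "omitted" means, and it is why EVI (which amplifies blue 7.5-fold)
develops outliers that SAVI (blue-free, red-damped) does not; (iii)
independent Gaussian band noise (default σ = 0.01); (iv) flagged-code
simulation for testing the mask. Reflectances are clipped to [0, 1] with a
logged count.

**Observation calendars.** A nominal 5-day revisit (days 3, 8, …, 363) is
thinned inside a climate gap window: continental sites lose winter
observations to snow (window day 335–59, retention 0.2), monsoonal sites
lose summer observations to the rainy season (window 152–243, retention
0.3). Retention is an independent Bernoulli per in-window date.

**Site noise presets.** Northern continental coasts have mean tidal ranges
near 0.5 m and southern monsoonal estuaries near 2.7 m, so the presets pair
the continental calendar with a 5% tide-event rate and the monsoonal
calendar with 25%. These two presets, with the six default class templates
and 40 samples per class, are the package's reference study conditions for
the climate-dependent model comparison.

**Per-sample jitter.** Within a class, amplitude (σ = 0.03), peak day
(σ = 5 d), widths (σ = 5 d) and base level (σ = 0.01) are independently
perturbed per sample, truncated to keep templates valid. The paper-level
description of real scenes is class-level only; these spreads are the
minimal within-class variability that makes covariance-based separability
meaningful.

What passing tests on these scenes do **not** show: robustness to real
atmospheric-correction residuals, mixed pixels, georegistration error, or
multi-year phenology drift — none of which the generator emulates.

## Curve fitting

All three families have exactly six free coefficients, so their R² values
are comparable. Fitting is bounded trust-region least squares with
analytic Jacobians and tolerances ftol = xtol = 1e-10; it is fully
deterministic (no multistart). Initialisation is data-driven: AG starts at
(min, range, day-of-max — earliest on ties, 40, 40, 2); DL places its
inflections at the first/last crossings of the 50% level; TF starts from
the closed-form harmonic least-squares solution with the frequency frozen
at 2π/365 and then releases it. Bounds keep fits in a single annual cycle —
AG widths 3–200 d and flatness 0.5–10, DL rates 0.5–60 d, TF frequency
within [0.5, 2] cycles per year, the latter because an unconstrained
frequency is routinely overestimated when the dormant season is
unobserved. Non-convergence returns the best iterate flagged
`converged=False` rather than raising. The AG form shares one flatness
exponent across both halves (unlike the TIMESAT original with separate
flatness terms) — implemented exactly as that six-coefficient form is
printed in the applied literature. The four-coefficient DL variant is
deliberately not implemented: it omits the senescence phase that
distinguishes the lagged cordgrass cycle. R² on a zero-variance series is
defined as 0 (with a warning); negative R² is allowed.

The EVI blue-band coefficient defaults to the canonical 7.5 with a config
switch for the 7.0 variant that circulates in the applied literature; both
conventions appear in published tables, so both must be reproducible.

## Phenological metrics

BV/MV are the curve's extrema on a 0.1-day grid over days 1–365; SOS/EOS
are the last up-crossing before / first down-crossing after the global
maximum of the level BV + q(MV − BV), with q = 0.5 by default (the value
that best matches field observations of season timing; a 10–90% sweep is
supported); ROI/ROD are (V₈₀ − V₂₀)/(t₈₀ − t₂₀) on each limb, stored as
magnitudes. Crossings are bracketed on a 1-day grid and refined by
bisection to 0.01 day. Multi-peak TF curves are handled around the global
maximum only — the metric set presumes one growing season. A missing
crossing (flat or monotone curve) sets the affected metric to 0 and flags
it, consistent with the all-zero fallback convention for pixels with fewer
than six observations; a NaN policy is available behind a parameter.

## Separability and evaluation

Class statistics use the sample mean and covariance (denominator n − 1).
Since a class with fewer than seven samples is singular in the
six-dimensional metric space, a ridge ε·I with ε = 1e-8 · tr(Σ)/6 (floored
at 1e-12, triggered whenever the smallest eigenvalue falls below ε) keeps
the Bhattacharyya machinery defined. No feature scaling is applied before
the distance: the Bhattacharyya form is invariant under any affine map
applied jointly to means and covariances. OJMD averages the JMD over
unordered class pairs (summing ordered pairs and halving the count would
give the identical value, by symmetry).

Classification is supporting machinery, not a contribution: a 500-tree
random forest with √p features per split on a stratified 50% holdout,
seeded for reproducibility. Stratification (rather than a simple random
split) guarantees every class appears on both sides. The disagreement
budget follows the standard decomposition: QD = ½ Σ|colsumᵢ − rowsumᵢ| is
the marginal mismatch, AD = Σ min(colsumᵢ − pᵢᵢ, rowsumᵢ − pᵢᵢ) the label
swapping, and OA + QD + AD = 1 exactly.

## Reference study conditions and problem sizes

The climate-calendar comparison (DL vs TF by median OJMD over 20 seeds)
runs the six default classes at 40 samples per class on NDVI — large enough
for stable 6-D covariance estimates, small enough to complete in minutes on
one CPU. Parameter-recovery checks use 40 irregular observation days and
100 noise replicates at σ = 0.02. The Monte-Carlo check of the
Jeffries–Matusita scale against the Bhattacharyya-coefficient integral
uses 10⁶ importance-sampling draws.

## Known limitations

* The generative truth being double-logistic means DL recovery results are
  partly circular; AG/TF conclusions rest on the cross-family tests with
  AG/TF-generated truth.
* The band model's fixed blue/green-to-red ratios understate real spectral
  diversity; GNDVI/WAVI comparisons reflect noise propagation, not
  chlorophyll or water physics.
* Tide events are independent Bernoulli draws; real flooding is
  tide-cycle-correlated and elevation-dependent.
* Single-year, single-season curves only; no leap days (day-of-year domain
  1–365).
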