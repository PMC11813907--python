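# Methods

This note documents the models implemented in `fruitcast`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Thermal time

Thermal time τ is the plain degree-day sum of daily mean air temperatures
from anthesis, base 0 °C. A base of 0 °C is the natural choice for heated
greenhouses held at 17–22 °C: typical fruits then reach harvest near
1000 °C d in 50–60 days, consistent with the 200–900 °C d anchor windows
the pipeline uses. The base is configurable (`ThermalClock(base=...)`),
with daily means clipped at zero after base subtraction; modified
degree-day formulas (upper cutoffs, sine interpolation) are deliberately
out of scope.

Sub-daily logs are reduced to daily means on load. Externally the API
deals in calendar dates; internally arithmetic is in fractional days, so a
query ending mid-day contributes (fraction of day) × (that day's mean).
`mean_temperature` is defined as accumulated degree-days divided by
elapsed fractional days, which makes `mean × elapsed = cumulative` an
exact identity rather than an approximation. `invert_thermal_time` returns
the earliest *day boundary* at which a thermal target is reached —
harvest-type decisions happen at day resolution.

## Allometry and density

The fruit volume index treats the fruit as a spheroid:
V = (4/3)π(l/2)(s/2)² = (π/6)·l·s². Mass is strictly proportional,
C = V·d, so the density fit is through-origin least squares
(d = ΣVm/ΣV²); an intercept would contradict C = V·d at V = 0. The
reported r² is consequently the *uncentred* coefficient of determination
(residuals relative to the zero line), the coherent definition for a
no-intercept model. Caliper pairs where the "short" reading exceeds the
"long" by more than 5% are swapped and flagged rather than rejected —
reading-order mistakes are common and the geometry is unambiguous.

## Growth curves and anchors

Each fruit's estimated masses C(τ) are fitted with an unconstrained OLS
cubic using observations with τ below the scheme window (625 °C d for
E500, 900 °C d for E800). The cubic is a smoothing device, not a
mechanistic growth law; its job is to interpolate an irregular measurement
schedule onto fixed anchors. Internally τ is scaled to [0, 1] before
building the Vandermonde matrix (conditioning), and coefficients are
rescaled back, so the stored coefficients act on raw °C d.

Quality control is a per-fruit r² gate (0.94 for E500, 0.95 for E800):
fruits below the gate are excluded from model building but retained in the
anchor table so exclusion rates can be audited. Fits are not constrained
to be monotone; a non-monotone fitted derivative on [0, window] sets an
audit flag only. Anchors below the first observed τ are obtained by
extrapolating the cubic and flagged `extrapolated` — the 200 °C d anchor
can precede the first caliper visit. Each scheme fits its own curve from
its own window; the two windows select different observation subsets, so
reusing one fit would conflate them.

## Feature table, normalisation and ridge

One row per quality-controlled fruit with a recorded harvest mass:
anchor masses (g), optionally the mean temperature from anthesis to the
last in-window measurement date ("the prediction period"), and harvest
mass (g) as the target. Features are z-scored with the *sample* standard
deviation (ddof = 1), fitted on the training split only; test rows always
pass through the training statistics. The target stays in grams so MAPE,
R² and RMSE read directly in physical units.

Ridge is solved in closed form on the normalised design,
w = (XᵀX + λI)⁻¹Xᵀ(y − ȳ), intercept ȳ unpenalised. At λ = 0 this is OLS;
an ill-conditioned system at λ = 0 raises an error advising
regularisation. λ is selected from the grid {0.01, 0.1, 1, 10, 100} by
repeated 10-fold cross-validation (3 repeats by default) maximising mean
held-out R²; rows are ordered by fruit id before folding so the selection
is invariant to input order, and ties break toward the larger λ.
Extra-trees and gradient-boosted trees are available behind the same
fit/predict interface as scikit-learn-backed plug-ins for comparison; the
ridge path is the reference implementation.

## Evaluation

MAPE = 100/n·Σ|P−H|/H, RMSE = √(mean squared error), and
R² = 1 − Σ(P−H)²/Σ(H−H̄)² with the *observed* masses in the denominator —
the standard definition, under which a constant predictor at the observed
mean scores exactly 0 and worse models go negative. The
temperature/thermal-time analysis is a Pearson correlation between each
fruit's growing-period mean temperature and its cumulative temperature at
harvest, with the usual t-distribution p-value.

## The synthetic greenhouse

The simulator generates everything the pipeline consumes. Defaults define
the standard experiment and are not tuned per run.

**Temperature.** Daily means follow a sinusoid (annual mean 19.5 °C,
amplitude 2.5 °C, peak mid-July — about 22 °C in summer falling to 17 °C
in winter, typical heated-greenhouse set points) plus N(0, 1.5 °C) daily
jitter. Season: 1 September to 30 June.

**Fruits.** Anthesis dates are uniform over the part of the season leaving
enough degree-days to reach harvest. Per fruit, with cultivar parameters:

- growing-period mean temperature T̄ (anthesis to the nominal
  1000 °C d harvest threshold);
- final-size factor f(T̄) = max(0.5, 1 − 0.002·(T̄ − 19.5)²);
- asymptotic mass M ~ N(mass_mean·f(T̄), sd_early), truncated positive;
- trajectory m(τ) = M·logistic(0.008·(τ − mid)) with per-fruit midpoint
  mid ~ N(450, 80) °C d;
- a **late-growth factor**: a fraction `late_frac = 0.5` of each
  cultivar's mass variance is only realised after the early anchor window,
  as two mean-one lognormal stages ramping over 500→800 and 800→1000 °C d
  with variance split 40/60 (`late_split = 0.6`). This encodes the
  field observation that cell-expansion and ripening outcomes are not
  visible to early measurements: early anchors are intrinsically imperfect
  predictors, late anchors see more, and high-variability cultivars are
  harder to predict at any stage. sd_early = mass_sd·√(1 − late_frac), so
  the cohort's total harvest-mass spread still matches the cultivar's
  published SD;
- harvest at τ_H = 1000 − 30·(T̄ − 19.5) °C d (warm periods need fewer
  degree-days), quantised to day boundaries;
- caliper visits every 3.5 days (once or twice a week) from fruit set
  (τ ≈ 50 °C d) to harvest; diameters by inverse allometry from m(τ) with
  a per-fruit aspect ratio and N(0, 0.05 cm) noise per reading; harvest
  mass weighed with N(0, 5 g) noise. Density-calibration pairs carry
  N(0, 3 g) mass noise.

The midpoint/late-stage spreads were calibrated once so that simulated
cohorts reproduce the accuracy regime reported for real greenhouse
cohorts — held-out MAPE in the 5–20% band, late-window (E800) models
beating early-window (E500) ones, and low-SD cultivars beating high-SD
ones — and then frozen. An exactly-cubic trajectory family
(`growth_shape="cubic"`, a smoothstep in τ) exists purely for validation:
with all noise off, the fitting stage must recover it to machine
precision and the pipeline's held-out MAPE drops below 0.5%.

**What the simulator does not capture.** Truss-level competition and fruit
load, fruit abortion, disease/drop censoring, sensor drift, and any
per-fruit randomness in the harvest rule. The last point matters when
reading the temperature/thermal-time correlation: simulated r is ≈ −0.99
because τ_H is a deterministic function of T̄, whereas real cohorts show
r around −0.5 to −0.7. Passing tests demonstrate that the pipeline
recovers known generative structure under realistic noise — not that the
accuracy figures transfer verbatim to any particular greenhouse.

**Determinism.** One seeded generator with a documented draw order;
identical configs produce bit-identical CSVs.

## Problem sizes

The standard experiment uses 300 fruits and 150 calibration fruits per
cultivar — the same order of magnitude as real per-cultivar cohorts
(~400–550 fruits). Multi-seed qualitative checks (window and cultivar
orderings) average 20 seeded replicates of 150-fruit cohorts, enough for
the orderings to be stable while keeping the full suite fast.

## Known limitations

- The cubic can go negative or non-monotone near the window edges for
  sparse fruits; such anchors are flagged, not corrected.
- Density is a single per-cultivar constant; per-fruit density variation
  is out of scope.
- The CV grid is small and fixed; tree-ensemble plug-ins are not tuned.
- `invert_thermal_time` is day-resolution by design; sub-day inversion
  would require an interpolation convention the data cannot support.
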