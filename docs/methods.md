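# Methods

## The geometric emission score

An atomizer is summarized by three bench measurements: total heated coil
wire length `L` (mm), wick outer surface area `SA` (mm²) and wraps per
coil `n`. The score

```
x = L / (SA · n)        [mm⁻¹]
```

rises with the amount of heated wire and falls with the wick area
available to absorb that heat and with the number of contact turns that
distribute it. A high score flags a build expected to run hot and degrade
more PG/GL into carbonyls. The score is dimensionally mm⁻¹; its unit
choice only rescales the calibrated rate `b`.

### Aggregation conventions for multi-coil builds

The field's device tables rarely state whether a recorded coil length is
per wire or total. The default convention (`Aggregation.SUM_WIRES`)
treats the recorded length as per wire: total length is
`wire_length_per_wire × wire_count`, wick areas sum over physical wicks,
and wraps stay per coil. This makes the score invariant under duplicating
an identical coil+wick unit — a dual build scores the same as one of its
halves — so dual devices sit on the same axis as singles. The alternative
(`Aggregation.PER_COIL`) takes the recorded length as already total, for
tables that tabulate it that way. Wick area is the lateral cylinder area
`π·d·l` (ends abut the tank and are not heated contact surface); a
directly measured per-wick area can be supplied instead. Parallel builds
share one wick and sum both wire lengths; no extra term models the zero
inter-wire spacing — that effect is left to the data.

## Emission summaries

A session's response is the TOTAL of the six carbonyls divided by grams
of e-liquid consumed (µg/g). Normalizing per e-liquid mass inherently
absorbs much of the power dependence, which is why the core score needs
no power term. Amounts declared in nmol are converted with a fixed
molar-mass table. A missing analyte is an error, never treated as zero.

Replicates are screened with a sequential two-sided Grubbs test on the
normalized totals at α = 0.05 (two-sided, totals rather than per-analyte
values, both package choices — the original procedure names only the
test):

1. compute `G = max|yᵢ − ȳ|/s` (sample SD, n−1); zero-variance samples
   (within rounding noise) give G = 0;
2. compare against `G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²))`, `t` the
   upper `α/(2n)` Student-t quantile at `n−2` degrees of freedom;
3. while `G > G_crit`, remove the most extreme value (ties break to the
   larger value — gross failures such as burnt coils are high-side) and
   repeat; the retained sample never drops below 2 values and the test
   itself needs n ≥ 3.

The summary is the mean and standard error `s/√n_used` of the survivors.

**Known limitation (masking).** With triplicate/quadruplicate replicates,
two gross outliers in the same device mask each other: for k equal
extremes among n values `G → √((n−k)(n−1)/(nk))`, which for k = 2, n = 4
is 0.866, below `G_crit(4, 0.05) = 1.481`, so screening never starts. At
a 10% independent per-session outlier rate roughly a quarter of injected
outliers co-occur this way, capping per-session sensitivity near ~72%
(measured) despite essentially perfect detection of isolated outliers and
a false-flag rate under 2%. A contaminated device mean can then visibly
degrade the original-scale fit R² of a single study. Detecting
co-occurring gross outliers at such small n would need a different
procedure (e.g. generalized ESD with a higher removal budget) or more
replicates; the sequential Grubbs screen is kept as the faithful
procedure.

## Exponential calibration

Emissions are modelled as `y = a·exp(b·x)`. Two fit methods:

- `log_linear_ols` (default): ordinary least squares of `ln y` on `x`
  (statsmodels), `a = exp(intercept)`, `b = slope`; optional
  inverse-variance weighting by device SE. This matches the
  spreadsheet-style "exponential trendline" and provides log-scale 95%
  intervals for `b` and `ln a`.
- `nonlinear_ls`: original-scale least squares (scipy `curve_fit`)
  initialized from the log-linear solution; a convergence failure raises
  an error carrying the log-linear fallback. Both methods require
  positive emissions and at least 3 devices with non-constant scores.
  Note the original-scale objective is dominated by the
  highest-emitting devices and its optimum can sit far from the
  log-scale one on noisy data.

Goodness of fit is reported two ways, because trendline tools print the
log-scale value while predictive claims should be judged on the original
scale: `fit_r2 = 1 − SSres/SStot` on the original scale, and `log_r2` for
the underlying log regression. Constant data fitted exactly score 1 by
convention; a flat curve on varying data scores ≤ 0 and is reported, not
clamped.

**Predictive R².** Out-of-sample accuracy is `1 − SSres/SStot` with
predictions used as-is against the identity line — *not* a squared
correlation of a refitted line. This convention can go negative when a
calibrated candidate predicts worse than the mean of the observations,
which is exactly the informative outcome when ranking candidate scores.
The evaluation fleet may overlap the training fleet (the emulated study
calibrates on nine devices and evaluates all twelve); both id sets are
recorded so strict held-out evaluation is equally expressible.

**Candidate ranking.** Candidate scores are monomials over
{L, SA, n, W} (products, quotients, real powers, positive coefficient) —
expressive enough for every printed alternative while keeping evaluation
safe and positive. Built-ins: the geometric score, `W·L/(SA·n)` and
`W/(L·SA)`. Ranking sorts by predictive R² descending, ties
lexicographically by name; a candidate that errors on a device (e.g. no
power recorded) is reported as failed, never dropped.

## Synthetic-data generator

The generator emulates the study conditions, not any particular dataset:

| parameter | default | rationale |
|---|---|---|
| n_devices | 12 | emulated fleet size spanning all styles/orientations |
| replicates_per_device | 4 | "minimum triplicate" plus one |
| a_true | 5 µg/g | baseline total carbonyls at score 0 |
| b_true | 8 per score unit | spreads scores 0.03–0.6 over ~1.3–50× baseline |
| noise_sigma | 0.2 | 20% multiplicative (lognormal) session noise |
| outlier_rate | 0.05 | occasional burnt-coil failures, per session |
| outlier_multiplier | 20 | gross high-side failure |
| wire length | 40–120 mm | brackets a real 98 mm rebuildable build |
| wraps | 4–10 | brackets the 8-wrap build |
| wick d × l | 2–4 × 8–15 mm | plausible cotton wick cylinders |
| power | 10–80 W | commercial range incl. the 65 W build |
| e-liquid per session | 0.5–1.5 g | plausible 40-puff consumption |

Sessions are `y = a_true·exp(b_true·score)·exp(ε)`, `ε ~ N(0, σ²)`, per
gram, times the sampled e-liquid mass; multiplicative noise makes the
absolute replicate spread grow with the device mean (constant CV), the
pattern seen in high-emitting devices. Outliers are high-side only.
The total is split across the six carbonyls with fixed proportions
(formaldehyde 0.30, acetaldehyde 0.40, acetone 0.08, propanal 0.12,
butyraldehyde 0.05, benzaldehyde 0.05 — aldehyde-dominant as in measured
carbonyl panels); the split never affects the totals-based analysis.
Draws for noise, outliers and e-liquid are consumed for every session
regardless of configuration, so configurations differing only in noise
or outlier settings are draw-for-draw comparable at the same seed.

What the generator does **not** emulate: puff topography, coil
temperature dynamics, analyte-specific chemistry, device-specific wick
degradation over sessions, inter-analyte correlation structure, or
score measurement error. Passing tests therefore demonstrate the
pipeline's statistical behavior under the assumed noise law, not the
field accuracy of the geometric model on real devices.

## Verification experiments and problem sizes

The acceptance surface (tests/test_acceptance.py and
scripts/acceptance.py) measures, per run:

- noiseless closed loop (σ = 0, no outliers): fit and predictive R² equal
  1 to machine precision;
- parameter recovery: 200 fleets of 12×4 at σ = 0.2; median relative
  error of `b` ≈ 2–3%, of `a` ≈ 4%;
- model selection: the generating geometric score ranks first against the
  two power candidates in ≈ 99% of 200 fleets;
- Grubbs screening at a 10% injection rate: false-flag rate ≈ 1.5%;
  sensitivity ≈ 72%, capped by the masking limitation above;
- oracle agreement: both fit methods against a brute-force grid search
  over (ln a, b); predictive R² against the hand formula; Grubbs critical
  values against a bisection inversion of the t CDF for n = 3–30.

These sizes (200 fleets of 48 sessions each) keep each experiment within
seconds while giving ~±3% Monte-Carlo resolution on the reported rates.

## Numerical choices

- Sample SDs use the n−1 denominator throughout.
- Spread below `1e−12` of the data scale counts as zero variance (G = 0);
  an original-scale SSres below rounding noise on constant data counts as
  an exact fit.
- CSVs are written with `%.17g` and read with round-trip float parsing,
  so benchmark files reproduce in-memory objects exactly.
- Device summaries sort sessions by replicate id before screening, making
  the procedure invariant to input order.
- Seeds: fleet geometry uses `seed`, sessions `seed + 1`; replicated
  experiments stride seeds so streams never overlap.
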