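# Methods

This note documents the models implemented in `dairytherm`, their
assumptions, the defaults that matter, and the design decisions taken where
the problem was genuinely open.

## Psychrometrics and the THI family

Dewpoint uses the Magnus approximation with constants A = 17.67,
B = 243.5 °C and reference saturation pressure 6.112 hPa:

    gamma = A·T/(B+T) + ln(RH/100),    Tdp = B·gamma / (A − gamma)

Its domain is RH ∈ (0, 100] (the log diverges at 0) and T > −243.5 °C; at
saturation the formula collapses to Tdp = T exactly.

Wet-bulb temperature is the root of the psychrometer balance

    e(Tdp) = es(Twet) − A_psy · P · (T − Twet)

with `es` the same Magnus curve (so the three temperatures are mutually
consistent), P the surface pressure in hPa and A_psy = 6.6×10⁻⁴ K⁻¹, the
standard coefficient for an unventilated psychrometer. The balance is
strictly monotone in Twet on [Tdp, T], so bisection converges
unconditionally; we iterate to 0.001 °C (well below sensor precision) with
a cap of 100 iterations, which a halving bracket can never exceed for any
physical temperature span. Pressure defaults to the standard atmosphere
(101.325 kPa) because farm stations rarely report it; the wet-bulb
depression term makes the result measurably pressure-sensitive, so a real
station value can be supplied per record.

Nine THI variants are evaluated exactly as printed in the animal-
biometeorology literature, with strict left-to-right grouping. Two
consequences are used as internal checks: THI₁ − THI₄ ≡ 6.4 for any input
(both reduce to 0.72·(T + Twet) plus a constant), and every variant is
strictly increasing in T at fixed humidity. Variant 5 circulates in two
readings that differ in one factor, `(1.8 + T − 26)` versus
`(1.8·T − 26)`; summary statistics cannot discriminate them because the
multiplier `0.55 − 0.0055·RH` is near zero at high humidity. The package
defaults to the first ("printed") dialect and exposes
`thi5_dialect="corrected"`; neither is asserted to be the true form.

THI₉ (the regression form 3.43 + 1.058·T − 0.293·RH + 0.0164·T·RH + 35.7)
drives all heat-stress logic downstream, as the variant best correlated
with physiological strain in cattle.

## Synthetic farm generator

The generator exists because robotic-farm records are proprietary; it
defines a *known* generative response so that the rest of the pipeline can
be tested for parameter recovery.

**Weather** (daily maxima, Southern-Hemisphere phase): temperature is a
seasonal cosine (annual mean 21.3 °C, amplitude 6.8 °C, peak day-of-year
15) plus an AR(1) anomaly (coefficient 0.62, innovation sd 3.0 °C), clipped
to [−5, 48] °C. Daily-maximum RH is anti-phased with the seasonal cycle
(base 78%, amplitude 18%) and coupled negatively to the temperature anomaly
(−1.6 %/°C), clipped to (5, 100]. Rainfall is Bernoulli(0.30) wet days with
gamma(0.65, 9 mm) amounts; wind is gamma(9, 1.8 km/h); direction uniform.
These defaults put seasonal THI₉ means near 48 (winter) and 77 (summer)
with heatwave excursions above 90 — a temperate, hot-summer dairy climate.
Not emulated: multi-day synoptic rain structure, diurnal cycles (the
generator produces daily maxima directly), inter-annual trends.

**Herd**: breeding values for heat tolerance uniform on [93, 112] (the
"similar-tolerance" herd convention; the score is centred at 100, and 93 ⇒
7% less tolerant, 110 ⇒ 10% more). Parities 1–8 with a decaying
distribution, staggered calvings over the preceding year, 10% of cows
'carryover' animals with extended (620–760 day) lactations, the rest
330–420 days; a 60-day dry period separates lactations.

**Response model** per cow-day (latent, then observation noise):

* yield = Wood(A=21, b=0.20, c=0.004)(lactation day) × parity scale
  (0.85 for first lactation, ~1.0–1.04 after) ×
  max(0, 1 − k_y·s(bv)·max(0, THI₉ − 72)), k_y = 0.018 per THI unit,
  s(bv) = 1 − (bv − 100)/100; zero on no-milking days (2% of lactating
  days, voluntary system, plus the dry period);
* protein % = 3.55 − 0.010·max(0, THI₉ − 50);
* fat % = 4.75 − 0.020·latent yield (dilution);
* intake = programmed feed × 0.92 × max(0, 1 − k_i·s(bv)·(THI₉ − 72)⁺),
  k_i = 0.012, never exceeding programmed + 0.5 kg.

Seasonality of composition enters through THI₉ rather than the calendar:
that is both the physically claimed mechanism and what makes the mapping
identifiable from the 21 inputs (calendar date is not an input).
Observation noise is Gaussian (sd 2.2 kg yield, 0.16% protein, 0.32% fat,
0.55 kg intake), clipped at zero. The noiseless latent values are stored so
evaluation can compute the generative noise ceiling. Defaults were chosen
once so that yearly target summaries fall inside realistic envelopes
(mean yield ≈ 22 kg/day, protein ≈ 3.4%, fat ≈ 4.3%, intake ≈ 6.5 kg/day)
and hot seasons are visibly less productive.

What passing tests on this generator do *not* show: robustness to sensor
faults, missing-data patterns, pasture-intake variation (unmeasurable under
commercial grazing and deliberately absent), disease dynamics, or the real
farm's unknown response shape. They show that *if* production responds to
heat through a THI-threshold mechanism, the pipeline recovers it to the
accuracy the noise permits.

## Feature matrix, normalization, split

The column order is frozen (5 raw weather maxima, Tdp, Twet, THI₁–₉,
5 management fields; 4 targets) and stamped into every trained model, which
refuses a differently ordered matrix. Daily aggregation takes maxima of T,
RH and wind speed; rainfall is the final value of the station's daily
running total; the daily wind direction is the direction *at* maximum wind
speed (earliest timestamp on ties) because a maximum over compass degrees
is physically meaningless — a `literal-max` option reproduces the naive
reading. Rows with any missing input or target are dropped and counted (no
imputation); zero-milking rows are retained, zero being a legitimate yield.

Normalization is per-column min-max onto [−1, 1], fitted by default on the
training rows only (fitting on all rows leaks the test range;
`normalize_on="all"` preserves the literal all-data convention). Test
values outside the fitted range map outside [−1, 1] and are not clipped.
The 70/30 split is a uniform random permutation over cow-day rows — not
cows — with |train| = round(0.7·n); the same cow may appear in both
partitions on different days, which matches per-sample accounting where
observations = samples × 4 targets.

## Network and trainer

One network serves all four targets: y = W2·tanh(W1·x + b1) + b2 with 10
hidden neurons (264 weights for 21 inputs). Initialization is
Nguyen–Widrow over the [−1, 1] cube, seeded. The Jacobian of the stacked
errors is exact per-sample backpropagation, accumulated blockwise into
JᵀJ (264×264) so memory is flat in sample count.

Training is Levenberg–Marquardt on F = β·E_D + α·E_W:
Δw = −(β·JᵀJ + (α+μ)I)⁻¹(β·Jᵀe + α·w), with μ starting at 0.005,
×10 on rejection, ×0.1 on acceptance, capped at 10¹⁰. A step is accepted
only if F decreases at the current (α, β), so the recorded history is
monotone within steps by construction. After each accepted step the
evidence framework re-estimates γ = N_w − α·tr(H⁻¹), α = γ/2E_W,
β = (N_D − γ)/2E_D, initialized at α = 0, β = 1. Numerical choices:

* tr(H⁻¹) is computed from the eigenvalues of JᵀJ (Σ 1/(βλᵢ + α), λ
  clamped at 0). The tanh layer always carries near-null gauge directions
  (compensating W1/W2 rescalings), so a Cholesky of β·JᵀJ + α·I fails
  intermittently at small α; the eigenvalue form is unconditionally stable
  and costs microseconds at this size. At α = 0, γ = N_w identically
  (no prior constrains anything), so the solve is skipped.
* The curvature used for the evidence update is the one accumulated at the
  step's starting point, saving a second Jacobian pass per epoch; with
  LM-sized steps the difference is far below the update's own
  approximation error.
* Stopping: max epochs, infinity-norm gradient below 10⁻⁷, μ cap, or zero
  error.

On noiseless targets E_D → 0 drives β → ∞ and γ → its ceiling (every
curvature direction becomes well-determined relative to the vanishing
noise); γ falls well below N_w — the capacity-pruning regime — only when
noise is substantial relative to the data volume. Both behaviours are
regression-tested.

There is no early-stopping validation set: the α·E_W term plays that role,
mirroring the two-way 70/30 split convention.

## Evaluation surface

Stage metrics pool the four normalized targets into one stream: Pearson R,
slope b of the least-squares fit obs = b·pred + a, and MSE (normalized
scale, which is what makes MSE comparable across targets); observation
counts are samples × 4. Per-target test metrics and de-normalized RMSEs are
emitted as a supplement.

"95% confidence bounds" for outlier counting is read as the two-sided 95%
*prediction* interval of the observed-on-predicted regression — only a
per-observation band yields outlier counts — with half-width
t₀.₉₇₅,ₙ₋₂·s·√(1 + 1/n + (x−x̄)²/Sxx); a `bounds="confidence"` flag gives
the mean-response band instead. Under correctly specified Gaussian
residuals the exclusion fraction converges to 5%; the pipeline's real
residuals are a mixture (zero-yield rows are near-deterministic, hot days
noisier), so its observed fraction runs above 5% — the machinery asserts
the Gaussian limit, not any particular mixture value.

Seasonal summaries use meteorological three-month seasons with a
configurable hemisphere; December joins the following January's
season-year.

## Drafting gate

Stress requires *both* an environmental trigger (THI₉ > 72 by default,
bounded to the plausible [50, 90] window) and a predicted production
shortfall against farm-set minima — the gate is driven by the model, not
by weather alone; a disjunctive `mode="any"` is available. The state
machine is NORMAL → STRESSED_DAY1 → {STRESSED_PERSISTENT, NORMAL} and
PERSISTENT → {PERSISTENT, NORMAL}; routes are COOLING on the first
stressed day (milking deferred — an `always_milk` flag upgrades this for
farms that milk regardless, since the convention is genuinely ambiguous),
COOLING_AND_MILK while persistent (milking avoids mastitis), MILKING
otherwise. Cooling does not feed back into the next day's inputs: its
physiological benefit is unmodeled. Decision logs are auditable by replay
against the transition table, and raising the THI threshold can only
reduce non-MILKING decisions (monotonicity, tested).

## Problem sizes and degenerate inputs

The shipped study configuration is 200 cows × 730 days (146 000 cow-day
rows, 584 000 observations) trained for 50 LM epochs — past the point
where the test R is within a few thousandths of the generative noise
ceiling, so further epochs polish E_D without changing conclusions; the
unit suites use farms of 8–36 cows. Degenerate inputs are rejected loudly:
saturated air collapses the psychrometrics consistently, constant columns
refuse normalization by name, empty partitions refuse to split, inverted
wet-bulb brackets and humidity outside (0, 100] raise with the offending
date.

## Known limitations

* The generator's response is the package's own construction; nothing here
  validates the THI-threshold model against real herds.
* Pooled-R reporting follows the single-number-per-stage convention; it
  overweights the targets with the widest normalized signal (yield,
  intake) relative to protein and fat, whose per-target correlations are
  intrinsically lower at the default noise settings.
* Heat-tolerance breeding values influence the simulated response but are
  deliberately not a model input, so their variance contributes an
  irreducible (small) gap to the noise ceiling.
* The wet-bulb solve assumes the unventilated psychrometer coefficient;
  aspirated instruments would need A_psy ≈ 6.2×10⁻⁴ K⁻¹.
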