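# Methods

## The problem

The dawn phenomenon (DP) is an abnormal early-morning glucose rise —
from the overnight (nocturnal) nadir up to the pre-breakfast level — in
the absence of nocturnal hypoglycemia. From CGM data it is classically
scored per night as a binary call: DP occurred if the measured rise
reached a threshold γ (20 mg/dL is the usual criterion in type 2
diabetes; 10 mg/dL has been proposed for type 1). The difficulty is
that CGM sensor error is of the same order as γ, so the binary call
both misses nights whose true rise was above γ but measured below it
and over-credits nights measured just above it.

`dawnprob` replaces the binary call with a probability. Each CGM
reading's error is modelled as an independent zero-mean Gaussian with
standard deviation σ. A night's measured rise r then defines a Gaussian
likelihood for the true rise, and the probability that a true rise ≥ γ
occurred is the upper-tail mass

    Prob(DP | r) = 1 − Φ((γ − r) / s),

with Φ the standard-normal CDF and s the effective SD of the
likelihood. Summing these probabilities over a participant's valid days
gives the *effective number of DP days* N_DP = Σᵢ Prob(dᵢ), and
100·N_DP/D is the participant's DP frequency (% of the D valid days).

## Deriving σ from device accuracy

Manufacturers publish accuracy as a within-band fraction: for the
FreeStyle Libre Pro, 80.2% of readings fall within ±20 mg/dL of
reference in the 80–180 mg/dL range that covers overnight glucose in
this population. Solving P(|X| ≤ 20) = 0.802 for a zero-mean Gaussian
gives σ = 20 / z₍₀.₉₀₁₎ = 15.54 mg/dL. The same derivation applies to
any device whose within-band accuracy is known; presets live in
`DEVICE_ACCURACY` (the Dexcom G6 entry is a placeholder to be
overridden from config with the device's published figures).

## The scale-mode choice

The measured rise is the difference of two noisy readings
(pre-breakfast minus nadir), whose error SD is σ_diff = √2·σ ≈ 21.97
mg/dL. There are therefore two defensible conventions for the
likelihood SD s:

* `"diff"` — s = √2·σ, consistent with the rise being a difference of
  two i.i.d. measurements;
* `"single"` — s = σ, the per-measurement SD, which treats the nadir as
  if it were noiseless.

The two give materially different probabilities (a rise of 15 mg/dL at
γ = 20 maps to 0.41 under `"diff"` and 0.37 under `"single"`). Rather
than defaulting silently, `scale_mode` is a mandatory parameter of
`ErrorModel` and of every pipeline config; the CLI's `--paper-style`
flag presets `"single"`, the convention under which the package's
worked example reproduces its reference numbers. Strictly, `"single"`
is also not unreasonable physically: the nadir of a smooth overnight
profile is estimated from many nearby readings, so its effective error
can be far below a single reading's.

Note one subtlety of the probabilistic estimator: it is *not* unbiased
for the per-night truth at fixed true rise r (for r ≠ γ the mean
assigned probability is a √2-smoothed step, not the step itself). Its
correct calibration property is Bayesian: under a locally flat prior on
the true rise, Σᵢ pᵢ is an unbiased estimate of the number of nights
whose true rise reached γ. Both facts are exercised in
`tests/test_synthetic.py::TestCalibration`.

## Breakfast detection

Only days with a valid breakfast enter the DP computation. Three rules
define a breakfast: (i) start between 05:00 and 11:00; (ii) rise from
start to the post-start peak ≥ 40 mg/dL; (iii) earliest qualifying
segment wins. The underlying segment extraction is, in the original
clinical workflow, a manual annotation step; this package reconstructs
it deterministically as local-minimum→peak excursions on the raw
sampled curve (no smoothing), with a 3-hour peak-search horizon
truncated at the next local minimum, and plateau ties resolved to the
earliest sample. Manual annotations, when supplied, take precedence:
the segment is anchored at the sample nearest the annotated start and
rules (i)–(ii) still apply as filters. The reconstruction is this
package's own deterministic reading of the published rules, not a
reimplementation of the original semi-automated tool.

The nocturnal nadir is the minimum reading from midnight to the
breakfast start inclusive (earliest sample on ties), which guarantees
rise ≥ 0. A day whose earliest sample is at or after the breakfast
start has no overnight record and is marked invalid. No nocturnal
hypoglycemia exclusion is applied by default (the probabilistic
computation does not operationalize one); a nadir-floor filter can be
added by callers who need it.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| γ (DP threshold) | 20 | mg/dL | standard T2D criterion; 10/30 in sensitivity analysis |
| σ | derived from (band, fraction) | mg/dL | never hard-coded; device presets store the published accuracy pair |
| scale_mode | none (mandatory) | — | two defensible conventions, see above |
| breakfast window | 05:00–11:00 | clock | rule (i) |
| min breakfast rise | 40 | mg/dL | rule (ii), from post-breakfast response studies |
| peak-search horizon | 3 | h | bounds the excursion; configurable |
| wear requirement | ≥10 usable days, ≥70% of nominal samples/day | — | consensus-style completeness; the 70% day-completeness cut is this package's choice (not defined in the source workflow) and is configurable |
| TIR range / cutoff | [70, 140] closed / 90% | mg/dL, % | overnight [00:00,06:00), daytime [06:00,24:00); closed interval is this package's documented choice |

## Cohort statistics

Per-participant summaries exist under both models. Probabilistic:
frequency = 100·N_DP/D; magnitude = mean measured rise over all valid
days (a probability-weighted mean is exported as a clearly-labelled
extra column, not used in headline summaries). Binary: frequency =
100·(#rise ≥ γ)/D; magnitude = mean rise over binary-DP days only
(absent when none) — which is why binary magnitude ≥ probabilistic
magnitude whenever a binary-DP day exists. Day-to-day variability is
the coefficient of variation (SD/mean·100) of the daily probability
and rise series, undefined for a zero mean or fewer than two days.

Group comparisons use Kruskal–Wallis (≥3 groups) with Dunn's post-hoc
test on pooled midranks (tie-corrected; raw two-sided normal p-values
reported alongside Holm-adjusted ones — raw is the default for
comparability), and the exact-capable Mann-Whitney rank-sum test for
two groups. Dunn's test is implemented here directly and is checked in
the test suite against exact permutation enumeration on small groups.
The HbA1c regression is OLS of HbA1c on age, gender, waist
circumference, Hispanic/Latino ethnicity, born-in-Mexico, and DP
frequency, with a rank-deficiency check and a pairwise |Spearman ρ| >
0.95 collinearity guard (the reason BMI and DP magnitude are excluded
as predictors in the canonical covariate set). The γ sensitivity
analysis recomputes probabilities from the retained per-day rises at γ
∈ {10, 20, 30}; the γ = 20 rows reproduce the primary analysis bit for
bit, and mean frequency is non-increasing in γ.

## The synthetic generator

`synthetic.py` generates cohorts with known ground truth. Each day's
true curve is piecewise-linear through anchors: bedtime level, nadir at
a uniform time in 01:00–04:45, flat plateau, dawn ramp, a 3 mg/dL
pre-meal dip ending exactly at the (grid-aligned) breakfast start, a
meal peak ≥ 40 mg/dL above the start within an hour, decay to a daytime
baseline with lunch and dinner bumps, and return to the evening level.
The dip makes the breakfast start a strict local minimum of the sampled
curve (so the detector can find it) without descending below the nadir
(so the noiseless measured rise equals the labelled true rise exactly).
Sensor noise is additive i.i.d. Gaussian, floored at 1 mg/dL.

True rises are drawn per night from a two-part mixture: with
probability `true_dp_rate` an above-γ rise (exponential excess by
default), otherwise a below-γ uniform. Default stratum parameters order
the DP burden T2D > pre-T2D > at-risk (rates 0.55/0.32/0.20) and give
each stratum HbA1c, age, waist, gender and ethnicity distributions
consistent with a predominantly Hispanic/Latino, middle-aged,
majority-female cohort; these are qualitative settings, not a claim to
reproduce any specific cohort's percentages.

What the generator does **not** emulate: physiological glucose–insulin
dynamics, autocorrelated or glucose-dependent sensor error, skipped or
late breakfasts, naps/shift work, compression lows. Passing tests on
synthetic data therefore validate the estimator pipeline under its own
error model, not CGM behaviour in free-living conditions.

## The estimator-bias experiment

`estimator_comparison` generates a cohort whose true rises are
concentrated at γ ± 5 mg/dL (the regime where thresholding is most
fragile), runs the full per-day pipeline on the noisy traces with
breakfast anchored at the ground-truth annotations, and compares each
model's mean estimated DP frequency with the true frequency. Both
estimators inherit an *upward* bias from the nadir being a minimum over
many noisy readings (an extreme-value effect that inflates every
measured rise); the probabilistic estimator tempers it — near-threshold
days are weighted by probabilities below one where the binary model
counts them fully — and ends up with the smaller absolute cohort-level
bias. This pipeline-level comparison is the operational content of the
claim that error-aware weighting beats thresholding; at the level of a
single noisy rise with a known nadir, smoothing alone would not confer
an advantage.

## Numerical choices

* Probabilities are carried at full precision; report tables round
  per-day probabilities to 2 dp and effective days to 1 dp.
* Ties: earliest sample wins everywhere (nadir, plateau extrema, peak
  maxima) — determinism on coarse 15-minute grids.
* σ = 0 degenerates every probability to the binary indicator; the
  likelihood curve becomes the unit step at γ.
* Day boundaries are half-open [00:00, 24:00) local clock; a sample at
  exactly midnight belongs to the new day. No time-zone handling.
* mmol/L inputs are rejected, never converted (the thresholds are
  mg/dL-bound).
* Duplicate timestamps: keep first, warn. Malformed CSV rows are
  counted and tolerated up to a configurable 10%.
* Problem sizes in the checked experiments: 3×50×14 noiseless days for
  detector recovery, n = 500 for regression recovery, 200×14 noisy
  days for the bias Monte-Carlo; all chosen as the smallest sizes at
  which the Monte-Carlo standard errors are comfortably below the
  effects being measured.

## Known limitations

* The Gaussian error model is reasonable when overnight glucose is
  near steady state; it degrades under rapid nocturnal excursions.
* The candidate-segment scheme is a deterministic reconstruction of a
  partly manual workflow; on real free-living traces the noise-driven
  local minima make automatic detection less reliable than annotated
  anchoring (which is why the bias experiment anchors on annotations).
* The within-band → σ derivation assumes the published accuracy band
  is symmetric and the error unbiased.
* Per-participant CVs are undefined for participants with a zero mean
  daily series; cohort summaries simply omit them.
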