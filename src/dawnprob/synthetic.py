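"""Synthetic multi-day CGM cohorts with known ground truth.

The generator emulates the statistical structure the error model
assumes: a smooth "true" glucose curve per day, sampled at the device
cadence, plus additive i.i.d. zero-mean Gaussian sensor noise.  Each
day's true curve is a piecewise-linear profile through anchor points:

    bedtime level -> nocturnal nadir (01:00-04:45) -> flat nadir plateau
    -> dawn ramp -> small pre-meal dip ending exactly at breakfast start
    -> post-breakfast meal peak (>= 40 mg/dL above the start) -> daytime
    baseline with lunch and dinner bumps -> evening level.

The small pre-meal dip makes the breakfast start a strict local minimum
of the noiseless sampled curve, so the rule-based detector can recover
the labelled start exactly; the dip does not descend below the nadir,
so the noiseless measured nocturnal rise equals the labelled true rise.

Ground truth records each night's true rise, the true DP indicator
(true rise >= gamma), and the breakfast start, enabling estimator-bias
evaluation of the probabilistic and binary models against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as Date, time as Time, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CGMTrace, DayTrace, write_long_csv
from .dawn import sigma_from_within_fraction

__all__ = [
    "StratumSpec",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "TrueDayLabels",
    "default_cohort_spec",
    "near_threshold_spec",
    "generate_true_day",
    "add_sensor_noise",
    "generate_cohort",
    "write_cohort",
    "estimator_comparison",
    "synthetic_regression_table",
    "LIBRE_SIGMA",
]

#: FreeStyle Libre Pro per-measurement error SD derived from its
#: published within-band accuracy (80.2% within +/-20 mg/dL).
LIBRE_SIGMA = sigma_from_within_fraction(20.0, 0.802)


@dataclass(frozen=True)
class StratumSpec:
    """Generative parameters of one HbA1c stratum.

    ``true_dp_rate`` is the probability that a night's *true* rise is at
    or above gamma; below-threshold rises are uniform on
    ``rise_below_range`` and above-threshold rises are gamma plus either
    an exponential excess (``rise_above_exp_scale``) or a uniform excess
    (``rise_above_range``, offsets from gamma).  Demographic parameters
    feed the synthetic metadata table only.
    """

    n_participants: int
    true_dp_rate: float
    rise_below_range: tuple[float, float] = (0.0, 18.0)
    rise_above_exp_scale: Optional[float] = 10.0
    rise_above_range: Optional[tuple[float, float]] = None
    hba1c_mean: float = 6.0
    hba1c_sd: float = 0.2
    hba1c_range: tuple[float, float] = (5.7, 6.4)
    nadir_range: tuple[float, float] = (85.0, 110.0)
    baseline_range: tuple[float, float] = (100.0, 135.0)
    age_mean: float = 54.0
    age_sd: float = 12.0
    waist_mean: float = 98.0
    waist_sd: float = 12.0
    male_prob: float = 0.29
    hispanic_prob: float = 0.87
    mexico_prob: float = 0.88

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_dp_rate <= 1.0:
            raise ValueError("true_dp_rate must lie in [0, 1]")
        if (self.rise_above_exp_scale is None) == (self.rise_above_range is None):
            raise ValueError("set exactly one of rise_above_exp_scale / rise_above_range")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full generative specification of a synthetic CGM cohort."""

    strata: Mapping[str, StratumSpec]
    days_per_participant: int = 14
    sampling_interval_min: int = 15
    gamma: float = 20.0
    sensor_sigma: float = LIBRE_SIGMA
    breakfast_earliest: Time = Time(6, 30)
    breakfast_latest: Time = Time(9, 30)
    meal_rise_mean: float = 70.0     # mg/dL, truncated below at meal_rise_min
    meal_rise_sd: float = 15.0
    meal_rise_min: float = 40.0
    pre_meal_dip: float = 3.0        # mg/dL dip ending at breakfast start
    start_date: Date = Date(2023, 3, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sensor_sigma < 0:
            raise ValueError("sensor_sigma must be >= 0")
        if 1440 % self.sampling_interval_min:
            raise ValueError("sampling_interval_min must divide 1440")


@dataclass(frozen=True)
class TrueDayLabels:
    """Ground truth for one synthetic night/day."""

    participant_id: str
    date: Date
    true_rise: float
    true_dp: bool
    breakfast_start: Time
    nadir_time: Time
    meal_rise: float


@dataclass
class SyntheticCohort:
    """Generated traces plus ground truth, metadata and annotations."""

    traces: list[CGMTrace]
    ground_truth: pd.DataFrame   # participant_id, date, true_rise, true_dp, ...
    metadata: pd.DataFrame       # participant_id, stratum, hba1c, covariates
    annotations: pd.DataFrame    # participant_id, date, breakfast_start


def default_cohort_spec(n_per_stratum: int = 10, days: int = 14,
                        sensor_sigma: float = LIBRE_SIGMA,
                        seed: int = 0) -> SyntheticCohortSpec:
    """Three-stratum cohort whose DP burden rises with HbA1c stratum.

    The stratum parameters are chosen so that DP frequency and magnitude
    order as T2D > pre-T2D > at-risk, qualitatively mirroring the
    clinical picture, with demographics in line with a predominantly
    Hispanic/Latino, middle-aged, majority-female cohort.
    """
    strata = {
        "at_risk": StratumSpec(
            n_participants=n_per_stratum, true_dp_rate=0.20,
            rise_below_range=(0.0, 18.0), rise_above_exp_scale=8.0,
            hba1c_mean=5.4, hba1c_sd=0.2, hba1c_range=(4.6, 5.69),
            nadir_range=(80.0, 100.0), baseline_range=(95.0, 120.0),
            age_mean=49.8, age_sd=12.3, waist_mean=95.9, waist_sd=12.0,
            male_prob=21 / 64, hispanic_prob=0.84, mexico_prob=0.94),
        "pre_t2d": StratumSpec(
            n_participants=n_per_stratum, true_dp_rate=0.32,
            rise_below_range=(2.0, 19.0), rise_above_exp_scale=10.0,
            hba1c_mean=6.0, hba1c_sd=0.2, hba1c_range=(5.7, 6.4),
            nadir_range=(85.0, 110.0), baseline_range=(105.0, 135.0),
            age_mean=58.0, age_sd=10.6, waist_mean=96.2, waist_sd=10.2,
            male_prob=10 / 57, hispanic_prob=0.91, mexico_prob=0.88),
        "t2d": StratumSpec(
            n_participants=n_per_stratum, true_dp_rate=0.55,
            rise_below_range=(5.0, 19.5), rise_above_exp_scale=15.0,
            hba1c_mean=8.1, hba1c_sd=1.8, hba1c_range=(6.41, 13.0),
            nadir_range=(100.0, 140.0), baseline_range=(130.0, 180.0),
            age_mean=55.8, age_sd=12.2, waist_mean=103.7, waist_sd=12.1,
            male_prob=19 / 52, hispanic_prob=0.87, mexico_prob=0.83),
    }
    return SyntheticCohortSpec(strata=strata, days_per_participant=days,
                               sensor_sigma=sensor_sigma, seed=seed)


def near_threshold_spec(n_participants: int = 200, gamma: float = 20.0,
                        half_width: float = 5.0, true_dp_rate: float = 0.5,
                        days: int = 14, sensor_sigma: float = LIBRE_SIGMA,
                        seed: int = 0) -> SyntheticCohortSpec:
    """Single-stratum cohort with true rises concentrated at gamma +/- half_width.

    The stress case for binary thresholding: every night's true rise is
    uniform within ``half_width`` of the threshold, so sensor noise
    flips many binary calls.
    """
    stratum = StratumSpec(
        n_participants=n_participants, true_dp_rate=true_dp_rate,
        rise_below_range=(gamma - half_width, gamma),
        rise_above_exp_scale=None, rise_above_range=(0.0, half_width),
        hba1c_mean=6.0, hba1c_sd=0.3, hba1c_range=(5.0, 7.5))
    return SyntheticCohortSpec(strata={"near_threshold": stratum},
                               days_per_participant=days, gamma=gamma,
                               sensor_sigma=sensor_sigma, seed=seed)


def _draw_true_rise(stratum: StratumSpec, gamma: float,
                    rng: np.random.Generator) -> float:
    if rng.random() < stratum.true_dp_rate:
        if stratum.rise_above_exp_scale is not None:
            return gamma + float(rng.exponential(stratum.rise_above_exp_scale))
        lo, hi = stratum.rise_above_range
        return gamma + float(rng.uniform(lo, hi))
    lo, hi = stratum.rise_below_range
    return float(rng.uniform(lo, min(hi, np.nextafter(gamma, 0.0))))


def _snap(minute: float, interval: int) -> int:
    return int(round(minute / interval) * interval)


def generate_true_day(spec: SyntheticCohortSpec, stratum: StratumSpec,
                      rng: np.random.Generator, date: Date,
                      participant_id: str = "synthetic",
                      nadir_level: float | None = None,
                      baseline: float | None = None,
                      true_rise: float | None = None,
                      ) -> tuple[DayTrace, TrueDayLabels]:
    """One noiseless day sampled at the device cadence, with its labels."""
    iv = spec.sampling_interval_min
    if nadir_level is None:
        nadir_level = float(rng.uniform(*stratum.nadir_range))
    if baseline is None:
        baseline = float(rng.uniform(*stratum.baseline_range))
    if true_rise is None:
        true_rise = _draw_true_rise(stratum, spec.gamma, rng)
    nadir_min = _snap(rng.uniform(60, 285), iv)                     # 01:00-04:45
    b_lo = spec.breakfast_earliest.hour * 60 + spec.breakfast_earliest.minute
    b_hi = spec.breakfast_latest.hour * 60 + spec.breakfast_latest.minute
    bstart = _snap(rng.uniform(b_lo, b_hi), iv)
    # rejection-sampled truncation: clipping to the floor would park true
    # meal rises exactly on the detector's >= min_rise boundary
    meal_rise = float(rng.normal(spec.meal_rise_mean, spec.meal_rise_sd))
    while meal_rise <= spec.meal_rise_min:
        meal_rise = float(rng.normal(spec.meal_rise_mean, spec.meal_rise_sd))
    evening_elev = float(rng.uniform(10, 30))
    lunch_rise = float(rng.uniform(20, 45))
    dinner_rise = float(rng.uniform(20, 45))
    pre = nadir_level + true_rise
    ramp_start = max(nadir_min + iv, bstart - 60)
    anchors = [
        (0, nadir_level + evening_elev),
        (nadir_min, nadir_level),
        (ramp_start, nadir_level),
        (bstart - 2 * iv, pre + spec.pre_meal_dip),
        (bstart, pre),
        (bstart + 60, pre + meal_rise),
        (bstart + 150, baseline),
        (780, baseline),                     # 13:00
        (840, baseline + lunch_rise),        # 14:00
        (930, baseline),                     # 15:30
        (1110, baseline),                    # 18:30
        (1170, baseline + dinner_rise),      # 19:30
        (1260, baseline),                    # 21:00
        (1440, nadir_level + evening_elev),
    ]
    anchors = sorted({t: v for t, v in anchors}.items())
    t_anchor = np.array([a[0] for a in anchors], dtype=float)
    v_anchor = np.array([a[1] for a in anchors], dtype=float)
    minutes = np.arange(0, 1440, iv)
    glucose = np.interp(minutes, t_anchor, v_anchor)
    idx = pd.Timestamp(date) + pd.to_timedelta(minutes, unit="m")
    day = DayTrace(date, pd.Series(glucose, index=pd.DatetimeIndex(idx)))
    labels = TrueDayLabels(
        participant_id=participant_id, date=date, true_rise=true_rise,
        true_dp=true_rise >= spec.gamma,
        breakfast_start=Time(bstart // 60, bstart % 60),
        nadir_time=Time(nadir_min // 60, nadir_min % 60),
        meal_rise=meal_rise)
    return day, labels


def add_sensor_noise(day: DayTrace, sigma: float,
                     rng: np.random.Generator) -> DayTrace:
    """Perturb each sample with an independent N(0, sigma^2) draw.

    Glucose is floored at 1 mg/dL to keep samples physically positive.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return day
    vals = day.samples.to_numpy() + rng.normal(0.0, sigma, len(day.samples))
    return DayTrace(day.date, pd.Series(np.maximum(vals, 1.0),
                                        index=day.samples.index))


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate the full cohort: identical spec (and seed) => identical output."""
    rng = np.random.default_rng(spec.seed)
    traces, truth_rows, meta_rows, ann_rows = [], [], [], []
    for stratum_name in spec.strata:
        stratum = spec.strata[stratum_name]
        for k in range(stratum.n_participants):
            pid = f"{stratum_name}_{k:03d}"
            nadir_level = float(rng.uniform(*stratum.nadir_range))
            baseline = float(rng.uniform(*stratum.baseline_range))
            day_series = []
            for d in range(spec.days_per_participant):
                date = spec.start_date + timedelta(days=d)
                day, labels = generate_true_day(
                    spec, stratum, rng, date, participant_id=pid,
                    nadir_level=nadir_level, baseline=baseline)
                noisy = add_sensor_noise(day, spec.sensor_sigma, rng)
                day_series.append(noisy.samples)
                truth_rows.append({
                    "participant_id": pid, "date": date.isoformat(),
                    "true_rise": labels.true_rise, "true_dp": labels.true_dp,
                    "breakfast_start": labels.breakfast_start.strftime("%H:%M"),
                    "nadir_time": labels.nadir_time.strftime("%H:%M"),
                    "meal_rise": labels.meal_rise})
                ann_rows.append({
                    "participant_id": pid, "date": date.isoformat(),
                    "breakfast_start": labels.breakfast_start.strftime("%H:%M")})
            samples = pd.concat(day_series)
            traces.append(CGMTrace(pid, samples, device="synthetic"))
            meta_rows.append({
                "participant_id": pid, "stratum": stratum_name,
                "hba1c": round(_truncated_normal(
                    rng, stratum.hba1c_mean, stratum.hba1c_sd,
                    *stratum.hba1c_range), 1),
                "age": round(_truncated_normal(
                    rng, stratum.age_mean, stratum.age_sd, 18, 90)),
                "gender_male": int(rng.random() < stratum.male_prob),
                "waist_cm": round(_truncated_normal(
                    rng, stratum.waist_mean, stratum.waist_sd, 60, 160), 1),
                "hispanic_latino": int(rng.random() < stratum.hispanic_prob),
                "born_in_mexico": int(rng.random() < stratum.mexico_prob)})
    return SyntheticCohort(traces, pd.DataFrame(truth_rows),
                           pd.DataFrame(meta_rows), pd.DataFrame(ann_rows))


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write the cohort in exactly the formats the reader modules accept."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": out / "cgm_long.csv",
        "ground_truth": out / "ground_truth.csv",
        "metadata": out / "metadata.csv",
        "annotations": out / "annotations.csv",
    }
    write_long_csv(cohort.traces, paths["traces"])
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    cohort.metadata.to_csv(paths["metadata"], index=False)
    cohort.annotations.to_csv(paths["annotations"], index=False)
    return paths


def estimator_comparison(spec: SyntheticCohortSpec,
                         scale_mode: str = "single") -> dict[str, float]:
    """Monte-Carlo bias of the probabilistic vs binary frequency estimator.

    Generates the cohort, runs the full per-day pipeline (breakfast
    anchored at the ground-truth annotations, nocturnal rise, DP
    probability and binary call with sigma matching the injected sensor
    noise), and compares each estimator's mean DP frequency with the
    ground-truth frequency (percentage of nights whose *true* rise
    reached gamma).  Returns the mean frequencies and the cohort-level
    absolute biases of both estimators, in percentage points.

    Both estimators inherit an upward bias from the nocturnal nadir
    being a minimum over many noisy readings; the probabilistic
    estimator tempers it by weighting near-threshold days by less than
    one where the binary estimator counts them fully.
    """
    from .breakfast import BreakfastRules
    from .dawn import ErrorModel, evaluate_day
    from .io import split_days

    cohort = generate_cohort(spec)
    rules = BreakfastRules()
    model = ErrorModel(spec.sensor_sigma, scale_mode, spec.gamma)
    ann = {(r.participant_id, r.date): Time.fromisoformat(r.breakfast_start)
           for r in cohort.annotations.itertuples()}
    truth = cohort.ground_truth.groupby("participant_id")["true_dp"].mean() * 100
    prob_freq, bin_freq, true_freq = [], [], []
    for tr in cohort.traces:
        valid = []
        for day in split_days(tr):
            a = ann.get((tr.participant_id, day.date.isoformat()))
            r = evaluate_day(day, rules, model, annotated_start=a)
            if r.valid:
                valid.append(r)
        if not valid:
            continue
        d = len(valid)
        prob_freq.append(100.0 * sum(r.probability for r in valid) / d)
        bin_freq.append(100.0 * sum(r.binary for r in valid) / d)
        true_freq.append(float(truth[tr.participant_id]))
    mean_true = float(np.mean(true_freq))
    mean_prob = float(np.mean(prob_freq))
    mean_bin = float(np.mean(bin_freq))
    return {
        "n_participants": len(true_freq),
        "true_frequency": mean_true,
        "probabilistic_frequency": mean_prob,
        "binary_frequency": mean_bin,
        "probabilistic_abs_bias": abs(mean_prob - mean_true),
        "binary_abs_bias": abs(mean_bin - mean_true),
    }


def synthetic_regression_table(n: int, beta: Mapping[str, float],
                               noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Covariate table with HbA1c generated from a known linear model.

    ``beta`` maps ``intercept`` and the regression predictor names to
    their true coefficients; HbA1c is the linear predictor plus
    N(0, noise_sd^2) noise.  Used for parameter-recovery checks of the
    regression fit.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "participant_id": [f"r{i:04d}" for i in range(n)],
        "age": rng.normal(54, 12, n),
        "gender_male": (rng.random(n) < 0.3).astype(int),
        "waist_cm": rng.normal(98, 12, n),
        "hispanic_latino": (rng.random(n) < 0.87).astype(int),
        "born_in_mexico": (rng.random(n) < 0.88).astype(int),
        "dp_frequency": rng.uniform(0, 100, n),
    })
    lin = np.full(n, float(beta.get("intercept", 0.0)))
    for name, b in beta.items():
        if name != "intercept":
            lin = lin + b * df[name].to_numpy(dtype=float)
    df["hba1c"] = lin + rng.normal(0.0, noise_sd, n)
    return df
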