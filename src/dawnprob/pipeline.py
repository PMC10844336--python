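"""Configuration and orchestration of the full DP analysis pipeline.

``run_pipeline`` ties the stages together: ingest traces, enforce the
wear requirement, segment days, detect breakfasts (annotations first),
compute per-day DP probabilities and binary calls, summarize
participants under both models, stratify and compare by HbA1c, compute
TIR control categories, run the gamma sensitivity analysis, fit the
HbA1c regression, and tabulate the likelihood curve.  Every output is a
plain CSV; a JSON manifest echoes the configuration, package version
and a config hash so a run can be reproduced byte for byte.

The likelihood scale convention (``scale_mode``) has *no default*: the
two conventions ("single" per-measurement SD vs "diff" sqrt(2)-scaled
SD for a difference of readings) give materially different
probabilities, and the choice must be visible in every run's config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import time as Time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breakfast import AnnotationError, BreakfastRules
from .cohort import (fit_hba1c_regression, sensitivity_analysis,
                     stratify_by_hba1c, summarize_participant, tir_profile,
                     compare_groups)
from .dawn import (DEVICE_ACCURACY, DayDPResult, ErrorModel,
                   day_results_from_rises, effective_days,
                   effective_days_partition, evaluate_day, likelihood_curve,
                   sigma_from_within_fraction)
from .io import CGMTrace, passes_wear_requirement, read_libreview_csv, \
    read_long_csv, split_days

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "demo_toy_example",
           "TOY_RISES"]

logger = logging.getLogger(__name__)

#: Measured nocturnal rises (mg/dL) of the 7-day worked example.
TOY_RISES = (10.0, 15.0, 25.0, 18.0, 12.0, 16.0, 8.0)


class PipelineError(RuntimeError):
    """A fatal pipeline condition (e.g. no participant passes wear time)."""


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults reproduce the primary analysis
    (gamma = 20 mg/dL, breakfast window 05:00-11:00, min rise 40 mg/dL,
    TIR 70-140 mg/dL at the 90% cutoff, 10-day wear requirement)."""

    input_path: str
    output_dir: str
    scale_mode: str                       # "single" | "diff" -- mandatory
    input_format: str = "long"            # "long" | "libreview"
    device: str = "FreeStyle Libre Pro"
    band_halfwidth: Optional[float] = None     # override the device preset
    within_fraction: Optional[float] = None
    gamma: float = 20.0
    window_start: str = "05:00"
    window_end: str = "11:00"
    min_rise: float = 40.0
    peak_horizon_hours: float = 3.0
    tir_lo: float = 70.0
    tir_hi: float = 140.0
    tir_threshold: float = 90.0
    min_days: int = 10
    min_day_fraction: float = 0.7
    include_partial_days: bool = True
    metadata_path: Optional[str] = None
    annotations_path: Optional[str] = None
    sensitivity_gammas: Sequence[float] = (10.0, 20.0, 30.0)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scale_mode not in ("single", "diff"):
            raise ValueError("scale_mode must be set to 'single' or 'diff' "
                             "(there is no default)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def error_model(self) -> ErrorModel:
        if self.band_halfwidth is not None and self.within_fraction is not None:
            sigma = sigma_from_within_fraction(self.band_halfwidth,
                                               self.within_fraction)
        else:
            sigma = DEVICE_ACCURACY[self.device].sigma
        return ErrorModel(sigma, self.scale_mode, self.gamma)

    def breakfast_rules(self) -> BreakfastRules:
        return BreakfastRules(
            window_start=Time.fromisoformat(self.window_start),
            window_end=Time.fromisoformat(self.window_end),
            min_rise=self.min_rise,
            peak_search_horizon=pd.Timedelta(hours=self.peak_horizon_hours))


def _load_annotations(path) -> dict[tuple[str, str], Time]:
    df = pd.read_csv(path, dtype=str)
    out = {}
    for _, row in df.iterrows():
        out[(row["participant_id"], row["date"])] = \
            Time.fromisoformat(row["breakfast_start"])
    return out


def _day_results_table(per_participant: dict[str, list[DayDPResult]]) -> pd.DataFrame:
    rows = []
    for pid, results in per_participant.items():
        for r in results:
            rows.append({
                "participant_id": pid, "date": r.date.isoformat(),
                "valid": r.valid, "reason": r.reason,
                "breakfast_start": (r.breakfast_start.strftime("%H:%M")
                                    if r.breakfast_start is not None else None),
                "nadir": r.nadir,
                "pre_breakfast_glucose": r.pre_breakfast_glucose,
                "rise": r.rise,
                "probability": (round(r.probability, 6)
                                if r.probability is not None else None),
                "binary": r.binary})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written outputs."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = config.error_model()
    rules = config.breakfast_rules()

    if config.input_format == "libreview":
        traces = [read_libreview_csv(config.input_path)]
    elif config.input_format == "long":
        traces = read_long_csv(config.input_path)
    else:
        raise ValueError(f"unknown input_format {config.input_format!r}")

    annotations = (_load_annotations(config.annotations_path)
                   if config.annotations_path else {})
    metadata = (pd.read_csv(config.metadata_path)
                if config.metadata_path else None)

    kept: list[CGMTrace] = []
    wear_rows = []
    for tr in traces:
        check = passes_wear_requirement(tr, config.min_days,
                                        config.min_day_fraction)
        wear_rows.append({"participant_id": tr.participant_id,
                          "usable_days": check.usable_days,
                          "passed": check.passed})
        if check.passed:
            kept.append(tr)
        else:
            logger.info("excluding %s: %d usable days < %d",
                        tr.participant_id, check.usable_days, config.min_days)
    if not kept:
        raise PipelineError(
            f"no participant meets the wear requirement "
            f"(>= {config.min_days} usable days); nothing to analyse")

    per_participant: dict[str, list[DayDPResult]] = {}
    funnel = {"total_days": 0, "valid_days": 0,
              "no_breakfast": 0, "no_overnight": 0, "annotation_errors": 0}
    for tr in kept:
        results = []
        for day in split_days(tr):
            ann = annotations.get((tr.participant_id, day.date.isoformat()))
            try:
                r = evaluate_day(day, rules, model, annotated_start=ann)
            except AnnotationError as exc:
                logger.warning("%s", exc)
                funnel["annotation_errors"] += 1
                r = DayDPResult(day.date, False, reason="annotation error")
            results.append(r)
            funnel["total_days"] += 1
            if r.valid:
                funnel["valid_days"] += 1
            elif r.reason == "no valid breakfast peak":
                funnel["no_breakfast"] += 1
            elif r.reason == "no overnight samples":
                funnel["no_overnight"] += 1
        per_participant[tr.participant_id] = results
    logger.info("day funnel: %s", funnel)

    day_table = _day_results_table(per_participant)

    summary_rows = []
    for pid, results in per_participant.items():
        if not any(r.valid for r in results):
            logger.info("excluding %s from summaries: zero valid days", pid)
            continue
        for mode in ("probabilistic", "binary"):
            s = summarize_participant(pid, results, mode)
            summary_rows.append(dataclasses.asdict(s))
    summaries = pd.DataFrame(summary_rows)

    valid_results = [r for rs in per_participant.values() for r in rs if r.valid]
    partition = effective_days_partition(valid_results, model.gamma)
    cohort_totals = pd.DataFrame([{
        "valid_days": len(valid_results),
        "effective_dp_days": round(effective_days(valid_results), 1),
        "binary_dp_days": int(sum(r.binary for r in valid_results)),
        "effective_below_gamma": round(partition["below_threshold"], 1),
        "effective_at_or_above_gamma": round(partition["at_or_above"], 1)}])

    tir_rows = []
    for tr in kept:
        prof = tir_profile(tr, config.tir_lo, config.tir_hi, config.tir_threshold)
        if prof is None:
            continue
        tir_rows.append({"participant_id": tr.participant_id,
                         "overnight_tir": round(prof.overnight_tir, 2),
                         "daytime_tir": round(prof.daytime_tir, 2),
                         "category": prof.category.value})
    tir_table = pd.DataFrame(tir_rows)

    sens = sensitivity_analysis(per_participant, model.sigma, model.scale_mode,
                                gammas=tuple(config.sensitivity_gammas),
                                metadata=None)

    comparison_lines = []
    regression_table = None
    if metadata is not None and "hba1c" in metadata.columns:
        meta = metadata.copy()
        meta["stratum"] = [stratify_by_hba1c(h).value for h in meta["hba1c"]]
        prob = summaries[summaries["mode"] == "probabilistic"] \
            .set_index("participant_id")
        meta = meta.set_index("participant_id").join(
            prob[["dp_frequency", "dp_magnitude"]], how="inner")
        groups = {name: grp["dp_frequency"].to_numpy()
                  for name, grp in meta.groupby("stratum")}
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            cmp = compare_groups(groups)
            comparison_lines.append(
                f"{cmp.test}: statistic={cmp.statistic:.4g} p={cmp.pvalue:.4g}")
            if cmp.pairwise is not None:
                comparison_lines.append(cmp.pairwise.to_string(index=False))
        needed = {"age", "gender_male", "waist_cm", "hispanic_latino",
                  "born_in_mexico"}
        if needed.issubset(meta.columns):
            reg = fit_hba1c_regression(meta.reset_index())
            regression_table = reg.table

    curve = likelihood_curve(model, np.arange(0.0, 60.5, 0.5))

    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=name == "regression")
        paths[name] = p

    _write("day_results", day_table)
    _write("participant_summary", summaries)
    _write("cohort_totals", cohort_totals)
    _write("tir_categories", tir_table)
    _write("sensitivity", sens.summaries)
    _write("wear_check", pd.DataFrame(wear_rows))
    _write("funnel", pd.DataFrame([funnel]))
    _write("likelihood_curve", curve)
    if regression_table is not None:
        _write("regression", regression_table)
    if comparison_lines:
        p = out_dir / "group_comparison.txt"
        p.write_text("\n".join(comparison_lines) + "\n")
        paths["group_comparison"] = p

    cfg = dataclasses.asdict(config)
    cfg["sensitivity_gammas"] = list(cfg["sensitivity_gammas"])
    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest = {"version": __version__, "config": cfg,
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "sigma_mgdl": round(model.sigma, 4),
                "effective_sd_mgdl": round(model.effective_sd, 4)}
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = mp
    return paths


def demo_toy_example(scale_mode: str = "single", echo=print) -> dict:
    """The 7-day worked example: rises 10, 15, 25, 18, 12, 16, 8 mg/dL.

    Derives sigma from the FreeStyle Libre Pro accuracy figures (80.2%
    of readings within +/-20 mg/dL) and computes each day's DP
    probability at gamma = 20 mg/dL plus the binary tally and the
    effective number of DP days.  Per-day probabilities are reported to
    2 dp and the effective-day total to 1 dp.
    """
    sigma = sigma_from_within_fraction(20.0, 0.802)
    model = ErrorModel(sigma, scale_mode, gamma=20.0)
    results = day_results_from_rises(TOY_RISES, model)
    probs = [r.probability for r in results]
    n_dp = effective_days(results)
    binary = int(sum(r.binary for r in results))
    echo(f"sigma = {sigma:.1f} mg/dL (scale '{scale_mode}', effective SD "
         f"{model.effective_sd:.1f} mg/dL), gamma = {model.gamma:.0f} mg/dL")
    echo(f"{'rise (mg/dL)':>14} {'Prob(DP)':>9} {'binary':>7}")
    for r in results:
        echo(f"{r.rise:>14.0f} {r.probability:>9.2f} {r.binary:>7d}")
    echo(f"binary DP days      = {binary}")
    echo(f"effective DP days   = {n_dp:.1f}")
    return {"sigma": sigma, "rises": list(TOY_RISES),
            "probabilities": probs, "effective_days": n_dp,
            "binary_days": binary}
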