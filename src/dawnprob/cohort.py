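"""Participant-level DP summaries and cohort statistics.

Covers the per-participant frequency/magnitude summaries under the
probabilistic and binary models, HbA1c risk strata, time-in-range
control categories, nonparametric group comparisons (Kruskal-Wallis
with Dunn post-hoc, Wilcoxon rank-sum), Spearman correlation, the
HbA1c multiple regression, and the gamma-threshold sensitivity
analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .dawn import DayDPResult, ErrorModel, dp_binary, dp_probability
from .io import CGMTrace

__all__ = [
    "ParticipantSummary",
    "HbA1cStratum",
    "TIRProfile",
    "RegressionResult",
    "GroupComparison",
    "SensitivityResult",
    "CollinearityError",
    "RankDeficiencyError",
    "summarize_participant",
    "stratify_by_hba1c",
    "tir_profile",
    "compare_groups",
    "dunn_test",
    "spearman_rho",
    "fit_hba1c_regression",
    "sensitivity_analysis",
    "HBA1C_PREDICTORS",
]


# --------------------------------------------------------------------------
# participant summaries

@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant DP summary under one model.

    Frequencies are percentages of valid days; the probabilistic
    frequency is 100 * N_DP / D (equivalently the mean daily probability
    times 100).  The probabilistic magnitude averages the measured rise
    over *all* valid days; the binary magnitude averages only over
    binary-DP days and is absent when there are none.  CVs are
    SD/mean * 100 of the daily series (probabilities or binary calls for
    the frequency CV; rises for the magnitude CV), undefined when the
    mean is zero or fewer than two valid days exist.
    """

    participant_id: str
    mode: str                       # "probabilistic" | "binary"
    n_valid_days: int
    n_dp: float                     # effective days (prob.) or binary count
    dp_frequency: float             # % of valid days
    dp_magnitude: Optional[float]   # mg/dL
    cv_frequency: Optional[float]   # %
    cv_magnitude: Optional[float]   # %
    dp_magnitude_weighted: Optional[float] = None
    """Probability-weighted mean rise (probabilistic mode only).

    A non-standard companion column: sum(p_i * r_i) / sum(p_i).  It is
    NOT the magnitude definition used in the headline summaries, which
    average over all valid days; it is exported clearly labelled for
    users who want the excursion size conditional on DP having occurred.
    """


def _cv_percent(x: np.ndarray) -> Optional[float]:
    if len(x) < 2:
        return None
    m = float(np.mean(x))
    if m == 0.0:
        return None
    return float(100.0 * np.std(x, ddof=1) / m)


def summarize_participant(participant_id: str,
                          day_results: Iterable[DayDPResult],
                          mode: str) -> ParticipantSummary:
    """Summarize one participant's valid days under one model.

    Raises ``ValueError`` when no valid day exists (the caller excludes
    the participant and logs the reason).
    """
    valid = [r for r in day_results if r.valid]
    if not valid:
        raise ValueError(f"participant {participant_id!r} has zero valid days")
    rises = np.array([r.rise for r in valid], dtype=float)
    d = len(valid)
    if mode == "probabilistic":
        probs = np.array([r.probability for r in valid], dtype=float)
        n_dp = float(probs.sum())
        psum = probs.sum()
        weighted = float((probs * rises).sum() / psum) if psum > 0 else None
        return ParticipantSummary(
            participant_id, mode, d, n_dp,
            dp_frequency=100.0 * n_dp / d,
            dp_magnitude=float(rises.mean()),
            cv_frequency=_cv_percent(probs),
            cv_magnitude=_cv_percent(rises),
            dp_magnitude_weighted=weighted,
        )
    if mode == "binary":
        flags = np.array([r.binary for r in valid], dtype=float)
        count = float(flags.sum())
        mag = float(rises[flags > 0].mean()) if count > 0 else None
        return ParticipantSummary(
            participant_id, mode, d, count,
            dp_frequency=100.0 * count / d,
            dp_magnitude=mag,
            cv_frequency=_cv_percent(flags),
            cv_magnitude=_cv_percent(rises),
        )
    raise ValueError(f"mode must be 'probabilistic' or 'binary', got {mode!r}")


# --------------------------------------------------------------------------
# HbA1c strata

class HbA1cStratum(str, Enum):
    """ADA-style HbA1c risk strata."""

    AT_RISK = "at_risk"      # HbA1c < 5.7 %
    PRE_T2D = "pre_t2d"      # 5.7 <= HbA1c <= 6.4 %
    T2D = "t2d"              # HbA1c > 6.4 %


def stratify_by_hba1c(hba1c: float) -> HbA1cStratum:
    """Assign the HbA1c stratum; both boundaries 5.7 and 6.4 map to pre-T2D."""
    if not np.isfinite(hba1c) or hba1c <= 0:
        raise ValueError(f"HbA1c must be a positive percentage, got {hba1c}")
    if hba1c < 5.7:
        return HbA1cStratum.AT_RISK
    if hba1c <= 6.4:
        return HbA1cStratum.PRE_T2D
    return HbA1cStratum.T2D


# --------------------------------------------------------------------------
# time in range

class TIRCategory(str, Enum):
    OPTIMAL_OVERALL = "optimal_overall"
    SUBOPTIMAL_DAYTIME = "suboptimal_daytime"
    SUBOPTIMAL_OVERNIGHT = "suboptimal_overnight"
    SUBOPTIMAL_OVERALL = "suboptimal_overall"


@dataclass(frozen=True)
class TIRProfile:
    """Overnight/daytime time-in-range and the 2x2 control category."""

    overnight_tir: float   # % of overnight samples in [lo, hi]
    daytime_tir: float     # % of daytime samples in [lo, hi]
    category: TIRCategory


def tir_profile(trace: CGMTrace, lo: float = 70.0, hi: float = 140.0,
                threshold: float = 90.0) -> Optional[TIRProfile]:
    """Per-participant time in the closed range [lo, hi] mg/dL.

    Computed separately overnight (clock time in [00:00, 06:00)) and
    during the day ([06:00, 24:00)); the two windows partition each day.
    The control category crosses the two >= threshold indicators.
    Returns ``None`` when either window holds no samples.
    """
    idx = trace.samples.index
    minutes = idx.hour * 60 + idx.minute
    overnight = minutes < 6 * 60
    vals = trace.samples.to_numpy()
    in_range = (vals >= lo) & (vals <= hi)
    n_over, n_day = int(overnight.sum()), int((~overnight).sum())
    if n_over == 0 or n_day == 0:
        return None
    tir_over = 100.0 * in_range[overnight].mean()
    tir_day = 100.0 * in_range[~overnight].mean()
    if tir_over >= threshold and tir_day >= threshold:
        cat = TIRCategory.OPTIMAL_OVERALL
    elif tir_over >= threshold:
        cat = TIRCategory.SUBOPTIMAL_DAYTIME
    elif tir_day >= threshold:
        cat = TIRCategory.SUBOPTIMAL_OVERNIGHT
    else:
        cat = TIRCategory.SUBOPTIMAL_OVERALL
    return TIRProfile(float(tir_over), float(tir_day), cat)


# --------------------------------------------------------------------------
# nonparametric group comparisons

@dataclass(frozen=True)
class GroupComparison:
    """Omnibus + pairwise comparison report for >= 2 groups."""

    test: str                       # "kruskal-wallis" | "rank-sum"
    statistic: float
    pvalue: float
    pairwise: Optional[pd.DataFrame] = None   # Dunn table for >= 3 groups
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.pvalue < self.alpha


def dunn_test(values_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's post-hoc test on pooled midranks, with tie correction.

    For each pair (i, j) the z statistic is the difference of mean ranks
    over its standard error ``sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))``,
    where ``T = sum(t^3 - t) / (12(N-1))`` corrects for tied ranks.
    Raw two-sided normal p-values are reported alongside Holm-adjusted
    ones; no adjustment is pre-applied to the raw column.
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    pooled = np.concatenate(samples)
    n_total = len(pooled)
    ranks = st.rankdata(pooled)  # midranks for ties
    mean_ranks, sizes, start = {}, {}, 0
    for g, x in zip(names, samples):
        mean_ranks[g] = float(ranks[start:start + len(x)].mean())
        sizes[g] = len(x)
        start += len(x)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        rows.append({"group1": g1, "group2": g2, "z": z,
                     "p_raw": 2.0 * st.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> GroupComparison:
    """Compare >= 2 groups of participant values.

    Two groups: Wilcoxon rank-sum (Mann-Whitney U, exact for small
    samples without ties).  Three or more: Kruskal-Wallis omnibus test
    followed by Dunn pairwise comparisons.
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(samples) < 2 or any(len(x) < 2 for x in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if len(samples) == 2:
        res = st.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupComparison("rank-sum", float(res.statistic),
                               float(res.pvalue), alpha=alpha)
    h, p = st.kruskal(*samples)
    return GroupComparison("kruskal-wallis", float(h), float(p),
                           pairwise=dunn_test(values_by_group), alpha=alpha)


def spearman_rho(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[Optional[float], Optional[float]]:
    """Spearman rank correlation; ``(None, None)`` for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None
    rho, p = st.spearmanr(x, y)
    return float(rho), float(p)


# --------------------------------------------------------------------------
# HbA1c regression

HBA1C_PREDICTORS = ["age", "gender_male", "waist_cm",
                    "hispanic_latino", "born_in_mexico", "dp_frequency"]


class RankDeficiencyError(ValueError):
    """The regression design matrix is rank-deficient."""


class CollinearityError(ValueError):
    """Two predictors are near-perfectly rank-correlated."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of HbA1c on demographic covariates + DP frequency."""

    table: pd.DataFrame          # Estimate, Std. error, t stat, p-value
    n_obs: int
    r_squared: float

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.table.loc[covariate]


def fit_hba1c_regression(table: pd.DataFrame, response: str = "hba1c",
                         predictors: Sequence[str] = tuple(HBA1C_PREDICTORS),
                         collinearity_rho: float = 0.95) -> RegressionResult:
    """Ordinary least squares of HbA1c on the adjusted covariate set.

    Complete-case rows only.  Refuses rank-deficient designs (naming
    the redundant columns) and near-collinear predictor pairs with
    pairwise |Spearman rho| above ``collinearity_rho`` -- the same guard
    that motivates including waist circumference but not BMI, and DP
    frequency but not DP magnitude, among the predictors.
    """
    predictors = list(predictors)
    cols = [response] + predictors
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing regression columns: {missing}")
    data = table[cols].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError(f"need >= {len(predictors) + 2} complete-case rows, "
                         f"got {len(data)}")
    x = data[predictors].to_numpy(dtype=float)
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        redundant = []
        base_rank = np.linalg.matrix_rank(sm.add_constant(
            np.empty((len(data), 0)), has_constant="add"))
        kept: list[int] = []
        for j in range(x.shape[1]):
            trial = sm.add_constant(x[:, kept + [j]], has_constant="add")
            if np.linalg.matrix_rank(trial) > base_rank:
                kept.append(j)
                base_rank += 1
            else:
                redundant.append(predictors[j])
        raise RankDeficiencyError(
            f"design matrix is rank-deficient; redundant column(s): {redundant}")
    for a, b in itertools.combinations(range(len(predictors)), 2):
        if np.ptp(x[:, a]) == 0 or np.ptp(x[:, b]) == 0:
            continue
        rho, _ = st.spearmanr(x[:, a], x[:, b])
        if abs(rho) > collinearity_rho:
            raise CollinearityError(
                f"predictors {predictors[a]!r} and {predictors[b]!r} are "
                f"near-collinear (|Spearman rho| = {abs(rho):.3f} > "
                f"{collinearity_rho}); drop one")
    fit = sm.OLS(data[response].to_numpy(dtype=float), design).fit()
    names = ["intercept"] + predictors
    out = pd.DataFrame({
        "Estimate": fit.params, "Std. error": fit.bse,
        "t stat": fit.tvalues, "p-value": fit.pvalues,
    })
    out.index = names
    return RegressionResult(out, int(fit.nobs), float(fit.rsquared))


# --------------------------------------------------------------------------
# threshold sensitivity

@dataclass(frozen=True)
class SensitivityResult:
    """Per-gamma participant summaries (both models) and regressions."""

    summaries: pd.DataFrame      # columns: gamma, participant_id, mode, ...
    regressions: dict[tuple[float, str], RegressionResult] = field(default_factory=dict)


def _recompute_day(r: DayDPResult, model: ErrorModel) -> DayDPResult:
    if not r.valid:
        return r
    return DayDPResult(
        date=r.date, valid=True, rise=r.rise,
        probability=dp_probability(r.rise, model),
        binary=dp_binary(r.rise, model.gamma),
        breakfast_start=r.breakfast_start, nadir=r.nadir,
        nadir_time=r.nadir_time, pre_breakfast_glucose=r.pre_breakfast_glucose)


def sensitivity_analysis(day_results_by_participant: Mapping[str, Sequence[DayDPResult]],
                         sigma: float, scale_mode: str,
                         gammas: Sequence[float] = (10.0, 20.0, 30.0),
                         metadata: pd.DataFrame | None = None) -> SensitivityResult:
    """Recompute DP summaries (and optionally regressions) per threshold.

    Per-day rises are retained; only the probability/binary mapping is
    recomputed for each gamma, so the row for the primary gamma
    reproduces the primary analysis bit for bit.  ``metadata`` (indexed
    or keyed by ``participant_id`` with the regression covariates and
    ``hba1c``) triggers a regression refit per gamma and mode.
    """
    rows = []
    regressions: dict[tuple[float, str], RegressionResult] = {}
    for gamma in gammas:
        model = ErrorModel(sigma, scale_mode, gamma)
        per_gamma: dict[str, dict[str, ParticipantSummary]] = {}
        for pid, results in day_results_by_participant.items():
            redone = [_recompute_day(r, model) for r in results]
            if not any(r.valid for r in redone):
                continue
            per_gamma[pid] = {
                mode: summarize_participant(pid, redone, mode)
                for mode in ("probabilistic", "binary")}
            for mode, s in per_gamma[pid].items():
                rows.append({"gamma": gamma, "participant_id": pid, "mode": mode,
                             "n_valid_days": s.n_valid_days, "n_dp": s.n_dp,
                             "dp_frequency": s.dp_frequency,
                             "dp_magnitude": s.dp_magnitude,
                             "cv_frequency": s.cv_frequency,
                             "cv_magnitude": s.cv_magnitude})
        if metadata is not None:
            meta = metadata.set_index("participant_id") \
                if "participant_id" in metadata.columns else metadata
            for mode in ("probabilistic", "binary"):
                freq = pd.Series({pid: d[mode].dp_frequency
                                  for pid, d in per_gamma.items()}, name="dp_frequency")
                joined = meta.join(freq, how="inner")
                regressions[(gamma, mode)] = fit_hba1c_regression(joined)
    return SensitivityResult(pd.DataFrame(rows), regressions)
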