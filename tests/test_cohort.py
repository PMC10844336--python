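"""Participant summaries, strata, TIR, group statistics, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h
from scipy.stats import norm

import dawnprob as dp
from dawnprob.cohort import (CollinearityError, RankDeficiencyError,
                             TIRCategory, dunn_test)


@pytest.fixture
def toy_results(toy_model):
    return dp.day_results_from_rises(dp.TOY_RISES, toy_model)


class TestSummarizeParticipant:
    def test_probabilistic_toy_frequency(self, toy_results):
        s = dp.summarize_participant("P", toy_results, "probabilistic")
        assert s.n_valid_days == 7
        assert round(s.n_dp, 1) == 2.6
        assert s.dp_frequency == pytest.approx(100 * s.n_dp / 7)
        # magnitude = mean rise over all valid days
        assert s.dp_magnitude == pytest.approx(np.mean(dp.TOY_RISES))

    def test_binary_toy_frequency(self, toy_results):
        s = dp.summarize_participant("P", toy_results, "binary")
        assert s.n_dp == 1
        assert s.dp_frequency == pytest.approx(100 / 7)
        assert s.dp_magnitude == 25.0  # mean rise over binary-DP days only

    def test_frequency_is_mean_daily_probability(self, toy_results):
        s = dp.summarize_participant("P", toy_results, "probabilistic")
        probs = [r.probability for r in toy_results]
        assert s.dp_frequency == pytest.approx(100 * np.mean(probs))

    def test_zero_probability_days_keep_magnitude(self):
        model = dp.ErrorModel(0.0, "single", gamma=20.0)
        results = dp.day_results_from_rises([5.0, 10.0], model)
        s = dp.summarize_participant("P", results, "probabilistic")
        assert s.dp_frequency == 0.0
        assert s.dp_magnitude == 7.5

    def test_binary_magnitude_absent_without_dp_days(self, toy_model):
        results = dp.day_results_from_rises([5.0, 10.0], toy_model)
        s = dp.summarize_participant("P", results, "binary")
        assert s.dp_magnitude is None

    def test_zero_valid_days_is_an_error(self):
        from datetime import date
        results = [dp.DayDPResult(date(2023, 1, 1), False, reason="x")]
        with pytest.raises(ValueError, match="zero valid days"):
            dp.summarize_participant("P", results, "probabilistic")

    def test_cv_undefined_for_single_day(self, toy_model):
        results = dp.day_results_from_rises([15.0], toy_model)
        s = dp.summarize_participant("P", results, "probabilistic")
        assert s.cv_frequency is None and s.cv_magnitude is None

    @given(rises=st_h.lists(st_h.floats(0, 80), min_size=3, max_size=30))
    def test_binary_magnitude_at_least_probabilistic(self, rises):
        """Averaging only over-threshold rises can never fall below the
        all-days average."""
        model = dp.ErrorModel(dp.LIBRE_SIGMA, "single", gamma=20.0)
        results = dp.day_results_from_rises(rises, model)
        sb = dp.summarize_participant("P", results, "binary")
        sp = dp.summarize_participant("P", results, "probabilistic")
        if sb.dp_magnitude is not None:
            assert sb.dp_magnitude >= sp.dp_magnitude - 1e-9


class TestStratify:
    @pytest.mark.parametrize("hba1c, stratum", [
        (5.4, dp.HbA1cStratum.AT_RISK),
        (5.69, dp.HbA1cStratum.AT_RISK),
        (5.7, dp.HbA1cStratum.PRE_T2D),
        (6.4, dp.HbA1cStratum.PRE_T2D),
        (6.41, dp.HbA1cStratum.T2D),
        (8.1, dp.HbA1cStratum.T2D),
    ])
    def test_boundaries(self, hba1c, stratum):
        assert dp.stratify_by_hba1c(hba1c) is stratum

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dp.stratify_by_hba1c(0.0)


class TestTIR:
    @staticmethod
    def _trace(overnight_vals, daytime_vals):
        over = pd.date_range("2023-05-01 00:00", "2023-05-01 05:45",
                             freq="15min")
        day = pd.date_range("2023-05-01 06:00", "2023-05-01 23:45",
                            freq="15min")
        vals = (list(itertools.islice(itertools.cycle(overnight_vals),
                                      len(over))) +
                list(itertools.islice(itertools.cycle(daytime_vals),
                                      len(day))))
        return dp.CGMTrace("P", pd.Series(
            vals, index=over.append(day), dtype=float))

    def test_all_in_range_is_optimal(self):
        prof = dp.tir_profile(self._trace([100], [100]))
        assert prof.overnight_tir == 100.0 and prof.daytime_tir == 100.0
        assert prof.category is TIRCategory.OPTIMAL_OVERALL

    def test_alternating_daytime_is_suboptimal_daytime(self):
        prof = dp.tir_profile(self._trace([100], [100, 160]))
        assert prof.daytime_tir == 50.0
        assert prof.category is TIRCategory.SUBOPTIMAL_DAYTIME

    def test_boundary_values_count_in_closed_range(self):
        prof = dp.tir_profile(self._trace([140], [70]))
        assert prof.overnight_tir == 100.0 and prof.daytime_tir == 100.0

    def test_suboptimal_overnight_and_overall(self):
        assert dp.tir_profile(self._trace([160], [100])).category is \
            TIRCategory.SUBOPTIMAL_OVERNIGHT
        assert dp.tir_profile(self._trace([160], [60])).category is \
            TIRCategory.SUBOPTIMAL_OVERALL

    def test_windows_partition_the_day(self):
        trace = self._trace([100], [100])
        idx = trace.samples.index
        overnight = (idx.hour < 6).sum()
        daytime = (idx.hour >= 6).sum()
        assert overnight + daytime == len(trace)

    def test_empty_window_gives_absent_profile(self):
        idx = pd.date_range("2023-05-01 08:00", periods=10, freq="15min")
        trace = dp.CGMTrace("P", pd.Series(100.0, index=idx))
        assert dp.tir_profile(trace) is None


class TestGroupComparisons:
    def test_kruskal_wallis_hand_computed(self):
        cmp = dp.compare_groups({"a": [1, 2, 3], "b": [4, 5, 6],
                                 "c": [7, 8, 9]})
        assert cmp.test == "kruskal-wallis"
        assert cmp.statistic == pytest.approx(7.2)
        assert cmp.pairwise is not None and len(cmp.pairwise) == 3

    def test_identical_groups_are_null(self):
        cmp = dp.compare_groups({"a": [1, 2, 3], "b": [1, 2, 3],
                                 "c": [1, 2, 3]})
        assert cmp.statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.pvalue > 0.99

    def test_two_group_exact_rank_sum(self):
        cmp = dp.compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert cmp.test == "rank-sum"
        assert cmp.statistic == 0.0  # U at its minimum
        assert cmp.pvalue == pytest.approx(0.1)  # 2/20 exact enumeration

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            dp.compare_groups({"a": [1.0], "b": [2, 3]})

    def test_dunn_z_matches_direct_formula(self):
        groups = {"a": [1.0, 4.0, 7.0], "b": [2.0, 5.0, 8.0],
                  "c": [3.0, 6.0, 9.0]}
        table = dunn_test(groups)
        # no ties: z_ab = (Rbar_a - Rbar_b) / sqrt(N(N+1)/12 * (1/3 + 1/3))
        rbar = {"a": (1 + 4 + 7) / 3, "b": (2 + 5 + 8) / 3, "c": (3 + 6 + 9) / 3}
        se = np.sqrt(9 * 10 / 12 * (2 / 3))
        row = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
        assert row.z == pytest.approx((rbar["a"] - rbar["b"]) / se)
        assert row.p_raw == pytest.approx(2 * norm.sf(abs(row.z)))

    def test_dunn_and_kruskal_match_exact_permutation(self):
        """Small-instance oracle: enumerate all group assignments."""
        values = np.array([3.1, 0.2, 5.9, 8.4, 9.7, 12.0, 1.5, 7.3, 10.8])
        groups = {"a": values[:3], "b": values[3:6], "c": values[6:]}
        cmp = dp.compare_groups(groups)
        dunn = dunn_test(groups)

        order = np.argsort(values)
        ranks_obs = np.empty(9)
        ranks_obs[order] = np.arange(1, 10)
        h_obs = 12 / (9 * 10) * 3 * sum(
            ranks_obs[i:i + 3].mean() ** 2 for i in (0, 3, 6)) - 3 * 10
        assert cmp.statistic == pytest.approx(h_obs)

        idx = list(range(9))
        h_null, dz_null = [], []
        for g1 in itertools.combinations(idx, 3):
            rest = [i for i in idx if i not in g1]
            for g2 in itertools.combinations(rest, 3):
                g3 = [i for i in rest if i not in g2]
                perm_ranks = ranks_obs[list(g1) + list(g2) + list(g3)]
                rb = [perm_ranks[0:3].mean(), perm_ranks[3:6].mean(),
                      perm_ranks[6:9].mean()]
                h_null.append(12 / (9 * 10) * 3 * sum(r ** 2 for r in rb)
                              - 3 * 10)
                dz_null.append(abs(rb[0] - rb[1]))
        h_null = np.array(h_null)
        p_exact = (h_null >= h_obs - 1e-9).mean()
        assert abs(p_exact - cmp.pvalue) < 0.05  # exact vs chi-square

        row = dunn[(dunn.group1 == "a") & (dunn.group2 == "b")].iloc[0]
        se = np.sqrt(9 * 10 / 12 * (2 / 3))
        obs_diff = abs(row.z) * se
        p_pair_exact = (np.array(dz_null) >= obs_diff - 1e-9).mean()
        assert abs(p_pair_exact - row.p_raw) < 0.1  # exact vs normal


class TestSpearman:
    def test_monotone_agreement(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rho, _ = dp.spearman_rho(x, [v ** 3 for v in x])
        assert rho == pytest.approx(1.0)
        rho, _ = dp.spearman_rho(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rho, _ = dp.spearman_rho([1, 2, 3, 4], [1, 2, 4, 3])
        assert rho == pytest.approx(0.8)  # 1 - 6*2 / (4*15)

    def test_constant_input_absent(self):
        assert dp.spearman_rho([1, 1, 1], [1, 2, 3]) == (None, None)


TRUE_BETA = {"intercept": 3.6, "age": -0.01, "gender_male": 0.47,
             "waist_cm": 0.023, "hispanic_latino": -0.65,
             "born_in_mexico": 0.34, "dp_frequency": 0.024}


class TestRegression:
    def test_zero_noise_exact_recovery(self):
        table = dp.synthetic_regression_table(80, TRUE_BETA, noise_sd=0.0,
                                              seed=2)
        res = dp.fit_hba1c_regression(table)
        for name, beta in TRUE_BETA.items():
            assert res.table.loc[name, "Estimate"] == \
                pytest.approx(beta, abs=1e-8)

    def test_noisy_recovery_within_three_se(self):
        table = dp.synthetic_regression_table(500, TRUE_BETA, noise_sd=0.3,
                                              seed=3)
        res = dp.fit_hba1c_regression(table)
        for name, beta in TRUE_BETA.items():
            est = res.table.loc[name, "Estimate"]
            se = res.table.loc[name, "Std. error"]
            assert abs(est - beta) < 3 * se

    def test_t_stat_is_estimate_over_se(self):
        table = dp.synthetic_regression_table(120, TRUE_BETA, noise_sd=0.3,
                                              seed=4)
        res = dp.fit_hba1c_regression(table)
        np.testing.assert_allclose(
            res.table["t stat"],
            res.table["Estimate"] / res.table["Std. error"], rtol=1e-10)

    def test_duplicated_predictor_is_rank_deficient(self):
        table = dp.synthetic_regression_table(100, TRUE_BETA, noise_sd=0.3,
                                              seed=5)
        table["dp_copy"] = table["dp_frequency"]
        with pytest.raises(RankDeficiencyError, match="dp_copy"):
            dp.fit_hba1c_regression(
                table, predictors=dp.cohort.HBA1C_PREDICTORS + ["dp_copy"])

    def test_near_collinear_predictors_refused(self):
        table = dp.synthetic_regression_table(100, TRUE_BETA, noise_sd=0.3,
                                              seed=6)
        rng = np.random.default_rng(0)
        table["bmi"] = table["waist_cm"] * 0.3 + rng.normal(0, 1e-4, 100)
        with pytest.raises(CollinearityError, match="bmi"):
            dp.fit_hba1c_regression(
                table, predictors=dp.cohort.HBA1C_PREDICTORS + ["bmi"])


class TestSensitivity:
    @pytest.fixture
    def per_participant(self, toy_model):
        rng = np.random.default_rng(9)
        return {
            f"P{i}": dp.day_results_from_rises(rng.uniform(0, 45, 14),
                                               toy_model)
            for i in range(6)}

    def test_frequency_nonincreasing_in_gamma(self, per_participant):
        res = dp.sensitivity_analysis(per_participant, dp.LIBRE_SIGMA,
                                      "single")
        for (pid, mode), grp in res.summaries.groupby(
                ["participant_id", "mode"]):
            freq = grp.sort_values("gamma")["dp_frequency"].to_numpy()
            assert np.all(np.diff(freq) <= 1e-9)

    def test_primary_gamma_reproduced_bit_for_bit(self, per_participant):
        res = dp.sensitivity_analysis(per_participant, dp.LIBRE_SIGMA,
                                      "single", gammas=(20.0,))
        for pid, results in per_participant.items():
            s = dp.summarize_participant(pid, results, "probabilistic")
            row = res.summaries.query(
                "participant_id == @pid and mode == 'probabilistic'").iloc[0]
            assert row["dp_frequency"] == s.dp_frequency
            assert row["n_dp"] == s.n_dp

    def test_zero_sigma_equals_binary_counts(self, per_participant):
        res = dp.sensitivity_analysis(per_participant, 0.0, "single",
                                      gammas=(10.0,))
        probs = res.summaries.query("mode == 'probabilistic'") \
            .set_index("participant_id")["n_dp"]
        for pid, results in per_participant.items():
            count = sum(r.rise >= 10.0 for r in results)
            assert probs[pid] == pytest.approx(count)
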