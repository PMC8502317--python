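"""Statistical surface vs independent textbook-formula oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from engage.analysis import (
    adjust_bmi_percentile,
    chi_square_independence,
    engagement_report,
    pearson_correlation,
    repeated_measures_by_group,
    two_group_t,
)
from engage.errors import ValidationError

from .reference import chi2_oracle, pearson_oracle, pooled_t_oracle, split_plot_oracle

TOL = 1e-10


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(1.0, 9.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0]
        r, p = pearson_correlation(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert abs(r - r0) < TOL and abs(p - p0) < TOL

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.normal(size=(2, 25))
            r, p = pearson_correlation(x, y)
            r0, p0 = pearson_oracle(x, y)
            assert abs(r - r0) < TOL and abs(p - p0) < TOL


class TestTwoGroupT:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = two_group_t(g, g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pooled_formula_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, size=8)
            y = rng.normal(0.5, 2, size=13)
            res = two_group_t(x, y, pooled=True)
            t0, df0, p0 = pooled_t_oracle(x, y)
            assert abs(res.statistic - t0) < TOL
            assert res.df == df0
            assert abs(res.p_value - p0) < TOL

    def test_welch_differs_from_pooled_when_variances_differ(self):
        x = [0.0, 0.1, 0.2, 0.05, 0.15]
        y = [1.0, 3.0, -2.0, 4.0, 0.5, 2.5]
        pooled = two_group_t(x, y, pooled=True)
        welch = two_group_t(x, y, pooled=False)
        assert pooled.df == 9
        assert welch.df != pooled.df

    def test_degenerate_zero_variance_groups(self):
        res = two_group_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        assert math.isinf(res.statistic) and res.p_value == 0.0
        assert res.warnings
        same = two_group_t([2.0, 2.0], [2.0, 2.0])
        assert same.statistic == 0.0 and same.p_value == 1.0

    def test_seeded_type_one_error_near_nominal(self):
        """Under the null, the pooled t at alpha=0.05 rejects ~5% of the time."""
        rng = np.random.default_rng(2026)
        reps, n = 2000, 15
        from scipy.stats import ttest_ind

        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        p = ttest_ind(x, y, axis=1, equal_var=True).pvalue
        # spot-check the vectorized run against our own surface
        res = two_group_t(x[0], y[0])
        assert abs(res.p_value - p[0]) < TOL
        rate = float((p < 0.05).mean())
        mc_sd = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * mc_sd

    def test_permuted_labels_keep_type_one_error(self):
        """Permuting group labels on skewed data keeps the rejection rate near alpha."""
        rng = np.random.default_rng(99)
        pool = rng.exponential(size=40)
        hits = 0
        reps = 2000
        for _ in range(reps):
            perm = rng.permutation(pool)
            if two_group_t(perm[:20], perm[20:]).p_value < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps) + 0.01


class TestChiSquare:
    def test_identical_row_proportions_give_zero(self):
        res = chi_square_independence([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_direct_sum_oracle(self):
        table = [[10, 20], [20, 10]]
        res = chi_square_independence(table)
        chi0, df0, p0 = chi2_oracle(table)
        assert abs(res.statistic - chi0) < TOL
        assert res.df == df0
        assert abs(res.p_value - p0) < TOL

    def test_df_for_2x4(self):
        res = chi_square_independence([[5, 6, 7, 8], [8, 7, 6, 5]])
        assert res.df == 3

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="zero margin"):
            chi_square_independence([[0, 0], [5, 5]])

    def test_small_expected_counts_warn(self):
        res = chi_square_independence([[1, 9], [2, 8]])
        assert res.warnings and "expected count < 5" in res.warnings[0]


class TestAdjustment:
    def _frame(self, values, schools, classrooms):
        return pd.DataFrame(
            {
                "bmi_percentile_t0": values,
                "school": schools,
                "classroom": classrooms,
            }
        )

    def test_single_school_single_classroom_is_identity(self):
        df = self._frame([40.0, 50.0, 60.0], ["s1"] * 3, ["c1"] * 3)
        adj = adjust_bmi_percentile(df)
        assert np.allclose(adj, df["bmi_percentile_t0"])

    def test_constant_school_offset_removed(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(30, 70, size=40)
        values = np.concatenate([base[:20], base[20:] + 15.0])
        schools = ["s1"] * 20 + ["s2"] * 20
        classrooms = ["c1"] * 10 + ["c2"] * 10 + ["c3"] * 10 + ["c4"] * 10
        df = self._frame(values, schools, classrooms)
        adj = adjust_bmi_percentile(df)
        m1, m2 = adj[:20].mean(), adj[20:].mean()
        assert m1 == pytest.approx(m2)
        assert adj.mean() == pytest.approx(values.mean())  # grand mean preserved

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        df = self._frame(
            rng.uniform(20, 80, size=30),
            ["s1"] * 15 + ["s2"] * 15,
            (["c1"] * 8 + ["c2"] * 7) + (["c3"] * 8 + ["c4"] * 7),
        )
        once = adjust_bmi_percentile(df)
        df2 = df.copy()
        df2["bmi_percentile_t0"] = once
        twice = adjust_bmi_percentile(df2)
        assert np.allclose(once, twice, atol=1e-8)

    def test_zero_covariance_with_school_indicators(self):
        rng = np.random.default_rng(21)
        df = self._frame(
            rng.uniform(10, 90, size=60),
            ["s1"] * 20 + ["s2"] * 20 + ["s3"] * 20,
            [f"c{i // 10}" for i in range(60)],
        )
        adj = adjust_bmi_percentile(df)
        for school in ("s1", "s2", "s3"):
            indicator = (df["school"] == school).astype(float)
            cov = np.cov(adj, indicator)[0, 1]
            assert abs(cov) < 1e-8

    def test_missing_rows_stay_missing(self):
        df = self._frame([40.0, np.nan, 45.0, 60.0, 55.0], ["s1", "s1", "s1", "s2", "s2"],
                         ["c1", "c1", "c1", "c2", "c2"])
        adj = adjust_bmi_percentile(df)
        assert math.isnan(adj.iloc[1]) and adj.notna().sum() == 4

    def test_singleton_classroom_warns(self):
        df = self._frame([40.0, 50.0, 60.0, 70.0], ["s1", "s1", "s1", "s1"],
                         ["c1", "c1", "c1", "c2"])
        with pytest.warns(UserWarning, match="single observation"):
            adjust_bmi_percentile(df)


class TestRepeatedMeasures:
    def _data(self, y0, y1, groups):
        return pd.DataFrame(
            {
                "parent_id": [f"p{i}" for i in range(len(y0))],
                "pd": groups,
                "bmi_percentile_t0": y0,
                "bmi_percentile_t2": y1,
            }
        )

    def test_null_data_has_no_effects(self):
        rng = np.random.default_rng(4)
        n = 30
        y0 = rng.normal(50, 5, size=2 * n)
        y1 = y0 + rng.normal(0, 1, size=2 * n)
        res = repeated_measures_by_group(self._data(y0, y1, [0] * n + [1] * n))
        assert res.group[2] > 0.01 and res.interaction[2] > 0.01

    def test_recovers_constant_group_offset(self):
        rng = np.random.default_rng(42)
        n = 25
        base0 = rng.normal(50, 4, size=n)
        base1 = base0 + rng.normal(0, 1, size=n)
        y0 = np.concatenate([base0, base0 + 8.0])
        y1 = np.concatenate([base1, base1 + 8.0])
        res = repeated_measures_by_group(self._data(y0, y1, [0] * n + [1] * n))
        mm = res.marginal_means
        gap0 = mm.loc[(1, "bmi_percentile_t0"), "mean"] - mm.loc[(0, "bmi_percentile_t0"), "mean"]
        assert gap0 == pytest.approx(8.0)
        assert res.group[2] < 1e-6          # strong between-group effect
        assert res.interaction[2] > 0.99    # parallel profiles

    def test_common_time_shift_hits_time_not_interaction(self):
        rng = np.random.default_rng(7)
        n = 25
        y0 = rng.normal(50, 4, size=2 * n)
        y1 = y0 + 5.0 + rng.normal(0, 0.5, size=2 * n)
        res = repeated_measures_by_group(self._data(y0, y1, [0] * n + [1] * n))
        assert res.time[2] < 1e-6
        assert res.interaction[2] > 0.05

    def test_matches_split_plot_sums_of_squares_oracle(self):
        rng = np.random.default_rng(13)
        n = 12
        y = rng.normal(50, 6, size=(2 * n, 2))
        y[n:] += 3.0
        y[:, 1] += 1.5
        res = repeated_measures_by_group(
            self._data(y[:, 0], y[:, 1], [0] * n + [1] * n)
        )
        (g, _, gp), (t, _, tp), (i, _, ip) = split_plot_oracle(y, n)
        assert res.group[0] == pytest.approx(g, abs=1e-8)
        assert res.time[0] == pytest.approx(t, abs=1e-8)
        assert res.interaction[0] == pytest.approx(i, abs=1e-8)
        assert res.group[2] == pytest.approx(gp, abs=1e-10)
        assert res.time[2] == pytest.approx(tp, abs=1e-10)
        assert res.interaction[2] == pytest.approx(ip, abs=1e-10)

    def test_small_group_rejected(self):
        df = self._data([50.0, 51.0, 52.0], [50.0, 51.0, 52.0], [0, 1, 1])
        with pytest.raises(ValidationError, match="at least 2 subjects"):
            repeated_measures_by_group(df)


class TestEngagementReport:
    def test_report_blocks_present_on_synthetic_cohort(self, small_cohort, catalog):
        from engage.scoring import score_cohort

        records, outcomes, _ = small_cohort
        res = score_cohort(records, outcomes, catalog)
        report = engagement_report(res.table)
        assert report["n_parents"] == len(res.table)
        assert "std_pei" in report["index_comparisons"]
        assert set(report["activity_by_pd"]) <= set(catalog.activities)
        assert "surveys" in report["activity_by_pd"]
        corr = report["bmi_correlations"]
        assert set(corr) == {"std_ppp", "std_pei"}
        for block in corr.values():
            assert -1 <= block["r"] <= 1 and 0 <= block["p"] <= 1
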