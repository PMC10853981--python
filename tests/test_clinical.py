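import numpy as np
import pandas as pd
import pytest

import dynstates as ds
from dynstates.clinical import results_table, validate_cohort

from _oracles import mannwhitney_exact_p, spearman_exact_p, wilcoxon_exact_p


class TestMedianIQR:
    def test_week3_summary_medians_from_cohort(self, cohort_table):
        assert ds.median_iqr(cohort_table["arat_w3"])[0] == 32
        assert ds.median_iqr(cohort_table["fmue_w3"])[0] == 50
        assert ds.median_iqr(cohort_table["nihss_day0"])[0] == 4
        assert ds.median_iqr(cohort_table["days_post_stroke"])[0] == 22
        assert ds.median_iqr(cohort_table["age"])[0] == 60

    def test_quartiles_ordered(self):
        med, q1, q3 = ds.median_iqr([1, 2, 3])
        assert q1 <= med <= q3 and med == 2

    def test_missing_excluded(self):
        med, q1, q3 = ds.median_iqr([1.0, np.nan, 3.0, np.nan, 5.0])
        assert med == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            ds.median_iqr([np.nan])

    def test_tukey_hinges_differ_from_linear_when_expected(self):
        x = [1, 2, 3, 4, 5, 6]
        assert ds.median_iqr(x, "tukey")[1] == 2
        assert ds.median_iqr(x, "linear")[1] == pytest.approx(2.25)


class TestMCIDAndSubgroups:
    def test_fmue_mcid_count_from_cohort(self, cohort_table):
        arat_n, fmue_n, n_pairs = ds.mcid_counts(cohort_table)
        assert (fmue_n, n_pairs) == (14, 29)
        assert 0 <= arat_n <= n_pairs

    def test_no_improvement_counts_in_neither(self):
        row = pd.DataFrame({
            "affected_hand": ["R"], "arat_w3": [10], "fmue_w3": [10],
            "arat_w12": [10.0], "fmue_w12": [10.0],
        })
        assert ds.mcid_counts(row)[:2] == (0, 0)

    def test_fmue_threshold_is_strict(self):
        row = pd.DataFrame({
            "affected_hand": ["R"], "arat_w3": [0], "fmue_w3": [10],
            "arat_w12": [0.0], "fmue_w12": [22.0],  # delta = 12 < 12.4
        })
        assert ds.mcid_counts(row)[1] == 0
        row["fmue_w12"] = 23.0  # delta = 13 > 12.4
        assert ds.mcid_counts(row)[1] == 1

    def test_subgroup_sizes_from_cohort(self, cohort_table):
        nr, rec = ds.recovery_subgroups(cohort_table)
        assert (len(nr), len(rec)) == (25, 12)

    def test_subgroup_boundaries(self):
        rows = pd.DataFrame({
            "arat_w3": [56, 55], "fmue_w3": [10, 64],
        })
        nr, rec = ds.recovery_subgroups(rows)
        assert rows.index[0] in rec.index  # ARAT 56 > 55 -> recovered
        assert rows.index[1] in nr.index  # 55/64 -> not recovered

    def test_cohort_ranges_valid(self, cohort_table):
        validate_cohort(cohort_table)
        bad = cohort_table.copy()
        bad.loc[0, "arat_w3"] = 58
        with pytest.raises(ValueError, match="arat_w3"):
            validate_cohort(bad)


class TestMannWhitney:
    def test_hand_example_min_convention(self):
        res = ds.mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.direction == "x < y"

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, size=int(rng.integers(2, 6))).astype(float)
            y = rng.integers(0, 5, size=int(rng.integers(2, 7))).astype(float)
            res = ds.mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(mannwhitney_exact_p(x, y), abs=1e-10)

    def test_identical_groups_null_result(self):
        res = ds.mann_whitney_u([1.0, 2.0, 3.0] * 6, [1.0, 2.0, 3.0] * 6)
        assert res.p_value > 0.9
        assert abs(res.effect_size) < 0.05

    def test_large_sample_z_and_effect_size(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 40)
        y = rng.normal(0.0, 1.0, 41)
        res = ds.mann_whitney_u(x, y)
        assert res.p_value < 0.001
        assert res.effect_size == pytest.approx(res.z_value / np.sqrt(81))
        assert res.direction == "x > y"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ds.mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_zero_differences_signalled(self):
        res = ds.wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert np.isnan(res.p_value)
        assert "no nonzero pairs" in res.note

    def test_all_positive_maximal_w(self):
        res = ds.wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == 15.0
        assert res.direction == "positive"

    def test_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.integers(-4, 5, size=8).astype(float)
            if not np.any(d):
                continue
            res = ds.wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(wilcoxon_exact_p(d), abs=1e-10)

    def test_paired_input_equals_difference_input(self):
        x = np.array([5.0, 7.0, 2.0, 9.0])
        y = np.array([3.0, 8.0, 2.5, 4.0])
        assert ds.wilcoxon_signed_rank(x, y).p_value == \
            ds.wilcoxon_signed_rank(x - y).p_value

    def test_pratt_zero_handling_changes_ranks(self):
        d = [0.0, 1.0, -2.0, 3.0]
        drop = ds.wilcoxon_signed_rank(d, zero_method="drop")
        pratt = ds.wilcoxon_signed_rank(d, zero_method="pratt")
        assert drop.statistic != pratt.statistic


class TestMixedAnova:
    def test_identical_within_measures_zero_region_ss(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=12)
        groups = np.repeat(["a", "b"], 6)
        out = ds.mixed_anova_2x2(groups, y, y.copy())
        region = out[out["effect"] == "region"].iloc[0]
        inter = out[out["effect"] == "interaction"].iloc[0]
        assert region["SS"] == pytest.approx(0.0, abs=1e-12)
        assert inter["SS"] == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_group_shift_saturates(self):
        y1 = np.array([1.0, 1.0, 1.0, 3.0, 3.0, 3.0])
        y2 = y1.copy()
        groups = np.repeat(["a", "b"], 3)
        out = ds.mixed_anova_2x2(groups, y1, y2)
        g = out[out["effect"] == "group"].iloc[0]
        assert np.isinf(g["F"])
        assert g["eta_p2"] == pytest.approx(1.0)

    def test_matches_reference_implementation_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        n = 12
        groups = np.array(["ctl"] * n + ["str"] * n)
        y1 = rng.normal(size=2 * n) + (groups == "str") * 0.8
        y2 = rng.normal(size=2 * n) + 0.3
        ours = ds.mixed_anova_2x2(groups, y1, y2).set_index("effect")
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(2 * n), 2),
            "group": np.repeat(groups, 2),
            "region": ["iSMN", "cSMN"] * (2 * n),
            "y": np.column_stack([y1, y2]).ravel(),
        })
        ref = pg.mixed_anova(long, dv="y", within="region", subject="subject",
                             between="group").set_index("Source")
        for ours_key, ref_key in (("group", "group"), ("region", "region"),
                                  ("interaction", "Interaction")):
            assert ours.loc[ours_key, "F"] == pytest.approx(ref.loc[ref_key, "F"], abs=1e-8)
            assert ours.loc[ours_key, "p_value"] == pytest.approx(
                ref.loc[ref_key, "p_unc"], abs=1e-8)
            assert ours.loc[ours_key, "eta_p2"] == pytest.approx(
                ref.loc[ref_key, "np2"], abs=1e-8)

    def test_matches_design_matrix_glm_unbalanced(self):
        # independent oracle: Type III tests from an explicit sum-coded
        # design matrix.  Group effect = OLS slope test on subject means;
        # region effect = OLS intercept test on difference scores; the
        # interaction = OLS slope test on difference scores.
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        n1, n2 = 9, 14
        groups = np.array(["ctl"] * n1 + ["str"] * n2)
        y1 = rng.normal(size=n1 + n2) + (groups == "str") * 0.8
        y2 = rng.normal(size=n1 + n2) + 0.3
        ours = ds.mixed_anova_2x2(groups, y1, y2).set_index("effect")
        g = np.where(groups == "ctl", 1.0, -1.0)
        design = np.column_stack([np.ones(n1 + n2), g])
        fit_s = sm.OLS((y1 + y2) / 2, design).fit()
        fit_d = sm.OLS(y1 - y2, design).fit()
        expected = {
            "group": fit_s.tvalues[1] ** 2,
            "region": fit_d.tvalues[0] ** 2,
            "interaction": fit_d.tvalues[1] ** 2,
        }
        pvals = {
            "group": fit_s.pvalues[1],
            "region": fit_d.pvalues[0],
            "interaction": fit_d.pvalues[1],
        }
        for effect in ("group", "region", "interaction"):
            assert ours.loc[effect, "F"] == pytest.approx(expected[effect], abs=1e-8)
            assert ours.loc[effect, "p_value"] == pytest.approx(pvals[effect], abs=1e-8)

    def test_interaction_reduces_to_t_squared_on_differences(self):
        rng = np.random.default_rng(5)
        n1, n2 = 8, 11
        groups = np.array(["a"] * n1 + ["b"] * n2)
        y1 = rng.normal(size=n1 + n2)
        y2 = rng.normal(size=n1 + n2)
        out = ds.mixed_anova_2x2(groups, y1, y2).set_index("effect")
        d = y1 - y2
        from scipy import stats as sstats

        t, p = sstats.ttest_ind(d[groups == "a"], d[groups == "b"])
        assert out.loc["interaction", "F"] == pytest.approx(t**2, abs=1e-8)
        assert out.loc["interaction", "p_value"] == pytest.approx(p, abs=1e-8)

    def test_missing_measures_excluded_listwise(self):
        groups = np.repeat(["a", "b"], 5)
        y1 = np.arange(10.0)
        y2 = np.arange(10.0) + 1
        y2[3] = np.nan
        with pytest.warns(UserWarning, match="excluded 1"):
            out = ds.mixed_anova_2x2(groups, y1, y2)
        assert out.iloc[0]["n"] == (4, 5)


class TestSpearman:
    def test_monotone_pair_perfect_rho(self):
        res = ds.spearman([1, 2, 3, 5, 10], [2, 4, 9, 10, 30])
        assert res.statistic == pytest.approx(1.0)

    def test_matches_permutation_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            res = ds.spearman(x, y)
            assert res.method == "exact permutation enumeration"
            assert res.p_value == pytest.approx(spearman_exact_p(x, y), abs=1e-10)

    def test_partial_controls_shared_rank_structure(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=40)
        x = z + 0.1 * rng.normal(size=40)
        y = z + 0.1 * rng.normal(size=40)
        plain = ds.spearman(x, y)
        partial = ds.spearman(x, y, control=z)
        assert plain.statistic > 0.9
        assert abs(partial.statistic) < plain.statistic
        assert partial.df == 37

    def test_partial_undefined_when_control_equals_y(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=10)
        res = ds.spearman(rng.normal(size=10), z, control=z)
        assert np.isnan(res.statistic)
        assert "undefined" in res.note

    def test_type_one_error_calibrated_under_null(self):
        # independence: rejection rate at alpha=0.05 within +/- 2 points
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            if ds.spearman(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestBonferroni:
    def test_corrected_alpha_for_two_tests(self):
        out = ds.bonferroni([0.03, 0.01], m=2)
        assert out["alpha_corrected"].iloc[0] == 0.025
        assert list(out["reject"]) == [False, True]

    def test_single_test_unchanged(self):
        out = ds.bonferroni([0.04], m=1)
        assert out["alpha_corrected"].iloc[0] == 0.05
        assert bool(out["reject"].iloc[0])


def test_results_table_round_trip(tmp_path):
    res = [ds.mann_whitney_u([1.0, 2.0, 5.0], [3.0, 4.0, 6.0]),
           ds.wilcoxon_signed_rank([1.0, -2.0, 3.0])]
    df = results_table(res)
    assert list(df["name"]) == ["Mann-Whitney U", "Wilcoxon signed-rank"]
    p = tmp_path / "tests.csv"
    df.to_csv(p, index=False)
    assert pd.read_csv(p).shape[0] == 2
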