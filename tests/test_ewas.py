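import numpy as np
import pandas as pd
import pytest
from scipy import stats

import shiftmethyl as sm
from shiftmethyl.errors import AlignmentError, ContractError, DesignError, FitError
from shiftmethyl.ewas import (
    BASE_COLUMNS,
    HYPER_AT_WORK,
    HYPO_AT_WORK,
    NO_DIRECTION,
    DesignMatrix,
    percent_integer,
    percent_one_decimal,
)


def _normal_equations_oracle(X, y):
    """Independent OLS oracle: beta = (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestBuildDesign:
    def test_tiny_sheet_encoding(self, tiny_sheet):
        design = sm.build_design(tiny_sheet)
        expected = np.array([
            [1, 0, 0, 0],
            [1, 0, 1, 0],
            [0, 1, 0, 0],
            [0, 1, 0, 1],
        ], dtype=float)
        np.testing.assert_array_equal(design.values, expected)
        assert design.columns == BASE_COLUMNS
        assert design.rank == 4

    def test_intercepts_sum_to_one(self, cohort_sheet):
        design = sm.build_design(cohort_sheet, ["age", "sex"])
        total = design.values[:, 0] + design.values[:, 1]
        np.testing.assert_array_equal(total, np.ones(design.n_samples))

    def test_constant_covariate_pruned(self, tiny_sheet, caplog):
        sheet = tiny_sheet.assign(sex="M")
        with caplog.at_level("WARNING", logger="shiftmethyl.ewas"):
            design = sm.build_design(sheet, ["sex"])
        assert design.columns == BASE_COLUMNS
        assert design.dropped == ("sex[M]",)
        assert any("pruned" in record.message for record in caplog.records)

    def test_collinear_covariate_pruned(self, tiny_sheet, caplog):
        sheet = tiny_sheet.copy()
        sheet["mirror"] = (sheet["group"] == "control").astype(float)
        with caplog.at_level("WARNING", logger="shiftmethyl.ewas"):
            design = sm.build_design(sheet, ["mirror"])
        assert "mirror" not in design.columns

    def test_rank_matches_independent_decomposition(self, cohort_sheet):
        design = sm.build_design(
            cohort_sheet, ["age", "sex", "plate", "alcohol", "smoking"])
        svd_rank = int(np.sum(np.linalg.svd(design.values, compute_uv=False) > 1e-8))
        assert design.rank == svd_rank == len(design.columns)
        assert design.rank == 4 + (len(design.columns) - 4)

    def test_empty_cell_raises(self, tiny_sheet):
        broken = tiny_sheet[tiny_sheet["sample_id"] != "C1_vacation"]
        with pytest.raises(DesignError, match="group='control', period='vacation'"):
            sm.build_design(broken)

    def test_missing_covariate_column(self, tiny_sheet):
        with pytest.raises(DesignError, match="bmi"):
            sm.build_design(tiny_sheet, ["bmi"])


class TestFitProbe:
    def test_constant_y(self):
        rows = []
        for subject, group in (("S1", "swd"), ("S2", "swd"),
                               ("C1", "control"), ("C2", "control")):
            for period in ("work", "vacation"):
                rows.append({"subject": subject, "group": group, "period": period})
        design = sm.build_design(pd.DataFrame(rows))
        fit = sm.fit_probe(np.full(8, 2.5), design)
        assert fit.coef("intercept_swd") == pytest.approx(2.5)
        assert fit.coef("intercept_ctrl") == pytest.approx(2.5)
        assert fit.coef("vacation_swd") == pytest.approx(0.0, abs=1e-12)
        assert fit.coef("vacation_ctrl") == pytest.approx(0.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_noiseless_planted_effect(self, cohort_sheet):
        design = sm.build_design(cohort_sheet)
        swd_vac = design.values[:, 2]
        y = 1.0 + 1.0 * swd_vac
        fit = sm.fit_probe(y, design)
        assert fit.coef("vacation_swd") == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, cohort_sheet, seed):
        rng = np.random.default_rng(seed)
        design = sm.build_design(
            cohort_sheet, ["age", "sex", "plate", "alcohol", "smoking"])
        y = rng.normal(size=design.n_samples)
        fit = sm.fit_probe(y, design)
        oracle = _normal_equations_oracle(design.values, y)
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8)
        resid = y - design.values @ oracle
        assert fit.rss == pytest.approx(float(resid @ resid), abs=1e-10)
        assert fit.df_resid == design.n_samples - design.rank

    def test_df_exhausted(self):
        X = DesignMatrix(values=np.eye(4), columns=("a", "b", "c", "d"), rank=4)
        with pytest.raises(FitError):
            sm.fit_probe(np.ones(4), X)

    def test_length_mismatch(self, tiny_sheet):
        design = sm.build_design(tiny_sheet)
        with pytest.raises(ContractError):
            sm.fit_probe(np.ones(5), design)


class TestFTest:
    def test_equal_rss_gives_p_one(self):
        full = sm.ProbeFit(np.zeros(2), ("a", "b"), rss=1.0, df_resid=10, rank=2)
        null = sm.ProbeFit(np.zeros(1), ("a",), rss=1.0, df_resid=11, rank=1)
        assert sm.f_test(full, null) == pytest.approx(1.0)

    def test_f_quantile_oracle(self):
        # F(1, 10) upper 5% point recovered through an inverse-CDF oracle
        f_crit = float(stats.f.ppf(0.95, 1, 10))
        assert f_crit == pytest.approx(4.964603, abs=1e-6)
        full = sm.ProbeFit(np.zeros(2), ("a", "b"), rss=1.0, df_resid=10, rank=2)
        null_rss = 1.0 + f_crit / 10.0  # solves (dRSS/1)/(RSS/10) = f_crit
        null = sm.ProbeFit(np.zeros(1), ("a",), rss=null_rss, df_resid=11, rank=1)
        assert sm.f_test(full, null) == pytest.approx(0.05, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_single_restriction_equals_t_squared(self, cohort_sheet, seed):
        import statsmodels.api as smf

        rng = np.random.default_rng(100 + seed)
        design = sm.build_design(cohort_sheet, ["age", "sex"])
        y = rng.normal(size=design.n_samples)
        full = sm.fit_probe(y, design)
        null = sm.fit_probe(y, design.drop_columns(["vacation_swd"]))
        p_f = sm.f_test(full, null)
        ols = smf.OLS(y, design.values).fit()
        p_t = float(ols.pvalues[design.column_index("vacation_swd")])
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_non_nested_raises(self):
        a = sm.ProbeFit(np.zeros(2), ("a", "b"), rss=1.0, df_resid=10, rank=2)
        with pytest.raises(ContractError):
            sm.f_test(a, a)

    def test_perfect_fit_warns(self):
        full = sm.ProbeFit(np.zeros(2), ("a", "b"), rss=0.0, df_resid=10, rank=2)
        null = sm.ProbeFit(np.zeros(1), ("a",), rss=1.0, df_resid=11, rank=1)
        with pytest.warns(UserWarning):
            assert sm.f_test(full, null) == 0.0


class TestHypotheses:
    def test_p_both_is_max(self, cohort_sheet):
        rng = np.random.default_rng(3)
        design = sm.build_design(cohort_sheet)
        for _ in range(20):
            y = rng.normal(size=design.n_samples)
            p_swd, p_ctrl, p_either, p_both = sm.test_probe_hypotheses(y, design)
            assert p_both == max(p_swd, p_ctrl)
            for p in (p_swd, p_ctrl, p_either, p_both):
                assert 0.0 <= p <= 1.0

    def test_effect_only_in_swd_shifts_p_swd(self, cohort_sheet):
        design = sm.build_design(cohort_sheet)
        swd_vac = design.values[:, 2]
        rng = np.random.default_rng(4)
        p_swd_all, p_ctrl_all = [], []
        for _ in range(200):
            y = 0.8 * swd_vac + rng.normal(0, 0.5, size=design.n_samples)
            p_swd, p_ctrl, _, _ = sm.test_probe_hypotheses(y, design)
            p_swd_all.append(p_swd)
            p_ctrl_all.append(p_ctrl)
        assert np.median(p_swd_all) < np.median(p_ctrl_all)


class TestRunEwas:
    def test_zero_probes(self, cohort_sheet):
        matrix = pd.DataFrame(
            np.empty((0, cohort_sheet.shape[0])),
            columns=cohort_sheet["sample_id"].to_list())
        table = sm.run_ewas(matrix, cohort_sheet)
        assert table.shape[0] == 0

    def test_sample_mismatch(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        renamed = matrix.rename(columns={matrix.columns[0]: "GHOST"})
        with pytest.raises(AlignmentError, match="GHOST"):
            sm.run_ewas(renamed, cohort_sheet)

    def test_null_dmp_fraction_in_binomial_band(self, cohort_sheet):
        effects = sm.EffectConfig(n_probes=1000, frac_affected_swd=0.0,
                                  frac_affected_ctrl=0.0, noise_sd=1.0)
        matrix, _ = sm.generate_methylome(cohort_sheet, effects, seed=17)
        table = sm.run_ewas(matrix, cohort_sheet)
        for col in ("dmp_swd", "dmp_ctrl"):
            frac = table[col].mean()
            assert 0.03 <= frac <= 0.07

    def test_power_asymmetry_swd_only_effects(self, cohort_sheet):
        wins = 0
        n_reps = 40
        for rep in range(n_reps):
            effects = sm.EffectConfig(n_probes=100, frac_affected_swd=0.1,
                                      frac_affected_ctrl=0.0,
                                      effect_size_mean=1.0, effect_size_sd=0.0,
                                      noise_sd=0.5)
            matrix, _ = sm.generate_methylome(cohort_sheet, effects, seed=1000 + rep)
            table = sm.run_ewas(matrix, cohort_sheet)
            if table["dmp_swd"].mean() > table["dmp_ctrl"].mean():
                wins += 1
        assert wins >= int(0.95 * n_reps)

    def test_skips_zero_variance_and_missing(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        matrix = matrix.iloc[:20].copy()
        matrix.iloc[0] = 1.0  # zero variance
        matrix.iloc[1, :60] = np.nan  # too few complete cases
        matrix.iloc[2, 0] = np.nan  # complete-case refit still possible
        table = sm.run_ewas(matrix, cohort_sheet)
        assert matrix.index[0] not in table.index
        assert matrix.index[1] not in table.index
        assert matrix.index[2] in table.index
        assert table.shape[0] == 18

    def test_complete_case_matches_subset_fit(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        probe = matrix.index[3]
        withnan = matrix.iloc[:10].copy()
        withnan.loc[probe, withnan.columns[5]] = np.nan
        table = sm.run_ewas(withnan, cohort_sheet)
        keep = [c for c in withnan.columns if c != withnan.columns[5]]
        sub_sheet = cohort_sheet[cohort_sheet["sample_id"].isin(keep)]
        design = sm.build_design(sub_sheet.set_index("sample_id").loc[keep].reset_index())
        p_swd, _, _, _ = sm.test_probe_hypotheses(
            withnan.loc[probe, keep].to_numpy(), design)
        assert table.loc[probe, "p_swd"] == pytest.approx(p_swd, rel=1e-10)

    def test_direction_counts_partition(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        table = sm.run_ewas(matrix, cohort_sheet)
        for col in ("direction_swd", "direction_ctrl"):
            counts = table[col].value_counts()
            assert counts.sum() == table.shape[0]
            assert set(counts.index) <= {HYPO_AT_WORK, HYPER_AT_WORK, NO_DIRECTION}


class TestDirection:
    @pytest.mark.parametrize("beta,label", [
        (0.3, HYPO_AT_WORK),
        (-0.3, HYPER_AT_WORK),
        (0.0, NO_DIRECTION),
    ])
    def test_labels(self, beta, label):
        assert sm.classify_direction(beta) == label

    def test_non_finite(self):
        with pytest.raises(ContractError):
            sm.classify_direction(float("nan"))


class TestBH:
    def test_hand_computed_step_up(self):
        q = sm.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(sm.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_single(self):
        np.testing.assert_allclose(sm.bh_adjust([0.42]), [0.42])

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(sm.bh_adjust(p), q_ref, atol=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ContractError):
            sm.bh_adjust([0.5, 1.5])


class TestSummarize:
    def test_percent_rules_match_worked_examples(self):
        assert percent_one_decimal(28419, 433479) == 6.5
        assert percent_one_decimal(16056, 433479) == 3.7
        assert percent_integer(22166, 28419) == 78
        assert percent_integer(290430, 433479) == 67
        assert percent_integer(4836, 6090) == 79

    def test_empty_denominator_reported_missing(self):
        assert percent_integer(0, 0) is None
        assert percent_one_decimal(0, 0) is None

    def test_summary_consistency(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        table = sm.run_ewas(matrix, cohort_sheet)
        summary = sm.summarize_ewas(table)
        swd = summary["swd"]
        assert swd["n_dmp"] == int((table["p_swd"] < 0.05).sum())
        assert swd["n_hypo"] + int(
            (table["direction_swd"] != HYPO_AT_WORK).sum()) == swd["n_probes"]

    def test_no_dmps_missing_pct(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        table = sm.run_ewas(matrix, cohort_sheet, alpha=1e-12)
        summary = sm.summarize_ewas(table, alpha=1e-12)
        if summary["swd"]["n_dmp"] == 0:
            assert summary["swd"]["pct_hypo_dmp"] is None


class TestQQ:
    def test_uniform_grid_on_identity(self):
        n = 100
        p = (np.arange(1, n + 1) - 0.5) / n
        expected, observed = sm.qq_points(p)
        np.testing.assert_allclose(expected, observed, atol=1e-12)

    def test_single_point(self):
        expected, observed = sm.qq_points([0.5])
        assert expected[0] == pytest.approx(np.log10(2))
        assert observed[0] == pytest.approx(np.log10(2))

    def test_null_simulation_close_to_identity(self, cohort_sheet, null_dataset):
        matrix, _ = null_dataset
        table = sm.run_ewas(matrix, cohort_sheet)
        expected, observed = sm.qq_points(table["p_swd"].to_numpy())
        # KS-style bound on the uniform scale
        gap = np.max(np.abs(10.0 ** -expected - 10.0 ** -observed))
        assert gap < 1.63 / np.sqrt(table.shape[0])  # 99% KS band
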