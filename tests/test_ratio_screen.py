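import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import ratioscreen as rs
from ratioscreen.ratio_screen import _screen_fit
from tests.conftest import make_matrix


def _standardized(n, m, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, m))
    df = pd.DataFrame(
        x, index=[f"S{i+1:03d}" for i in range(n)], columns=[f"M{j+1}" for j in range(m)]
    )
    return (df - df.mean()) / df.std(ddof=1)


class TestZscore:
    def test_symmetric_example(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0]]))
        assert list(rs.zscore_standardize(m)["M1"]) == [-1.0, 0.0, 1.0]

    def test_hand_computed_example(self):
        col = np.array([2.0, 4.0, 4.0, 4.0, 5.0, 5.0, 7.0, 9.0])[:, None]
        z = rs.zscore_standardize(make_matrix(col))["M1"]
        # mean 5, sample SD sqrt(32/7) = 2.13809...
        assert z.iloc[0] == pytest.approx(-3 / np.sqrt(32 / 7))
        assert z.iloc[0] == pytest.approx(-1.4031, abs=1e-4)

    def test_normalization_identity(self, qc_matrix):
        z = rs.zscore_standardize(qc_matrix)
        assert z.mean().abs().max() < 1e-10
        assert (z.std(ddof=1) - 1).abs().max() < 1e-10

    def test_constant_column_named(self):
        m = make_matrix(np.column_stack([np.ones(5), np.arange(5.0)]),
                        metabolites=["Flat", "Ok"])
        with pytest.raises(ValueError, match="Flat"):
            rs.zscore_standardize(m)

    def test_unimputed_rejected(self):
        vals = np.ones((4, 1)) * 2
        vals[0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            rs.zscore_standardize(make_matrix(vals))


class TestBuildPairwiseRatios:
    def test_ordered_pair_count_m3(self):
        ratios = rs.build_pairwise_ratios(_standardized(10, 3))
        assert ratios.ratios.shape[1] == 6

    @pytest.mark.parametrize("m, mode, expected", [
        (152, "ordered", 22952),
        (152, "unordered", 11476),
        (5, "ordered", 20),
        (5, "unordered", 10),
    ])
    def test_pair_count_formula(self, m, mode, expected, qc_matrix):
        if m == 152:
            z = rs.zscore_standardize(qc_matrix).iloc[:10]
            z = (z - z.mean()) / z.std(ddof=1)
        else:
            z = _standardized(10, m)
        ratios = rs.build_pairwise_ratios(z, mode=mode)
        assert ratios.ratios.shape[1] == expected
        assert len(ratios.pairs) == expected

    def test_values_are_elementwise_quotients(self):
        z = _standardized(8, 3, seed=2)
        ratios = rs.build_pairwise_ratios(z)
        for _, row in ratios.pairs.iterrows():
            np.testing.assert_allclose(
                ratios.ratios[row["pair_id"]],
                z[row["numerator"]] / z[row["denominator"]],
            )

    def test_antisymmetry_reciprocal(self):
        z = _standardized(12, 4, seed=3)
        ratios = rs.build_pairwise_ratios(z, mode="ordered")
        a, b = z.columns[:2]
        fwd = ratios.ratios[f"{a}/{b}"]
        rev = ratios.ratios[f"{b}/{a}"]
        np.testing.assert_allclose(fwd, 1.0 / rev)

    def test_no_self_pairs(self):
        ratios = rs.build_pairwise_ratios(_standardized(6, 4))
        assert not (ratios.pairs["numerator"] == ratios.pairs["denominator"]).any()

    def test_guard_epsilon_flags_degenerate_cells(self):
        z = _standardized(20, 3, seed=4)
        eps = 0.5
        ratios = rs.build_pairwise_ratios(z, guard_epsilon=eps)
        for _, row in ratios.pairs.iterrows():
            expected = (z[row["denominator"]].abs() < eps).to_numpy()
            np.testing.assert_array_equal(
                ratios.degenerate[row["pair_id"]].to_numpy(), expected
            )
            assert ratios.ratios[row["pair_id"]].isna().to_numpy()[expected].all()

    def test_single_metabolite_rejected(self):
        with pytest.raises(ValueError, match="2 metabolites"):
            rs.build_pairwise_ratios(_standardized(5, 1))

    def test_unstandardized_input_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(5, 2, (10, 3)))
        with pytest.raises(ValueError, match="standardized"):
            rs.build_pairwise_ratios(df)

    def test_ratio_then_zscore_scheme(self):
        rng = np.random.default_rng(5)
        raw = pd.DataFrame(np.exp(rng.normal(2, 0.4, (15, 3))),
                           columns=["A", "B", "C"])
        ratios = rs.build_pairwise_ratios(raw, scheme="ratio_then_zscore")
        got = ratios.ratios["A/B"]
        expected = raw["A"] / raw["B"]
        expected = (expected - expected.mean()) / expected.std(ddof=1)
        np.testing.assert_allclose(got, expected)


class TestBonferroni:
    def test_metabolome_wide_threshold(self):
        thr = rs.bonferroni_threshold(0.05, 21952)
        assert thr.threshold == 0.05 / 21952
        assert f"{thr.threshold:.1e}" == "2.3e-06"

    @pytest.mark.parametrize("alpha, n, expected", [
        (0.05, 1, 0.05),
        (0.01, 100, 1e-4),
    ])
    def test_exact_division(self, alpha, n, expected):
        assert rs.bonferroni_threshold(alpha, n).threshold == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            rs.bonferroni_threshold(0.05, 0)


def _normal_equations_oracle(X, y, alpha=0.05):
    """Brute-force OLS via (X'X)^-1 X'y with t inference."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    tq = stats.t.ppf(1 - alpha / 2, df)
    return beta, se, p, beta - tq * se, beta + tq * se


class TestFitLinearAssociation:
    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_cov", [0, 3, 6])
    def test_matches_both_oracles(self, seed, n_cov):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 80))
        ratio = rng.standard_normal(n)
        cov = (
            pd.DataFrame(
                rng.standard_normal((n, n_cov)),
                columns=[f"c{i}" for i in range(n_cov)],
            )
            if n_cov
            else None
        )
        y = rng.standard_normal(n) + 0.5 * ratio
        fit = rs.fit_linear_association(ratio, y, cov)

        X = np.column_stack(
            [np.ones(n)] + ([cov.to_numpy()] if n_cov else []) + [ratio]
        )
        beta, se, p, lo, hi = _normal_equations_oracle(X, y)
        assert fit.beta == pytest.approx(beta[-1], rel=1e-8)
        assert fit.se == pytest.approx(se[-1], rel=1e-8)
        assert fit.p == pytest.approx(p[-1], rel=1e-6, abs=1e-12)
        assert fit.ci_low == pytest.approx(lo[-1], rel=1e-8)
        assert fit.ci_high == pytest.approx(hi[-1], rel=1e-8)

        res = sm.OLS(y, X).fit()
        assert fit.beta == pytest.approx(res.params[-1], rel=1e-8)
        assert fit.se == pytest.approx(res.bse[-1], rel=1e-8)
        assert fit.p == pytest.approx(res.pvalues[-1], rel=1e-6, abs=1e-12)

    def test_exact_fit_collapses_ci(self):
        x = np.arange(1.0, 11.0)
        fit = rs.fit_linear_association(x, 2.0 * x)
        assert fit.beta == pytest.approx(2.0, abs=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-10)
        assert fit.ci_low == pytest.approx(fit.ci_high, abs=1e-8)

    def test_null_p_values_uniform(self):
        ps = []
        for s in range(1000):
            rng = np.random.default_rng(s)
            ps.append(
                rs.fit_linear_association(
                    rng.standard_normal(30), rng.standard_normal(30)
                ).p
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            rs.fit_linear_association(rng.standard_normal(30),
                                      rng.standard_normal(30), cov)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            rs.fit_linear_association([1.0], [2.0])

    def test_nan_rows_dropped(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        y = 1.5 * x + rng.standard_normal(20)
        x_nan = x.copy()
        x_nan[:3] = np.nan
        fit = rs.fit_linear_association(x_nan, y)
        ref = rs.fit_linear_association(x[3:], y[3:])
        assert fit.n_used == 17
        assert fit.beta == pytest.approx(ref.beta, rel=1e-12)


class TestScreenFitVectorized:
    @pytest.mark.parametrize("n_cov", [0, 4])
    def test_agrees_with_single_fits(self, n_cov):
        rng = np.random.default_rng(7)
        n, m = 50, 30
        R = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        cov = pd.DataFrame(rng.standard_normal((n, n_cov)),
                           columns=[f"c{i}" for i in range(n_cov)]) if n_cov else None
        X0 = np.column_stack([np.ones(n)] + ([cov.to_numpy()] if n_cov else []))
        beta, se, p, lo, hi = _screen_fit(R, y, X0, 0.05)
        for j in range(m):
            fit = rs.fit_linear_association(R[:, j], y, cov)
            assert beta[j] == pytest.approx(fit.beta, rel=1e-9)
            assert se[j] == pytest.approx(fit.se, rel=1e-9)
            assert p[j] == pytest.approx(fit.p, rel=1e-6, abs=1e-12)
            assert lo[j] == pytest.approx(fit.ci_low, rel=1e-9, abs=1e-12)


def _small_screen_inputs(seed=0, m=6, n=60, beta=-2.0):
    """Small planted-effect dataset for screen-level tests."""
    panel = rs.make_panel({"amino_acid": m}, seed=seed)
    conc = rs.simulate_concentrations(panel, n, seed=seed, censor_plan={})
    cohort = rs.simulate_cohort((n // 2, n - n // 2), seed=seed)
    effect = rs.EffectSpec(
        numerator_id=panel.index[0], denominator_id=panel.index[1],
        beta=beta, residual_sd=1.0,
    )
    vols = rs.simulate_outcomes(conc, cohort, effect, seed=seed)
    prog = rs.build_progression_table(vols)
    z = rs.zscore_standardize(conc.values)
    ratios = rs.build_pairwise_ratios(z)
    return ratios, prog, cohort, effect


class TestRunScreen:
    def test_planted_pair_ranks_first(self):
        ratios, prog, cohort, effect = _small_screen_inputs()
        table, thr = rs.run_screen(ratios, prog, "lateral", cohort)
        assert table["pair_id"].iloc[0] == (
            f"{effect.numerator_id}/{effect.denominator_id}"
        )
        assert thr.n_tests == len(table)
        assert table["p_unadj"].is_monotonic_increasing

    def test_significance_flag_matches_threshold(self):
        ratios, prog, cohort, _ = _small_screen_inputs()
        table, thr = rs.run_screen(ratios, prog, "lateral", cohort)
        np.testing.assert_array_equal(
            table["significant"], table["p_unadj"] <= thr.threshold
        )

    def test_scale_equivariance(self):
        ratios, prog, cohort, _ = _small_screen_inputs()
        t1, _ = rs.run_screen(ratios, prog, "lateral", cohort)
        prog2 = prog.copy()
        prog2["pct_change"] *= 3.0
        t2, _ = rs.run_screen(ratios, prog2, "lateral", cohort)
        for col in ("beta_unadj", "ci_low_unadj", "ci_high_unadj", "beta_adj"):
            np.testing.assert_allclose(t2[col], 3.0 * t1[col], rtol=1e-9)
        np.testing.assert_allclose(t2["p_unadj"], t1["p_unadj"], rtol=1e-9)
        np.testing.assert_allclose(t2["p_adj"], t1["p_adj"], rtol=1e-9)

    def test_n_tests_override(self):
        ratios, prog, cohort, _ = _small_screen_inputs()
        cfg = rs.RunConfig(n_tests_override=21952)
        _, thr = rs.run_screen(ratios, prog, "lateral", cohort, cfg)
        assert thr.n_tests == 21952
        assert thr.threshold == 0.05 / 21952

    def test_missing_compartment_rejected(self):
        ratios, prog, cohort, _ = _small_screen_inputs()
        with pytest.raises(ValueError, match="patellar"):
            rs.run_screen(ratios, prog[prog["compartment"] == "lateral"],
                          "patellar", cohort)

    def test_missing_covariate_named(self):
        ratios, prog, cohort, _ = _small_screen_inputs()
        with pytest.raises(ValueError, match="bmi"):
            rs.run_screen(ratios, prog, "lateral", cohort.drop(columns=["bmi"]))

    def test_degenerate_cells_excluded_from_fit(self):
        ratios, prog, cohort, _ = _small_screen_inputs()
        z_cols = ratios.ratios
        # re-build with a large guard: some cells drop, n_used < n
        z = rs.zscore_standardize(
            rs.simulate_concentrations(
                rs.make_panel({"amino_acid": 6}, seed=0), 60, seed=0, censor_plan={}
            ).values
        )
        guarded = rs.build_pairwise_ratios(z, guard_epsilon=0.3)
        table, _ = rs.run_screen(guarded, prog, "lateral", cohort)
        assert (table["n_used"] < 60).any()
        # spot-check one pair against a complete-case single fit
        row = table[table["n_used"] < 60].iloc[0]
        y = (
            prog[prog["compartment"] == "lateral"]
            .set_index("subject_id")["pct_change"]
            .reindex(guarded.ratios.index)
        )
        ref = rs.fit_linear_association(guarded.ratios[row["pair_id"]], y)
        assert row["beta_unadj"] == pytest.approx(ref.beta, rel=1e-9)
        assert row["n_used"] == ref.n_used

    def test_permuted_outcome_destroys_planted_signal(self):
        ratios, prog, cohort, effect = _small_screen_inputs(m=6, n=139, beta=-1.0)
        pair = f"{effect.numerator_id}/{effect.denominator_id}"
        r = ratios.ratios[pair].to_numpy()
        y = (
            prog[prog["compartment"] == "lateral"]
            .set_index("subject_id")["pct_change"]
            .reindex(ratios.ratios.index)
            .to_numpy()
        )
        thr = rs.bonferroni_threshold(0.05, ratios.ratios.shape[1]).threshold
        rng = np.random.default_rng(0)
        hits = sum(
            rs.fit_linear_association(r, rng.permutation(y)).p <= thr
            for _ in range(200)
        )
        assert hits <= 10  # significant in <= 5% of permutations


class TestPosthocPower:
    def test_null_power_matches_alpha(self):
        power = rs.posthoc_power(0.0, 60, alpha=0.05, sim_reps=600, seed=0)
        assert power == pytest.approx(0.05, abs=0.03)

    def test_large_effect_saturates(self):
        power = rs.posthoc_power(5.0, 139, alpha=2.3e-6, sim_reps=200, seed=0,
                                 residual_sd=1.0)
        assert power > 0.99

    def test_matches_analytic_approximation(self):
        # normal regressor, n large enough that the t and normal critical
        # values agree at this extreme alpha; beta/SE ~ 5
        n, sd, alpha = 2000, 1.0, 2.3e-6
        beta = 5.0 * sd / np.sqrt(n)
        power = rs.posthoc_power(beta, n, alpha, sim_reps=800, seed=1,
                                 residual_sd=sd, ratio_dist="normal")
        approx = rs.analytic_power(beta, sd / np.sqrt(n), alpha)
        assert power == pytest.approx(approx, abs=0.06)
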