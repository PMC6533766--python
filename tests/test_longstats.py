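"""Random-intercept time-course models, DMC calling and supporting statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_series, gls_time_fit
from methdyn.longstats import (
    bh_fdr,
    call_dmcs,
    concordance_test,
    dmc_analysis,
    fit_covariate_model,
    fit_genotype_model,
    fit_time_model,
    parametric_bootstrap,
    posthoc_contrasts,
    power_sim,
    relative_expression,
    stepwise_aic,
)
from methdyn.simdata import SimulationConfig, counts_from_truth, simulate_cohort


class TestFitTimeModel:
    def test_exact_shift_recovered_at_tiny_noise(self):
        df = balanced_series(
            10, (0, 3), {3: -4.0}, subject_sd=3.0, residual_sd=1e-3, seed=2
        )
        fit = fit_time_model(df)
        assert fit.converged
        assert fit.time_coefficients.iloc[0] == pytest.approx(-4.0, abs=1e-2)

    def test_balanced_zero_subject_variance_matches_ols(self):
        df = balanced_series(
            12, (0, 1, 3, 6, 23), {3: -2.0, 6: -3.0}, subject_sd=0.0,
            residual_sd=2.0, seed=5,
        )
        fit = fit_time_model(df)
        # balanced design: fixed effects equal the OLS group means exactly
        times = sorted(df["time_h"].unique())
        means = df.groupby("time_h")["level"].mean()
        assert fit.params["Intercept"] == pytest.approx(means[0.0], abs=1e-6)
        for t, coef in zip(times[1:], fit.time_coefficients):
            assert coef == pytest.approx(means[t] - means[0.0], abs=1e-6)

    def test_wald_matches_gls_closed_form(self):
        df = balanced_series(
            15, (0, 1, 3, 6, 23), {1: -1.0, 3: -4.0, 6: -5.0, 23: -1.0},
            subject_sd=3.0, residual_sd=1.5, seed=8,
        )
        fit = fit_time_model(df)
        beta, cov, chi2 = gls_time_fit(df, fit.sigma_u2, fit.sigma_e2)
        assert fit.chi2 == pytest.approx(chi2, rel=1e-4)
        np.testing.assert_allclose(
            fit.params.to_numpy(), beta, rtol=1e-5, atol=1e-6
        )

    def test_single_timepoint_is_error(self):
        df = balanced_series(5, (0,), {})
        with pytest.raises(ValueError):
            fit_time_model(df)

    def test_degenerate_response_flagged_not_raised(self):
        df = balanced_series(5, (0, 3), {}, subject_sd=0.0, residual_sd=0.0)
        fit = fit_time_model(df)
        assert not fit.converged and np.isnan(fit.p)


class TestPosthocContrasts:
    def test_null_delta_near_zero(self):
        df = balanced_series(20, (0, 3), {}, seed=3)
        ph = posthoc_contrasts(df)
        assert abs(ph["delta_pct"].iloc[0]) < 1.5

    def test_constructed_shift_recovered(self):
        df = balanced_series(
            15, (0, 3, 6), {3: -5.0, 6: -5.0}, residual_sd=0.3, seed=4
        )
        ph = posthoc_contrasts(df).set_index("time_h")
        assert ph.loc[3.0, "delta_pct"] == pytest.approx(-5.0, abs=0.2)
        assert ph.loc[6.0, "delta_pct"] == pytest.approx(-5.0, abs=0.2)

    def test_unbalanced_subset_still_fits(self):
        df = balanced_series(8, (0, 3, 6), {3: -3.0}, seed=6)
        df = df[~((df["subject"] == "s000") & (df["time_h"] == 3.0))]
        ph = posthoc_contrasts(df)
        assert ph["delta_pct"].notna().all()


def _bh_oracle(p):
    """Step-up rule by direct enumeration."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBhFdr:
    def test_hand_enumeration(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCallDmcs:
    def _frame(self, q, delta, p_contrast):
        return pd.DataFrame(
            {
                "cpg_id": ["x"],
                "q_value": [q],
                "delta_3": [delta],
                "p_3": [p_contrast],
            }
        )

    @pytest.mark.parametrize(
        "q,delta,p,expected",
        [
            (0.04, 1.2, 0.01, True),  # passes both rules
            (0.04, 0.8, 0.01, False),  # |delta| < 1
            (0.06, 5.0, 0.01, False),  # fails FDR
            (0.04, 5.0, 0.2, False),  # delta at a non-significant timepoint
        ],
    )
    def test_threshold_rules(self, q, delta, p, expected):
        out = call_dmcs(self._frame(q, delta, p))
        assert bool(out["is_dmc"].iloc[0]) is expected

    def test_empty_input(self):
        out = call_dmcs(pd.DataFrame({"cpg_id": [], "q_value": []}))
        assert out.empty


class TestCovariateModel:
    def _series_with_cov(self, slope=0.0, delta=-5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(20):
            u = rng.normal(0, 3)
            lymph0 = rng.normal(2.0, 0.4)
            for t in (0.0, 3.0, 18.0):
                lymph = lymph0 * (0.55 if t == 3.0 else 1.0) + rng.normal(0, 0.05)
                lvl = (
                    50
                    + u
                    + (delta if t == 3.0 else 0.0)
                    + slope * lymph
                    + rng.normal(0, 1.0)
                )
                rows.append((f"s{i}", t, lvl, lymph))
        return pd.DataFrame(
            rows, columns=["subject", "time_h", "level", "lymphocyte_count"]
        )

    def test_null_covariate_coefficient_near_zero(self):
        df = self._series_with_cov(slope=0.0)
        rng = np.random.default_rng(1)
        df["noise_cov"] = rng.normal(size=len(df))
        fit = fit_covariate_model(df, ["noise_cov"])
        se = abs(fit.params["noise_cov"]) / max(
            np.sqrt(-2 * np.log(max(fit.covariate_p["noise_cov"], 1e-300))), 1e-9
        )
        assert fit.covariate_p["noise_cov"] > 0.01

    def test_time_effect_survives_adjustment(self):
        # lymphocytes co-vary with time (DEX lymphopenia), so adjustment
        # absorbs part of the shift; the time effect must stay significant
        df = self._series_with_cov(slope=0.0, delta=-5.0)
        fit = fit_covariate_model(df, ["lymphocyte_count"])
        assert fit.omnibus_time[2] < 0.05
        assert fit.coefficient_ratio["lymphocyte_count"] > 1.0

    def test_standardization_preserves_wald_p(self):
        df = self._series_with_cov(slope=2.0)
        raw = fit_covariate_model(df, ["lymphocyte_count"], standardize=False)
        std = fit_covariate_model(df, ["lymphocyte_count"], standardize=True)
        assert raw.covariate_p["lymphocyte_count"] == pytest.approx(
            std.covariate_p["lymphocyte_count"], rel=1e-4
        )
        assert raw.params["lymphocyte_count"] != pytest.approx(
            std.params["lymphocyte_count"]
        )

    def test_constant_covariate_dropped(self):
        df = self._series_with_cov()
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_covariate_model(df, ["const"])
        assert fit.dropped == ["const"]


class TestStepwiseAic:
    def _series(self, effect=0.0, seed=0, n=80):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            u = rng.normal(0, 2)
            smoking = rng.normal(0, 2)
            age = rng.normal(40, 10)
            for t in (0.0, 3.0):
                lvl = (
                    50 + u - (4.0 if t else 0.0)
                    + effect * smoking
                    + rng.normal(0, 1.0)
                )
                rows.append((f"s{i}", t, lvl, smoking, age))
        return pd.DataFrame(
            rows, columns=["subject", "time_h", "level", "smoking_score", "age"]
        )

    def test_independent_candidates_mostly_select_time_only(self):
        # AIC admits a useless term when its LR improvement exceeds 2,
        # which happens ~16% of the time per candidate; the time-only
        # model must still win in the clear majority of replicates
        n_time_only = 0
        for seed in range(12):
            df = self._series(effect=0.0, seed=seed)
            table = stepwise_aic(df, ["smoking_score", "age"])
            n_time_only += table.attrs["selected_covariates"] == []
        assert n_time_only >= 6

    def test_strong_covariate_selected_first(self):
        wins = 0
        for seed in range(10):
            df = self._series(effect=2.0, seed=seed)
            table = stepwise_aic(df, ["smoking_score", "age"])
            sel = table.attrs["selected_covariates"]
            if sel and sel[0] == "smoking_score":
                wins += 1
        assert wins >= 9

    def test_aic_bookkeeping_matches_direct_likelihood(self):
        import statsmodels.formula.api as smf

        df = self._series(effect=0.0, seed=3)
        table = stepwise_aic(df, ["age"])
        res0 = smf.mixedlm(
            "level ~ C(time_h, Treatment(0.0))", df, groups=df["subject"]
        ).fit(reml=False)
        aic0 = -2 * res0.llf + 2 * (len(res0.fe_params) + 2)
        assert table.loc[table["model"] == "time_only", "aic"].iloc[0] == pytest.approx(
            aic0, rel=1e-6
        )
        # a useless predictor costs at most +2 AIC minus twice its logLik gain
        aic_age = table.loc[table["model"] == "time + age", "aic"].iloc[0]
        assert aic_age <= aic0 + 2 + 1e-8


class TestGenotypeModel:
    def _series(self, interaction=1.0, n=60, seed=0, delta=-5.0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            grp = "T-carrier" if i < int(0.45 * n) else "CC"
            g = interaction if grp == "T-carrier" else 1.0
            u = rng.normal(0, 3)
            for t in (0.0, 3.0, 18.0):
                d = delta if t == 3.0 else (0.2 * delta if t == 18.0 else 0.0)
                rows.append((f"s{i}", t, 50 + u + g * d + rng.normal(0, 1.5), grp))
        return pd.DataFrame(
            rows, columns=["subject", "time_h", "level", "genotype_group"]
        )

    def test_single_group_is_error(self):
        df = self._series()
        df["genotype_group"] = "CC"
        with pytest.raises(ValueError, match="genotype"):
            fit_genotype_model(df)

    def test_interaction_detected_when_present(self):
        hits = 0
        for seed in range(6):
            g = fit_genotype_model(self._series(interaction=2.0, seed=seed))
            if g.interaction_p[3.0] <= 0.05:
                hits += 1
        assert hits >= 5

    def test_no_interaction_when_groups_identical(self):
        ps = [
            fit_genotype_model(self._series(interaction=1.0, seed=s)).interaction_p[3.0]
            for s in range(8)
        ]
        assert sum(p <= 0.05 for p in ps) <= 2

    def test_effect_signs_reported_per_group_and_time(self):
        g = fit_genotype_model(self._series(interaction=2.0, seed=1))
        signs = g.effect_signs.set_index(["time_h", "group"])["sign"]
        assert signs.loc[(3.0, "CC")] == -1
        assert signs.loc[(3.0, "T-carrier")] == -1
        assert g.interaction_sign(3.0) == -1  # carriers fall further


# the Wald chi-square is asymptotic: alpha recovery needs a design large
# enough that t-vs-normal differences are negligible
@pytest.fixture(scope="module")
def null_fit():
    df = balanced_series(60, (0, 3), {}, subject_sd=2.0, residual_sd=1.5, seed=9)
    return fit_time_model(df)


class TestPowerSim:

    def test_zero_effect_recovers_alpha(self, null_fit):
        pw = power_sim(null_fit, min_effect_pct=0.0, n_sim=100, seed=3)
        se = np.sqrt(0.05 * 0.95 / 100)
        assert abs(pw.power - 0.05) < 2.58 * se + 1e-9

    def test_huge_effect_certain_detection(self, null_fit):
        effect = 10 * np.sqrt(null_fit.sigma_e2)
        pw = power_sim(null_fit, min_effect_pct=effect, n_sim=50, seed=3)
        assert pw.power >= 0.99

    def test_deterministic_under_seed(self, null_fit):
        a = power_sim(null_fit, n_sim=30, seed=11)
        b = power_sim(null_fit, n_sim=30, seed=11)
        assert a == b
        assert a.ci_low <= a.power <= a.ci_high


class TestParametricBootstrap:
    def test_near_degenerate_model_collapses_ci(self):
        df = balanced_series(
            8, (0, 3), {3: -5.0}, subject_sd=0.0, residual_sd=1e-3, seed=2
        )
        fit = fit_time_model(df)
        boot = parametric_bootstrap(fit, n_sim=30, seed=1)
        name = fit.time_coefficients.index[0]
        assert boot.se[name] < 0.01
        assert boot.ci_high[name] - boot.ci_low[name] < 0.01
        assert abs(boot.bias[name]) < 0.01

    def test_se_matches_sampling_theory(self):
        df = balanced_series(
            20, (0, 3), {3: -3.0}, subject_sd=3.0, residual_sd=2.0, seed=7
        )
        fit = fit_time_model(df)
        boot = parametric_bootstrap(fit, n_sim=80, seed=5)
        name = fit.time_coefficients.index[0]
        theory = np.sqrt(2 * fit.sigma_e2 / 20)
        assert boot.se[name] == pytest.approx(theory, rel=0.35)
        assert boot.reliable

    def test_deterministic_under_seed(self):
        df = balanced_series(8, (0, 3), {3: -2.0}, seed=4)
        fit = fit_time_model(df)
        b1 = parametric_bootstrap(fit, n_sim=20, seed=9)
        b2 = parametric_bootstrap(fit, n_sim=20, seed=9)
        pd.testing.assert_series_equal(b1.se, b2.se)
        pd.testing.assert_series_equal(b1.ci_low, b2.ci_low)


def _concordance_oracle(n, k):
    """Exhaustive enumeration of all 2^n outcomes."""
    count = 0
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) >= k:
            count += 1
    return count / 2**n


class TestConcordance:
    def test_printed_example_n30_k20(self):
        n, k, p = concordance_test([1] * 20 + [-1] * 10, [1] * 30)
        assert (n, k) == (30, 20)
        assert round(p, 3) == 0.049

    def test_n50_k27(self):
        a = [1] * 27 + [-1] * 23
        b = [1] * 50
        _, _, p = concordance_test(a, b)
        assert p == pytest.approx(0.336, abs=5e-4)

    def test_perfect_agreement_closed_form(self):
        for n in (3, 7, 10):
            _, k, p = concordance_test([1] * n, [1] * n)
            assert k == n
            assert p == pytest.approx(0.5**n)

    def test_matches_exhaustive_enumeration_small_n(self):
        for n in range(1, 13):
            for k in range(0, n + 1):
                a = [1] * k + [-1] * (n - k)
                b = [1] * n
                _, got_k, p = concordance_test(a, b)
                assert got_k == k
                assert p == pytest.approx(_concordance_oracle(n, k), abs=1e-12)

    def test_zero_signs_excluded(self):
        n, k, _ = concordance_test([1, 0, -1, 1], [1, 1, -1, 0])
        assert n == 2 and k == 2

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            concordance_test([0, 0], [1, 1])


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ct_t,ct_r,et,er,expected",
        [
            ((20.0, 20.0), (18.0, 18.0), 2.0, 2.0, 1.0),
            ((22.0, 20.0), (18.0, 18.0), 2.0, 2.0, 4.0),
            ((22.0, 20.0), (19.0, 18.0), 1.9, 2.0, 1.805),
        ],
    )
    def test_ratio_formula(self, ct_t, ct_r, et, er, expected):
        assert relative_expression(ct_t, ct_r, et, er) == pytest.approx(expected)

    def test_nonpositive_efficiency_is_error(self):
        with pytest.raises(ValueError):
            relative_expression((1, 1), (1, 1), eff_target=0.0)


class TestDmcAnalysisPipeline:
    def test_recovers_planted_dmcs_from_counts(self):
        sites = [f"site{i}" for i in range(10)]
        base = {s: 0.5 for s in sites}
        prof = {
            s: (
                {0.0: 0.0, 3.0: -6.0, 6.0: -6.0}
                if i < 3
                else {0.0: 0.0, 3.0: 0.0, 6.0: 0.0}
            )
            for i, s in enumerate(sites)
        }
        cfg = SimulationConfig(
            n_subjects=19,
            timepoints_h=(0.0, 3.0, 6.0),
            genotype_freqs={"CC": 1.0, "CT": 0.0, "TT": 0.0},
            baseline_level=base,
            delta_profile=prof,
            subject_sd=3.0,
            residual_sd=1.5,
            seed=12,
        )
        truth = simulate_cohort(cfg)
        matrix = counts_from_truth(truth, coverage=1000, seed=12)
        res = dmc_analysis(matrix, truth.sample_sheet)
        called = set(res.loc[res["is_dmc"], "cpg_id"])
        assert {"site0", "site1", "site2"} <= called
        assert len(called - {"site0", "site1", "site2"}) <= 1
        hit = res.set_index("cpg_id").loc["site0"]
        assert hit["delta_3"] == pytest.approx(-6.0, abs=1.5)
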