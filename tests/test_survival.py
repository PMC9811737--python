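"""Cox fitting, bootstrap stabilisation, score, KM/log-rank, c-index."""

import math

import numpy as np
import pandas as pd
import pytest

from petsig.containers import CohortTable
from petsig.simulate import CohortSimConfig, TABLE_EFFECTS, simulate_cohort
from petsig.survival import (
    CoxModel,
    apply_score,
    bootstrap_cox,
    build_genetic_score,
    compare_risk_groups,
    concordance_index,
    cox_partial_loglik,
    derive_hr,
    fit_cox,
    km_estimate,
    logrank_test,
    optimism_corrected_cindex,
)
from tests.conftest import make_cohort

# Published multivariable model rows used as fixed inputs for the
# derived-quantity arithmetic: (beta, se, hr, ci_low, ci_high).
PUBLISHED_ROWS = {
    "PARP2": (0.254, 0.0914, 1.29, 1.08, 1.54),
    "SLC2A4": (-0.733, 0.244, 0.48, 0.30, 0.78),
    "CTH": (-0.372, 0.144, 0.69, 0.52, 0.91),
    "ALDOB": (0.140, 0.0588, 1.15, 1.03, 1.29),
    "FOLH1": (-0.0943, 0.110, 0.91, 0.73, 1.13),
}


def brute_breslow_loglik(beta, times, events, x):
    """Explicit loop-based Breslow partial log-likelihood, 1 covariate."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestDeriveHR:
    @pytest.mark.parametrize("gene", sorted(PUBLISHED_ROWS))
    def test_reproduces_published_rows(self, gene):
        beta, se, hr_ref, lo_ref, hi_ref = PUBLISHED_ROWS[gene]
        hr, ci, _ = derive_hr(beta, se)
        assert hr[0] == pytest.approx(hr_ref, abs=0.005)
        assert ci[0, 0] == pytest.approx(lo_ref, abs=0.005)
        assert ci[0, 1] == pytest.approx(hi_ref, abs=0.005)

    def test_wald_p_values_match_closed_form(self):
        from scipy import stats
        # rows where the printed p agrees with the Wald arithmetic
        _, _, p = derive_hr(0.254, 0.0914)
        assert p[0] == pytest.approx(0.005, abs=0.002)
        _, _, p = derive_hr(-0.372, 0.144)
        assert p[0] == pytest.approx(0.009, abs=0.002)
        # every row matches the normal-tail closed form exactly
        for beta, se, *_ in PUBLISHED_ROWS.values():
            _, _, p = derive_hr(beta, se)
            assert p[0] == pytest.approx(2 * stats.norm.sf(abs(beta / se)), rel=1e-12)

    def test_null_beta(self):
        hr, ci, p = derive_hr(0.0, 0.3)
        assert hr[0] == 1.0 and p[0] == 1.0
        assert ci[0, 0] * ci[0, 1] == pytest.approx(1.0)  # symmetric about 1

    def test_zero_se_flags_degenerate_p(self):
        _, _, p = derive_hr(0.5, 0.0)
        assert p[0] == 0.0
        with pytest.raises(ValueError):
            derive_hr(0.1, -0.1)


class TestFitCox:
    def test_matches_grid_search_oracle(self, tiny_cohort):
        model = fit_cox(tiny_cohort, ["x"])
        grid = np.linspace(-4, 4, 16001)
        lls = [
            brute_breslow_loglik(b, tiny_cohort.times, tiny_cohort.events,
                                 tiny_cohort.data["x"].to_numpy())
            for b in grid
        ]
        assert model.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_partial_loglik_agrees_with_brute_force(self, tiny_cohort):
        for b in (-1.2, 0.0, 0.7):
            ours = cox_partial_loglik([b], tiny_cohort.times, tiny_cohort.events,
                                      tiny_cohort.data[["x"]].to_numpy())
            ref = brute_breslow_loglik(b, tiny_cohort.times, tiny_cohort.events,
                                       tiny_cohort.data["x"].to_numpy())
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_constant_covariate_is_singular(self):
        cohort = make_cohort([1, 2, 3, 4.0], [1, 1, 1, 0], g=[2.0] * 4)
        with pytest.raises(np.linalg.LinAlgError):
            fit_cox(cohort, ["g"])

    def test_no_events_errors(self):
        cohort = make_cohort([1, 2, 3.0], [0, 0, 0], g=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            fit_cox(cohort, ["g"])

    def test_two_group_hazard_ratio_recovery(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
        c = rng.uniform(0, 40, n)
        cohort = make_cohort(np.minimum(t, c), (t <= c).astype(int), g=x)
        model = fit_cox(cohort, ["g"])
        assert abs(model.beta[0] - np.log(2.0)) < 3 * model.se[0]

    def test_agrees_with_statsmodels_breslow(self, default_cohort):
        sm = pytest.importorskip("statsmodels.duration.hazard_regression")
        genes = list(TABLE_EFFECTS)
        model = fit_cox(default_cohort, genes)
        ref = sm.PHReg(
            default_cohort.times, default_cohort.columns_matrix(genes),
            status=default_cohort.events, ties="breslow",
        ).fit()
        assert np.allclose(model.beta, ref.params, atol=1e-6)
        assert np.allclose(model.se, ref.bse, atol=1e-6)

    def test_efron_agrees_with_lifelines(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(5)
        n = 120
        x = rng.standard_normal(n)
        t = np.ceil(rng.exponential(1.0 / (0.1 * np.exp(0.5 * x))))  # heavy ties
        cohort = make_cohort(t, np.ones(n, int), g=x)
        model = fit_cox(cohort, ["g"], ties="efron")
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": 1, "g": x}), "t", "e")
        assert model.beta[0] == pytest.approx(cph.params_["g"], abs=1e-5)

    def test_hr_ci_consistency_invariant(self, default_cohort):
        model = fit_cox(default_cohort, list(TABLE_EFFECTS))
        assert np.allclose(model.hr, np.exp(model.beta), atol=1e-9)
        assert np.allclose(model.ci95[:, 0], np.exp(model.beta - 1.96 * model.se), atol=1e-9)
        assert np.allclose(model.ci95[:, 1], np.exp(model.beta + 1.96 * model.se), atol=1e-9)


class TestBootstrapCox:
    def test_single_replicate_equals_its_fit(self, default_cohort):
        genes = ["PARP2", "SLC2A4"]
        model = bootstrap_cox(default_cohort, genes, B=1, seed=123)
        idx = np.random.default_rng(123).integers(0, default_cohort.n_patients,
                                                  default_cohort.n_patients)
        sub = CohortTable(
            data=default_cohort.data.iloc[idx].assign(
                patient_id=[f"B{i:05d}" for i in range(len(idx))]),
            gene_cols=default_cohort.gene_cols,
            clinical_cols=default_cohort.clinical_cols,
        )
        assert np.allclose(model.beta, fit_cox(sub, genes).beta)

    def test_null_effects_center_on_zero(self):
        cfg = CohortSimConfig(n_patients=250, n_genes=5,
                              causal_effects={g: 0.0 for g in TABLE_EFFECTS},
                              censoring_window=120.0, seed=2)
        cohort = simulate_cohort(cfg)
        model = bootstrap_cox(cohort, list(TABLE_EFFECTS), B=60, seed=0)
        assert np.all(np.abs(model.beta) < 3 * model.se)

    def test_invalid_B(self, default_cohort):
        with pytest.raises(ValueError):
            bootstrap_cox(default_cohort, ["PARP2"], B=0)


class TestParameterRecovery:
    def test_ci_coverage_of_generating_betas(self):
        """Multivariable CIs cover the generating coefficients at ~95 %."""
        truth = {g: v for g, v in TABLE_EFFECTS.items() if v != 0.0}
        genes = sorted(truth)
        covered = total = 0
        for seed in range(60):
            cfg = CohortSimConfig(n_genes=30, censoring_window=85.0, seed=seed)
            cohort = simulate_cohort(cfg)
            model = fit_cox(cohort, genes)
            for i, g in enumerate(genes):
                lo = model.beta[i] - 1.96 * model.se[i]
                hi = model.beta[i] + 1.96 * model.se[i]
                covered += lo <= truth[g] <= hi
                total += 1
        assert covered / total >= 0.93


class TestGeneticScore:
    def _published_model(self):
        rows = [PUBLISHED_ROWS[g] for g in ("PARP2", "SLC2A4", "CTH", "ALDOB", "FOLH1")]
        return CoxModel(
            features=("PARP2", "SLC2A4", "CTH", "ALDOB", "FOLH1"),
            beta=np.array([r[0] for r in rows]),
            se=np.array([r[1] for r in rows]),
            n_boot=500,
        )

    def test_significance_filter_drops_folh1(self):
        score = build_genetic_score(self._published_model())
        assert score.coefficients == {
            "PARP2": 0.254, "SLC2A4": -0.733, "CTH": -0.372, "ALDOB": 0.140,
        }

    def test_forced_gene_keeps_its_coefficient(self):
        score = build_genetic_score(self._published_model(), force_include=["FOLH1"])
        assert score.coefficients["FOLH1"] == pytest.approx(-0.0943)
        assert "0.0943*FOLH1" in score.formula_text

    def test_nothing_significant_errors(self):
        model = CoxModel(features=("A",), beta=np.array([0.01]), se=np.array([1.0]))
        with pytest.raises(ValueError):
            build_genetic_score(model)

    def test_score_values_on_unit_and_zero_expression(self):
        score = build_genetic_score(self._published_model())
        df = pd.DataFrame({
            "patient_id": ["P1", "P2"], "time_months": [1.0, 2.0], "event": [1, 0],
            "PARP2": [1.0, 0.0], "SLC2A4": [1.0, 0.0], "CTH": [1.0, 0.0],
            "ALDOB": [1.0, 0.0],
        })
        cohort = CohortTable(df, gene_cols=("PARP2", "SLC2A4", "CTH", "ALDOB"))
        s, _ = apply_score(score, cohort)
        assert s.iloc[0] == pytest.approx(0.254 - 0.733 - 0.372 + 0.140)
        assert s.iloc[1] == 0.0

    def test_median_tie_goes_to_high_risk(self):
        score = build_genetic_score(
            CoxModel(features=("g",), beta=np.array([1.0]), se=np.array([0.1])))
        cohort = make_cohort([1, 2, 3.0], [1, 1, 1], g=[-1.0, 0.0, 1.0])
        s, groups = apply_score(score, cohort)
        assert score.threshold == 0.0
        assert list(groups) == ["low", "high", "high"]

    def test_missing_gene_errors(self, default_cohort):
        score = build_genetic_score(
            CoxModel(features=("NOT_A_GENE",), beta=np.array([1.0]), se=np.array([0.1])))
        with pytest.raises(Exception):
            apply_score(score, default_cohort)


class TestKaplanMeierLogRank:
    def test_no_censoring_matches_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        steps = dict(zip(km.event_times, km.survival))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)
        assert km.median_survival == 2.0

    def test_all_censored_never_reaches_median(self):
        km = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)
        assert np.isinf(km.median_survival)
        assert km.median_label == "not reached"

    def test_hand_product_limit_with_censoring(self):
        # times 1, 2+, 3: S(1) = 2/3, S(3) = (2/3)*(0/1) = 0
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        steps = dict(zip(km.event_times, km.survival))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_survival_is_monotone_from_one(self, default_cohort):
        km = km_estimate(default_cohort.times, default_cohort.events)
        assert km.survival[0] <= 1.0 + 1e-12
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_logrank_identical_groups(self):
        t, e = [1, 2, 3, 4.0], [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_logrank_separated_groups_and_symmetry(self):
        rng = np.random.default_rng(0)
        n = 250
        ta = rng.exponential(10, n)
        tb = rng.exponential(10 / 3, n)  # hazard ratio 3
        ones = np.ones(n, int)
        res = logrank_test(ta, ones, tb, ones)
        assert res.p < 1e-4
        res_swapped = logrank_test(tb, ones, ta, ones)
        assert res.chi_square == pytest.approx(res_swapped.chi_square)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], [3.0, 4.0], [0, 0])


class TestConcordance:
    def test_perfect_predictor(self):
        times = np.array([3.0, 1.0, 4.0, 2.0])
        assert concordance_index(-times, times, np.ones(4, int)) == 1.0

    def test_all_ties_is_chance(self):
        assert concordance_index(np.zeros(5), np.arange(5.0), np.ones(5, int)) == 0.5

    def test_random_predictor_near_half(self):
        rng = np.random.default_rng(1)
        c = concordance_index(rng.standard_normal(2000), rng.exponential(5, 2000),
                              np.ones(2000, int))
        assert abs(c - 0.5) < 0.03


class TestOptimismCorrection:
    def test_low_overfitting_regime(self):
        cfg = CohortSimConfig(n_patients=600, n_genes=5, censoring_window=85.0, seed=3)
        cohort = simulate_cohort(cfg)
        apparent, corrected = optimism_corrected_cindex(
            cohort, ["SLC2A4", "CTH"], B=60, seed=0)
        # near-zero optimism up to Monte-Carlo jitter in the mean
        assert abs(apparent - corrected) < 0.01

    def test_overfitting_regime_shrinks_cindex(self):
        rng = np.random.default_rng(7)
        n, p = 40, 15
        genes = {f"g{i:02d}": rng.standard_normal(n) for i in range(p)}
        cohort = make_cohort(rng.exponential(10, n), np.ones(n, int), **genes)
        apparent, corrected = optimism_corrected_cindex(
            cohort, sorted(genes), B=60, seed=1)
        assert apparent - corrected > 0.02

    def test_invalid_B(self, default_cohort):
        with pytest.raises(ValueError):
            optimism_corrected_cindex(default_cohort, ["PARP2"], B=0)


class TestGroupComparisons:
    def test_identical_continuous_samples(self):
        cohort = make_cohort(
            np.arange(1.0, 7.0), [1] * 6, g=np.zeros(6))
        cohort.data["age_years"] = [60.0, 61.0, 62.0, 60.0, 61.0, 62.0]
        groups = pd.Series(["low", "low", "low", "high", "high", "high"])
        res = compare_risk_groups(cohort, groups, ["age_years"], continuous={"age_years"})
        assert res[0].test == "t_test" and res[0].p == pytest.approx(1.0)

    def test_balanced_table_has_zero_chisquare(self):
        n = 200
        cohort = make_cohort(np.arange(1.0, n + 1), [1] * n, g=np.zeros(n))
        cohort.data["flag"] = ([0] * 50 + [1] * 50) * 2
        groups = pd.Series(["a"] * 100 + ["b"] * 100)
        res = compare_risk_groups(cohort, groups, ["flag"], continuous=set())
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)

    def test_chisquare_matches_hand_formula(self):
        # 2x2 table (90,10 / 60,40): sum (O-E)^2/E = 24.0
        n = 200
        cohort = make_cohort(np.arange(1.0, n + 1), [1] * n, g=np.zeros(n))
        cohort.data["flag"] = [0] * 90 + [1] * 10 + [0] * 60 + [1] * 40
        groups = pd.Series(["a"] * 100 + ["b"] * 100)
        res = compare_risk_groups(cohort, groups, ["flag"], continuous=set())
        assert res[0].statistic == pytest.approx(24.0)

    def test_more_than_two_groups_errors(self, default_cohort):
        groups = pd.Series(np.arange(default_cohort.n_patients) % 3)
        with pytest.raises(ValueError):
            compare_risk_groups(default_cohort, groups, ["age_years"])
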