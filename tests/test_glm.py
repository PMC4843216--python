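import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from occgaps.glm import (
    GLMFit,
    RankDeficientError,
    aicc,
    apply_nesting_rule,
    check_collinearity,
    fit_binomial_glm,
    fit_realm_model,
    rank_all_subsets,
    rank_country_models,
)


def no_design(n):
    return pd.DataFrame(index=range(n))


class TestFitBinomialGLM:
    def test_intercept_only_is_logit_of_pooled_proportion(self):
        fit = fit_binomial_glm([30], [100], no_design(1))
        assert fit.coefficients["(Intercept)"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_single_binary_covariate_is_log_odds_ratio(self):
        # grouped 2x2: 10/50 in group 0, 25/50 in group 1
        design = pd.DataFrame({"x": [0.0, 1.0]})
        fit = fit_binomial_glm([10, 25], [50, 50], design)
        lor = np.log((25 / 25) / (10 / 40))
        assert fit.coefficients["x"] == pytest.approx(lor, abs=1e-8)
        assert fit.coefficients["(Intercept)"] == pytest.approx(np.log(10 / 40), abs=1e-8)

    def test_all_zero_response_flags_separation(self):
        fit = fit_binomial_glm([0, 0, 0], [10, 10, 10], no_design(3))
        assert not fit.converged

    def test_runaway_bernoulli_separation_flagged(self):
        design = pd.DataFrame({"x": [0.0, 0, 0, 1, 1, 1]})
        fit = fit_binomial_glm([0, 0, 0, 1, 1, 1], np.ones(6), design)
        assert not fit.converged

    def test_rank_deficient_design_names_columns(self):
        design = pd.DataFrame({"a": [0.0, 1, 2, 3], "b": [0.0, 2, 4, 6]})
        with pytest.raises(RankDeficientError, match="a|b"):
            fit_binomial_glm([1, 2, 1, 3], [5, 5, 5, 5], design)

    def test_matches_independent_numerical_mle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n_units = 60
            x = pd.DataFrame(
                {"x1": rng.normal(size=n_units), "x2": rng.binomial(1, 0.4, n_units) * 1.0}
            )
            trials = rng.integers(5, 25, n_units)
            eta = -0.3 + 0.8 * x["x1"] - 0.5 * x["x2"]
            succ = rng.binomial(trials, 1 / (1 + np.exp(-eta)))
            fit = fit_binomial_glm(succ, trials, x)

            design = np.column_stack([np.ones(n_units), x.to_numpy()])

            def nll(beta):
                eta = design @ beta
                # binomial log-likelihood up to the constant choose term
                return -(succ * eta - trials * np.logaddexp(0.0, eta)).sum()

            res = minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
            got = np.array(list(fit.coefficients.values()))
            assert np.max(np.abs(got - res.x)) < 1e-6

    def test_coefficient_recovery_within_three_se(self):
        # grouped-binomial simulation from known coefficients
        rng = np.random.default_rng(42)
        truth = np.array([-0.5, 0.6, -0.4])
        inside = 0
        n_rep, n_units, trials_per = 200, 500, 20
        for _ in range(n_rep):
            x = pd.DataFrame(
                {"x1": rng.normal(size=n_units), "x2": rng.normal(size=n_units)}
            )
            eta = truth[0] + truth[1] * x["x1"] + truth[2] * x["x2"]
            succ = rng.binomial(trials_per, 1 / (1 + np.exp(-eta)))
            fit = fit_binomial_glm(succ, np.full(n_units, trials_per), x)
            est = np.array(list(fit.coefficients.values()))
            se = np.array(list(fit.standard_errors.values()))
            inside += int(np.all(np.abs(est - truth) <= 3 * se))
        assert inside / n_rep >= 0.95

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_binomial_glm([1], [0], no_design(1))
        with pytest.raises(ValueError):
            fit_binomial_glm([5], [3], no_design(1))


class TestAICc:
    def fit(self, llf, k, n):
        return GLMFit({}, {}, llf, n, k, True)

    def test_closed_form(self):
        assert aicc(self.fit(-5.0, 2, 10)) == pytest.approx(10 + 4 + 12 / 7)

    def test_zero_parameters(self):
        assert aicc(self.fit(-3.0, 0, 10)) == pytest.approx(6.0)

    def test_large_n_tends_to_aic(self):
        val = aicc(self.fit(-5.0, 2, 10**7))
        assert val == pytest.approx(14.0, abs=1e-5)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(self.fit(-5.0, 4, 5))


class TestModelRanking:
    def sim_country_data(self, rng, beta_gpi=0.6, n=25):
        gpi = rng.normal(size=n)
        gdp = rng.normal(size=n)
        eng = rng.binomial(1, 0.4, n) * 1.0
        trials = rng.integers(20, 80, n)
        eta = -1.0 + beta_gpi * gpi
        succ = rng.binomial(trials, 1 / (1 + np.exp(-eta)))
        cand = pd.DataFrame({"log_gdp_pc": gdp, "gpi_rank": gpi, "english_official": eng})
        return succ, trials, cand

    def test_eight_models_for_three_predictors(self):
        rng = np.random.default_rng(3)
        succ, trials, cand = self.sim_country_data(rng)
        ranking = rank_all_subsets(succ, trials, cand)
        assert len(ranking.models) == 8
        assert ranking.models[0].delta_aicc == 0.0
        deltas = [m.delta_aicc for m in ranking.models]
        assert deltas == sorted(deltas)
        subsets = {m.predictors for m in ranking.models}
        assert () in subsets and ("log_gdp_pc", "gpi_rank", "english_official") in subsets

    def test_null_wins_without_signal(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            succ, trials, cand = self.sim_country_data(rng, beta_gpi=0.0)
            ranking = rank_all_subsets(succ, trials, cand)
            wins += ranking.best.predictors == ()
        assert wins > 10  # the null model ranks first on most no-effect draws

    def test_true_predictor_found_with_signal(self):
        rng = np.random.default_rng(8)
        succ, trials, cand = self.sim_country_data(rng, beta_gpi=0.8)
        ranking = rank_all_subsets(succ, trials, cand)
        assert "gpi_rank" in ranking.best.predictors

    def test_duplicated_predictor_fails_that_subset_only(self):
        rng = np.random.default_rng(5)
        succ, trials, cand = self.sim_country_data(rng)
        cand["dup"] = cand["gpi_rank"]
        ranking = rank_all_subsets(succ, trials, cand)
        assert ranking.failures  # subsets containing both collinear columns
        failed = {s for s, _ in ranking.failures}
        assert all({"gpi_rank", "dup"} <= set(s) for s in failed)


class TestNestingRule:
    def ranked(self, predictors, llf, aicc_val, competitive=True):
        from occgaps.glm import RankedModel

        fit = GLMFit({}, {}, llf, 25, len(predictors) + 1, True)
        return RankedModel(predictors, fit, aicc_val, 0.0, competitive)

    def test_one_extra_uninformative_parameter_demoted(self):
        from occgaps.glm import ModelRanking

        best = self.ranked(("gpi_rank",), -10.0, 24.0)
        extra = self.ranked(("gpi_rank", "log_gdp_pc"), -9.9, 25.5)
        ranking = apply_nesting_rule(ModelRanking([best, extra]))
        assert best.competitive and not extra.competitive

    def test_non_nested_competitor_stays(self):
        from occgaps.glm import ModelRanking

        best = self.ranked(("gpi_rank",), -10.0, 24.0)
        other = self.ranked(("log_gdp_pc",), -10.1, 25.5)
        ranking = apply_nesting_rule(ModelRanking([best, other]))
        assert other.competitive

    def test_genuinely_better_superset_stays(self):
        from occgaps.glm import ModelRanking

        best = self.ranked(("gpi_rank",), -10.0, 24.0)
        better = self.ranked(("gpi_rank", "log_gdp_pc"), -8.0, 25.0)
        ranking = apply_nesting_rule(ModelRanking([best, better]))
        assert better.competitive

    def test_empty_competitive_set_unchanged(self):
        from occgaps.glm import ModelRanking

        best = self.ranked(("gpi_rank",), -10.0, 24.0)
        far = self.ranked((), -20.0, 40.0, competitive=False)
        ranking = apply_nesting_rule(ModelRanking([best, far]))
        assert not far.competitive


class TestCollinearity:
    def test_perfectly_correlated_flagged(self):
        x = np.arange(10.0)
        rep = check_collinearity(pd.DataFrame({"x": x, "y": 2 * x}))
        assert rep["flagged"].all() and rep["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_columns_pass(self):
        rng = np.random.default_rng(1)
        rep = check_collinearity(
            pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        )
        assert not rep["flagged"].any()
        assert abs(rep["r"].iloc[0]) < 0.1

    def test_constant_column_flagged(self):
        rep = check_collinearity(pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]}))
        assert rep["flagged"].all() and rep["note"].iloc[0] == "constant column"


class TestConcreteAnalyses:
    def test_realm_model_terms(self, joined):
        fit = fit_realm_model(joined, "Palaearctic")
        assert set(fit.coefficients) == {
            "(Intercept)",
            "grassland_shrubland",
            "anthrome",
            "pa",
            "hii",
        }
        assert fit.converged

    def test_country_ranking_runs_with_nesting_rule(self, joined, high_effort):
        from occgaps.absence import summarize_by_country

        tab = summarize_by_country(joined, high_effort.countries)
        ranking = rank_country_models(tab)
        assert len(ranking.models) == 8
        frame = ranking.to_frame()
        assert {"predictors", "aicc", "delta_aicc", "competitive"} <= set(frame.columns)
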