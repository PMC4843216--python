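"""Binomial regressions of data-absence, with AICc all-subsets selection.

Two analyses share this machinery:

* per-cell, within each biogeographic realm: a Bernoulli (logit) GLM of
  data-absence against land cover (two dummies, forest as reference),
  protected-area overlap and mean human influence index;
* per-country: a grouped binomial GLM of the proportion of data-absent
  cells out of all surveyed cells against log GDP per capita, global peace
  index rank and English-official-language, with every predictor subset
  ranked by the small-sample AIC (AICc) and near-ties screened by a
  one-parameter nesting rule.

Model fitting is iteratively reweighted least squares via statsmodels;
selection, the nesting rule and the collinearity screen live here.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "GLMFit",
    "RankedModel",
    "ModelRanking",
    "fit_binomial_glm",
    "aicc",
    "rank_all_subsets",
    "apply_nesting_rule",
    "check_collinearity",
    "fit_realm_model",
    "rank_country_models",
]

#: IRLS convergence tolerance on the coefficient change
IRLS_TOL = 1e-8
IRLS_MAXITER = 100

#: |coefficient| beyond which a logit fit is treated as separated
SEPARATION_COEF = 15.0


@dataclass
class GLMFit:
    """A fitted binomial GLM (logit link)."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    n_obs: int
    k_params: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        terms = list(self.coefficients)
        est = np.array([self.coefficients[t] for t in terms])
        se = np.array([self.standard_errors[t] for t in terms])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        return pd.DataFrame({"term": terms, "estimate": est, "se": se, "z": z})


class RankDeficientError(ValueError):
    """The design matrix is not full rank."""


def _validate_design(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the offending columns: those whose removal restores full rank
        culprits = [
            c
            for c in design.columns
            if np.linalg.matrix_rank(design.drop(columns=c).to_numpy(dtype=float))
            == np.linalg.matrix_rank(x)
        ]
        raise RankDeficientError(f"collinear design columns: {culprits}")


def fit_binomial_glm(
    successes,
    trials,
    design: pd.DataFrame,
    add_intercept: bool = True,
) -> GLMFit:
    """Fit a (possibly grouped) binomial GLM with a logit link.

    ``successes``/``trials`` are per-unit counts (Bernoulli data is the
    ``trials = 1`` case).  The design must be full column rank; a degenerate
    response (no successes or no failures anywhere) or runaway coefficients
    mark the fit as not converged (separation).
    """
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if np.any(trials < 1):
        raise ValueError("every unit needs at least one trial")
    if np.any(successes < 0) or np.any(successes > trials):
        raise ValueError("successes must lie in [0, trials]")
    x = design.copy()
    if add_intercept:
        x.insert(0, "(Intercept)", 1.0)
    _validate_design(x)
    endog = np.column_stack([successes, trials - successes])
    model = sm.GLM(endog, x.to_numpy(dtype=float), family=sm.families.Binomial())
    converged = True
    try:
        res = model.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL)
        params, bse, llf = res.params, res.bse, float(res.llf)
        converged = bool(getattr(res, "converged", True))
    except Exception as exc:  # pragma: no cover - perfect separation paths
        logger.warning("GLM fit failed (%s); flagged not converged", exc)
        params = np.full(x.shape[1], np.nan)
        bse = np.full(x.shape[1], np.nan)
        llf = float("nan")
        converged = False
    if successes.sum() == 0 or (trials - successes).sum() == 0:
        converged = False  # degenerate response: MLE on the boundary
    if converged and np.nanmax(np.abs(params)) > SEPARATION_COEF:
        converged = False
    return GLMFit(
        coefficients=dict(zip(x.columns, map(float, params))),
        standard_errors=dict(zip(x.columns, map(float, bse))),
        log_likelihood=llf,
        n_obs=len(x),
        k_params=x.shape[1],
        converged=converged,
    )


def aicc(fit: GLMFit) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1); undefined when n ≤ k+1.
    """
    n, k = fit.n_obs, fit.k_params
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k+1)")
    return -2.0 * fit.log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class RankedModel:
    predictors: tuple[str, ...]
    fit: GLMFit
    aicc: float
    delta_aicc: float = float("nan")
    competitive: bool = False


@dataclass
class ModelRanking:
    models: list[RankedModel] = field(default_factory=list)
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    @property
    def best(self) -> RankedModel:
        return self.models[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictors": ["+".join(m.predictors) or "(null)" for m in self.models],
                "k": [m.fit.k_params for m in self.models],
                "log_lik": [m.fit.log_likelihood for m in self.models],
                "aicc": [m.aicc for m in self.models],
                "delta_aicc": [m.delta_aicc for m in self.models],
                "competitive": [m.competitive for m in self.models],
            }
        )


def rank_all_subsets(
    successes,
    trials,
    candidates: pd.DataFrame,
    delta_competitive: float = 2.0,
) -> ModelRanking:
    """Fit every predictor subset (incl. the intercept-only null), rank by AICc.

    Models within ``delta_competitive`` AICc units of the best are marked
    competitive.  Subsets whose fit fails are recorded with the reason and
    left out of the ranking.
    """
    names = list(candidates.columns)
    if len(names) > 12:
        raise ValueError("all-subsets enumeration capped at 12 candidates")
    ranking = ModelRanking()
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            try:
                fit = fit_binomial_glm(successes, trials, candidates[list(subset)])
                ranking.models.append(RankedModel(subset, fit, aicc(fit)))
            except (ValueError, RankDeficientError) as exc:
                ranking.failures.append((subset, str(exc)))
    if not ranking.models:
        raise ValueError("no candidate model could be fitted")
    ranking.models.sort(key=lambda m: m.aicc)
    best = ranking.models[0].aicc
    for m in ranking.models:
        m.delta_aicc = m.aicc - best
        m.competitive = m.delta_aicc <= delta_competitive
    return ranking


def apply_nesting_rule(ranking: ModelRanking, loglik_tol: float = 0.5) -> ModelRanking:
    """Demote competitive models that merely add/drop one uninformative term.

    A model nested with the best model (superset or subset) that differs by
    exactly one parameter and leaves the maximised log-likelihood essentially
    unchanged (|Δ logL| < ``loglik_tol``) is not treated as truly competing.
    """
    best = ranking.best
    best_set = set(best.predictors)
    for m in ranking.models[1:]:
        if not m.competitive:
            continue
        m_set = set(m.predictors)
        nested = best_set < m_set or m_set < best_set
        one_param = abs(len(m_set) - len(best_set)) == 1
        same_ll = abs(m.fit.log_likelihood - best.fit.log_likelihood) < loglik_tol
        if nested and one_param and same_ll:
            m.competitive = False
    return ranking


def check_collinearity(design: pd.DataFrame, r_threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise Pearson correlations among covariates, with flags.

    Returns one row per pair with ``r`` and ``flagged`` (|r| above the
    threshold, or either column constant).
    """
    cols = list(design.columns)
    constant = {c for c in cols if design[c].nunique(dropna=True) <= 1}
    rows = []
    for a, b in itertools.combinations(cols, 2):
        if a in constant or b in constant:
            rows.append((a, b, np.nan, True, "constant column"))
            continue
        r = float(np.corrcoef(design[a], design[b])[0, 1])
        rows.append((a, b, r, abs(r) > r_threshold, ""))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "flagged", "note"])


# --- the two concrete analyses -------------------------------------------


def _realm_design(joined: pd.DataFrame) -> pd.DataFrame:
    """Land-cover dummies (forest reference), PA flag and mean HII."""
    return pd.DataFrame(
        {
            "grassland_shrubland": joined["landcover"].eq("grassland_shrubland").astype(float),
            "anthrome": joined["landcover"].eq("anthrome").astype(float),
            "pa": joined["pa"].astype(float),
            "hii": joined["hii"].astype(float),
        },
        index=joined.index,
    )


def fit_realm_model(joined: pd.DataFrame, realm: str) -> GLMFit:
    """Bernoulli GLM of data-absence vs cell covariates within one realm."""
    sub = joined[joined["realm"] == realm]
    if sub.empty:
        raise ValueError(f"no recorded cells in realm {realm!r}")
    y = sub["status"].eq("data_absent").astype(float)
    return fit_binomial_glm(y, np.ones(len(sub)), _realm_design(sub))


def rank_country_models(
    country_table: pd.DataFrame,
    loglik_tol: float = 0.5,
) -> ModelRanking:
    """Grouped-binomial all-subsets ranking of country-level predictors.

    Response: data-absent cells out of surveyed cells per country;
    candidates: log GDP per capita, global peace index rank, and whether
    English is an official language.  AICc uses the number of countries as
    the sample size; the nesting rule is applied to the competitive set.
    """
    cand = pd.DataFrame(
        {
            "log_gdp_pc": country_table["log_gdp_pc"].astype(float),
            "gpi_rank": country_table["gpi_rank"].astype(float),
            "english_official": country_table["english_official"].astype(float),
        }
    )
    ranking = rank_all_subsets(
        country_table["n_data_absent"], country_table["n_surveyed"], cand
    )
    return apply_nesting_rule(ranking, loglik_tol)
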