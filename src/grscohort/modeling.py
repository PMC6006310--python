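"""Multivariable logistic modelling of AF status with clinical covariates + GRS.

Fits a maximum-likelihood logistic regression (via statsmodels) on
complete-case rows, reports per-term odds ratios with Wald 95% confidence
intervals, McFadden's pseudo-R² = 1 − ln(Lm)/ln(L0), the odds ratio for a
0.1-unit change in a continuous predictor such as the GRS, resubstitution
classification accuracy, and a single backward-selection step that keeps
the terms with Wald P < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "LogisticFit",
    "fit_logistic",
    "mcfadden_r2",
    "scaled_or",
    "classification_accuracy",
    "reduced_model",
    "predicted_probabilities",
    "model_frame",
]

INTERCEPT = "const"
Z_95 = 1.96


@dataclass
class LogisticFit:
    """A fitted logistic model and the data bookkeeping needed downstream."""

    terms: list[str]  # predictor labels, intercept excluded
    beta: pd.Series  # coefficients incl. intercept
    se: pd.Series
    pvalues: pd.Series
    ll_model: float
    ll_null: float
    converged: bool
    n_obs: int
    n_dropped_rows: int
    dropped_terms: list[str]
    fitted_prob: pd.Series  # resubstitution probabilities on rows used
    outcome_used: pd.Series
    design_used: pd.DataFrame
    diagnostic: str = ""

    def odds_ratio(self, term: str) -> float:
        return math.exp(self.beta[term])

    def wald_ci(self, term: str, z: float = Z_95) -> tuple[float, float]:
        b, s = self.beta[term], self.se[term]
        return math.exp(b - z * s), math.exp(b + z * s)


def _null_loglik(y: np.ndarray) -> float:
    """Intercept-only log-likelihood, in closed form: the MLE intercept fits
    the observed case fraction exactly."""
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / n
    return n1 * math.log(p) + n0 * math.log(1 - p)


def fit_logistic(design: pd.DataFrame, outcome: pd.Series) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome on a design frame.

    Rows with any missing predictor or outcome are dropped (complete case)
    and counted. Constant predictors are dropped with a warning. Perfect
    separation yields ``converged=False`` with NaN coefficients and a
    diagnostic, never silently huge estimates.
    """
    design = design.astype(float)
    outcome = outcome.astype(float)
    joined = design.join(outcome.rename("__y__"), how="inner")
    complete = joined.dropna()
    n_dropped = len(joined) - len(complete)
    y = complete["__y__"]
    X = complete.drop(columns="__y__")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome must contain at least one case and one control")

    dropped_terms = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped_terms:
        warnings.warn(f"dropping constant predictors: {dropped_terms}")
        X = X.drop(columns=dropped_terms)
    terms = list(X.columns)
    Xc = sm.add_constant(X, has_constant="add")
    ll_null = _null_loglik(y.to_numpy())

    def _failed(msg: str) -> LogisticFit:
        nan = pd.Series(np.nan, index=[INTERCEPT] + terms)
        return LogisticFit(
            terms=terms,
            beta=nan,
            se=nan.copy(),
            pvalues=nan.copy(),
            ll_model=math.nan,
            ll_null=ll_null,
            converged=False,
            n_obs=len(y),
            n_dropped_rows=n_dropped,
            dropped_terms=dropped_terms,
            fitted_prob=pd.Series(np.nan, index=y.index),
            outcome_used=y,
            design_used=X,
            diagnostic=msg,
        )

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        return _failed(f"perfect separation detected: {exc}")
    except np.linalg.LinAlgError as exc:
        return _failed(f"singular design: {exc}")
    if not res.mle_retvals.get("converged", False):
        return _failed("optimizer failed to converge")

    beta = res.params.rename({"const": INTERCEPT})
    return LogisticFit(
        terms=terms,
        beta=beta,
        se=res.bse.rename({"const": INTERCEPT}),
        pvalues=res.pvalues.rename({"const": INTERCEPT}),
        ll_model=float(res.llf),
        ll_null=ll_null,
        converged=True,
        n_obs=len(y),
        n_dropped_rows=n_dropped,
        dropped_terms=dropped_terms,
        fitted_prob=pd.Series(res.predict(Xc), index=y.index),
        outcome_used=y,
        design_used=X,
    )


def mcfadden_r2(fit: LogisticFit) -> float:
    """McFadden pseudo-R²: 1 − ln(Lm)/ln(L0).

    L0 is the likelihood of the intercept-only model, Lm of the fitted one;
    an intercept-only fit returns exactly 0. Undefined when every sample has
    the same outcome (L0 = 1)."""
    if not fit.converged:
        raise ValueError("McFadden R² requires a converged fit")
    if fit.ll_null == 0:
        raise ValueError("null log-likelihood is zero (constant outcome)")
    if not fit.terms:
        return 0.0
    return 1.0 - fit.ll_model / fit.ll_null


def scaled_or(
    fit: LogisticFit, term: str, delta: float = 0.1
) -> tuple[float, tuple[float, float]]:
    """Odds ratio for a ``delta``-unit change in a predictor, with Wald CI.

    exp(delta·beta) and exp(delta·(beta ± 1.96·se)); delta = 1 reproduces
    the ordinary per-unit OR. Used to present the per-0.1-unit GRS effect.
    """
    if term not in fit.beta.index:
        raise KeyError(f"term {term!r} not in fitted model")
    b, s = fit.beta[term], fit.se[term]
    return (
        math.exp(delta * b),
        (math.exp(delta * (b - Z_95 * s)), math.exp(delta * (b + Z_95 * s))),
    )


def predicted_probabilities(fit: LogisticFit, design: pd.DataFrame) -> pd.Series:
    """Predicted case probabilities for new rows under the fitted model."""
    X = design[fit.terms].astype(float)
    lp = fit.beta[INTERCEPT] + X.to_numpy() @ fit.beta[fit.terms].to_numpy()
    return pd.Series(1.0 / (1.0 + np.exp(-lp)), index=design.index)


def classification_accuracy(
    fit: LogisticFit,
    design: Optional[pd.DataFrame] = None,
    outcome: Optional[pd.Series] = None,
    threshold: float = 0.5,
) -> float:
    """Fraction of samples correctly classified at the probability threshold.

    With no arguments this is resubstitution accuracy on the fitted rows.
    A probability exactly at the threshold is classified as a case.
    """
    if not fit.converged:
        raise ValueError("classification requires a converged fit")
    if design is None:
        prob, y = fit.fitted_prob, fit.outcome_used
    else:
        if outcome is None:
            raise ValueError("outcome is required when a design is supplied")
        prob = predicted_probabilities(fit, design)
        y = outcome.astype(float)
    predicted = (prob >= threshold).astype(float)
    return float((predicted == y).mean())


def reduced_model(
    fit: LogisticFit,
    alpha: float = 0.05,
) -> LogisticFit:
    """Single backward step: refit keeping only terms with Wald P < alpha.

    The refit uses the same rows as the full model, so the reduced model's
    log-likelihood (and hence McFadden R²) can be compared directly. If no
    term survives, the intercept-only model is returned.
    """
    if not fit.converged:
        raise ValueError("cannot reduce a non-converged fit")
    kept = [t for t in fit.terms if fit.pvalues[t] < alpha]
    return fit_logistic(fit.design_used[kept], fit.outcome_used)


def model_frame(fit: LogisticFit, *, grs_term: str = "grs", delta: float = 0.1) -> pd.DataFrame:
    """Report table: per-term OR (95% CI) and P, GRS shown per 0.1 unit."""
    rows = []
    for term in fit.terms:
        if term == grs_term and fit.converged:
            or_, (lo, hi) = scaled_or(fit, term, delta)
            label = f"{term} (per {delta} unit)"
        elif fit.converged:
            or_ = fit.odds_ratio(term)
            lo, hi = fit.wald_ci(term)
            label = term
        else:
            or_, lo, hi, label = math.nan, math.nan, math.nan, term
        rows.append(
            {
                "term": label,
                "or": round(or_, 2) if math.isfinite(or_) else math.nan,
                "ci_low": round(lo, 2) if math.isfinite(lo) else math.nan,
                "ci_high": round(hi, 2) if math.isfinite(hi) else math.nan,
                "p": float(f"{fit.pvalues[term]:.3g}") if fit.converged else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["term", "or", "ci_low", "ci_high", "p"])
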