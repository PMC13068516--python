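"""Exploratory logistic regression of judgment inconsistency on covariates.

The dependent variable is the dichotomized individual consistency verdict
(CR > 0.2 at a given hierarchy level); covariates are VAS utility, gender,
age, treatment duration and treatment scheme.  Because the reference
coding of the categorical covariates in the source analysis is unknown,
the coding-invariant fit summaries (-2 log-likelihood, Cox-Snell and
Nagelkerke pseudo-R-squared, omnibus likelihood-ratio test) are the
reproduction targets; odds ratios are reported for display.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import ParticipantRecord

__all__ = [
    "CovariateEffect",
    "LogisticFit",
    "covariate_frame",
    "fit_logistic",
    "vif",
]

#: IRLS stopping rule: change in deviance below this is convergence.
DEVIANCE_TOL = 1e-8
MAX_IRLS_ITERATIONS = 50


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    coefficient: float
    std_error: float
    wald_p: float
    odds_ratio: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with coding-invariant summaries."""

    outcome: str
    n: int
    effects: tuple[CovariateEffect, ...]
    intercept: CovariateEffect
    minus_two_log_likelihood: float
    cox_snell_r2: float
    nagelkerke_r2: float
    omnibus_chi2: float
    omnibus_df: int
    omnibus_p: float
    converged: bool
    separation_suspected: bool
    small_sample_warning: bool

    def summary(self) -> pd.DataFrame:
        """Per-covariate table in the conventional reporting layout."""
        rows = [
            {
                "variable": e.name,
                "coefficient": e.coefficient,
                "se": e.std_error,
                "p": e.wald_p,
                "odds_ratio": e.odds_ratio,
                "ci95_low": e.ci_low,
                "ci95_high": e.ci_high,
            }
            for e in (*self.effects, self.intercept)
        ]
        return pd.DataFrame(rows).set_index("variable")


def covariate_frame(
    participants: Sequence[ParticipantRecord],
) -> pd.DataFrame:
    """Design covariates: VAS, male indicator, age, duration, combination
    indicator — unstandardized, indexed by participant id."""
    return pd.DataFrame(
        {
            "vas": [p.vas for p in participants],
            "gender": [1.0 if p.gender == "m" else 0.0
                       for p in participants],
            "age": [p.age for p in participants],
            "duration": [p.duration_years for p in participants],
            "scheme": [1.0 if p.scheme == "combi" else 0.0
                       for p in participants],
        },
        index=pd.Index([p.id for p in participants], name="id"),
    )


def fit_logistic(
    outcome: Sequence[int] | np.ndarray,
    covariates: pd.DataFrame,
    outcome_name: str = "inconsistent",
) -> LogisticFit:
    """Fit a binary logistic model by IRLS and report invariant summaries.

    ``outcome`` must contain both classes.  Nagelkerke R-squared rescales
    Cox-Snell by its maximum ``1 - L0**(2/n)``; the omnibus test is the
    likelihood-ratio chi-square against the intercept-only model with one
    degree of freedom per covariate.  Quasi-separation is reported through
    ``separation_suspected`` rather than raised, since exploratory fits on
    small samples should surface, not hide, such geometry.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit "
                         "undefined")
    n, k = covariates.shape
    if len(y) != n:
        raise ValueError("outcome and covariates disagree in length")
    if n <= k + 1:
        raise ValueError("fewer observations than parameters")

    x = sm.add_constant(covariates.astype(float), prepend=False)
    model = sm.GLM(y, x, family=sm.families.Binomial())
    result = model.fit(maxiter=MAX_IRLS_ITERATIONS, tol=DEVIANCE_TOL)
    null_result = sm.GLM(
        y, np.ones((n, 1)), family=sm.families.Binomial()
    ).fit()

    llf = float(result.llf)
    ll0 = float(null_result.llf)
    chi2 = max(2.0 * (llf - ll0), 0.0)
    cox_snell = 1.0 - float(np.exp(-chi2 / n))
    max_cox_snell = 1.0 - float(np.exp(2.0 * ll0 / n))
    nagelkerke = cox_snell / max_cox_snell if max_cox_snell > 0 else 0.0

    params = result.params
    ses = result.bse
    pvals = result.pvalues

    def _effect(name: str) -> CovariateEffect:
        b, se, p = float(params[name]), float(ses[name]), float(pvals[name])
        with np.errstate(over="ignore"):  # separation: CI bound may be inf
            return CovariateEffect(
                name=name,
                coefficient=b,
                std_error=se,
                wald_p=p,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - 1.96 * se)),
                ci_high=float(np.exp(b + 1.96 * se)),
            )

    converged = bool(getattr(result, "converged", True))
    separation = bool(
        np.any(np.abs(params.to_numpy()) > 30)
        or np.any(ses.to_numpy() > 1e3)
        or not converged
    )
    return LogisticFit(
        outcome=outcome_name,
        n=n,
        effects=tuple(_effect(c) for c in covariates.columns),
        intercept=_effect("const"),
        minus_two_log_likelihood=-2.0 * llf,
        cox_snell_r2=cox_snell,
        nagelkerke_r2=nagelkerke,
        omnibus_chi2=chi2,
        omnibus_df=k,
        omnibus_p=float(stats.chi2.sf(chi2, k)),
        converged=converged,
        separation_suspected=separation,
        small_sample_warning=n < 10 * k,
    )


def vif(covariates: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors: ``1 / (1 - R2_j)`` from regressing each
    covariate on the others (with intercept).

    Perfect collinearity is reported as ``inf``, not raised.  Categorical
    covariates must already be encoded as 0/1 indicators.
    """
    from statsmodels.stats.outliers_influence import (
        variance_inflation_factor,
    )

    if covariates.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    x = covariates.astype(float)
    if np.any(x.to_numpy().std(axis=0) == 0):
        raise ValueError("constant covariate column; VIF undefined")
    exog = sm.add_constant(x, prepend=False).to_numpy()
    out: dict[str, float] = {}
    with np.errstate(divide="ignore"):
        for j, name in enumerate(covariates.columns):
            value = float(variance_inflation_factor(exog, j))
            # numerically huge VIFs from an exactly collinear column are
            # reported as infinite
            out[name] = float("inf") if value > 1e12 else value
    return out
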