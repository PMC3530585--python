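"""OLS estimation on the logit scale, backward stepwise AIC and diagnostics.

The probability model is linear after the transform y = log((1-P_LS)/P_LS),
so parameters are estimated by ordinary least squares on that scale (bud
counts are not observed, so a binomial GLM with proper weights is not an
option).  Model selection runs backward from the full term set
{PI, LW1, PIxLW1} dropping one term at a time by AIC, with no marginality
constraint: the interaction may survive while the PI main effect is dropped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.stats.diagnostic import het_breuschpagan

from .exceptions import SingularDesignError, UndefinedRSquaredError
from .model import TERMS, ModelParameters, logit_linearize

__all__ = [
    "LinearizedFit",
    "StepwiseResult",
    "DiagnosticsReport",
    "fit_model",
    "gaussian_aic",
    "stepwise_backward_aic",
    "r_squared",
    "pls_scale_r_squared",
    "residual_diagnostics",
]

logger = logging.getLogger(__name__)

_AIC_TIE_TOL = 1e-9


@dataclass(frozen=True)
class LinearizedFit:
    """OLS result on the logit scale."""

    params: ModelParameters
    terms: tuple[str, ...]
    n: int
    rss: float
    aic: float
    r2: float
    residuals: np.ndarray
    fitted: np.ndarray

    def to_dict(self) -> dict:
        coef = {"log_a": self.params.log_a}
        for name in ("b", "c", "e"):
            v = getattr(self.params, name)
            if v is not None:
                coef[name] = v
        return {
            "terms": list(self.terms),
            "coefficients": coef,
            "rss": self.rss,
            "aic": self.aic,
            "r2": self.r2,
            "n": self.n,
        }


@dataclass(frozen=True)
class StepwiseResult:
    """Selected fit plus the deletion trace (one entry per examined step)."""

    fit: LinearizedFit
    trace: tuple[dict, ...] = field(default_factory=tuple)


def gaussian_aic(n: int, rss: float, n_coefficients: int) -> float:
    """AIC under Gaussian errors: n*log(rss/n) + 2*(p + 1).

    ``n_coefficients`` counts intercept plus slope terms; the +1 counts the
    error variance.  Additive constants are omitted, so values are comparable
    only across fits of the same response.  A perfect fit (rss = 0) returns
    -inf with a warning.
    """
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0.0:
        warnings.warn("rss = 0 (perfect fit): AIC is -inf", stacklevel=2)
        return -math.inf
    return n * math.log(rss / n) + 2 * (n_coefficients + 1)


def _canonical(terms: Iterable[str]) -> tuple[str, ...]:
    terms = set(terms)
    unknown = terms - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    return tuple(t for t in TERMS if t in terms)


def fit_model(records: Iterable, terms: Iterable[str] = TERMS) -> LinearizedFit:
    """Fit the linearized model by OLS with the given slope terms.

    The intercept is always included and maps to log_a; slope coefficients
    map to b (PI), c (LW1) and e (PIxLW1).
    """
    records = list(records)
    terms = _canonical(terms)
    X, y = logit_linearize(records, terms)
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(
            f"need more observations ({n}) than coefficients ({p})"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularDesignError(f"design matrix for terms {terms} is rank deficient")
    res = sm.OLS(y, X).fit()
    coef = dict(zip(("PI", "LW1", "PIxLW1"), [None] * 3))
    for name, value in zip(terms, res.params[1:]):
        coef[name] = float(value)
    params = ModelParameters(
        log_a=float(res.params[0]), b=coef["PI"], c=coef["LW1"], e=coef["PIxLW1"]
    )
    rss = float(res.ssr)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aic = gaussian_aic(n, rss, p)
    return LinearizedFit(
        params=params,
        terms=terms,
        n=n,
        rss=rss,
        aic=aic,
        r2=r2,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


def stepwise_backward_aic(records: Iterable) -> StepwiseResult:
    """Backward stepwise AIC selection from the full term set.

    At each step the single term whose removal lowers AIC the most is
    dropped; selection stops when no removal lowers AIC.  The intercept is
    never dropped.  Ties within 1e-9 are broken by dropping the interaction
    last (simpler main-effect structure preferred), with deterministic order
    PI, LW1, PIxLW1 otherwise.
    """
    records = list(records)
    current = fit_model(records, TERMS)
    trace: list[dict] = []
    # tie-break order: interaction dropped last
    drop_priority = {"PI": 0, "LW1": 1, "PIxLW1": 2}
    while current.terms:
        candidates = {}
        for term in current.terms:
            reduced = tuple(t for t in current.terms if t != term)
            candidates[term] = fit_model(records, reduced)
        best_term = min(
            candidates,
            key=lambda t: (candidates[t].aic, drop_priority[t]),
        )
        step = {
            "terms": current.terms,
            "aic": current.aic,
            "candidate_aics": {t: f.aic for t, f in candidates.items()},
        }
        if candidates[best_term].aic < current.aic - _AIC_TIE_TOL:
            step["dropped"] = best_term
            trace.append(step)
            logger.info(
                "stepwise: dropped %s (AIC %.4f -> %.4f)",
                best_term,
                current.aic,
                candidates[best_term].aic,
            )
            current = candidates[best_term]
        else:
            step["dropped"] = None
            trace.append(step)
            break
    logger.info("stepwise: selected terms %s (AIC %.4f)", current.terms, current.aic)
    return StepwiseResult(fit=current, trace=tuple(trace))


def r_squared(fit: LinearizedFit) -> float:
    """Coefficient of determination on the logit scale, 1 - rss/tss."""
    if fit.n < 2:
        raise UndefinedRSquaredError("r2 needs at least 2 observations")
    if math.isnan(fit.r2):
        raise UndefinedRSquaredError("response has zero total sum of squares")
    return fit.r2


def pls_scale_r_squared(fit: LinearizedFit) -> float:
    """R^2 after back-transforming fitted values to the probability scale.

    Reported alongside the logit-scale value because variance explained on
    the two scales can differ for skewed proportions.
    """
    y_obs = fit.fitted + fit.residuals
    p_obs = expit(-y_obs)  # y = log((1-P)/P)  =>  P = expit(-y)
    p_hat = expit(-fit.fitted)
    tss = float(((p_obs - p_obs.mean()) ** 2).sum())
    if tss == 0:
        raise UndefinedRSquaredError("observed P_LS has zero variance")
    return 1.0 - float(((p_obs - p_hat) ** 2).sum()) / tss


@dataclass(frozen=True)
class DiagnosticsReport:
    """Advisory residual checks; never gates the pipeline."""

    normality_stat: float
    normality_pvalue: float
    normality_ok: bool
    heteroscedasticity_stat: float
    heteroscedasticity_pvalue: float
    homoscedasticity_ok: bool
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "normality": {
                "stat": self.normality_stat,
                "pvalue": self.normality_pvalue,
                "ok": self.normality_ok,
            },
            "heteroscedasticity": {
                "stat": self.heteroscedasticity_stat,
                "pvalue": self.heteroscedasticity_pvalue,
                "ok": self.homoscedasticity_ok,
            },
            "alpha": self.alpha,
        }


def residual_diagnostics(fit: LinearizedFit, alpha: float = 0.05) -> DiagnosticsReport:
    """Normality (Shapiro-Wilk) and heteroscedasticity checks on residuals.

    The heteroscedasticity check is the Breusch-Pagan LM statistic from the
    auxiliary regression of squared residuals on the fitted values.  Both are
    advisory: the report carries pass flags at ``alpha`` but nothing is
    raised on failure.
    """
    if fit.n < 8:
        raise ValueError("diagnostics need at least 8 residuals")
    w_stat, w_p = stats.shapiro(fit.residuals)
    exog = sm.add_constant(fit.fitted)
    lm_stat, lm_p, _, _ = het_breuschpagan(fit.residuals, exog)
    return DiagnosticsReport(
        normality_stat=float(w_stat),
        normality_pvalue=float(w_p),
        normality_ok=bool(w_p >= alpha),
        heteroscedasticity_stat=float(lm_stat),
        heteroscedasticity_pvalue=float(lm_p),
        homoscedasticity_ok=bool(lm_p >= alpha),
        alpha=alpha,
    )
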