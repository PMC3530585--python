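"""Bud-fate probability model and its analytic properties.

The probability that a peach-tree bud develops into a long shoot is modelled
as a logistic function of winter pruning intensity PI (fraction of 1-yr-old
wood removed), previous-season growth L_W1 (total length of 1-yr-old wood
before pruning, in meters) and their interaction::

    P_LS = 1 / (1 + a * exp(b*PI + c*L_W1 + e*PI*L_W1)),   a = exp(log_a)

so that 1/(1+a) is the baseline long-shoot probability and b, c, e scale the
covariate effects.  With the sign convention above and estimates c > 0,
e < 0, P_LS increases monotonically with PI, and the effect of L_W1 on P_LS
changes sign at the critical pruning intensity PI* = -c/e.

Linearization for fitting: taking y = log((1 - P_LS)/P_LS) turns the model
into an ordinary linear regression y = log_a + b*PI + c*L_W1 + e*PI*L_W1, so
OLS coefficients estimate (log_a, b, c, e) directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from .exceptions import TransformError, UndefinedCriticalValueError

__all__ = [
    "TERMS",
    "ModelParameters",
    "REFERENCE_PARAMS",
    "predict_pls",
    "logit_linearize",
    "critical_pruning_intensity",
    "dpls_dpi_sign",
    "dpls_dlw1_sign",
]

#: Canonical term order: pruning intensity, 1-yr-old wood length, interaction.
TERMS = ("PI", "LW1", "PIxLW1")

#: Tolerance below which a derivative is reported as exactly zero.
_SIGN_TOL = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """Coefficients of the long-shoot probability model.

    A coefficient set to ``None`` means the corresponding term is excluded
    from the model (it contributes nothing to the exponent).

    Parameters
    ----------
    log_a
        Intercept on the linearized (logit) scale; ``a = exp(log_a)``.
    b
        Coefficient of PI (dimensionless), or None.
    c
        Coefficient of L_W1 (per meter), or None.
    e
        Coefficient of the PI x L_W1 interaction (per meter), or None.
    """

    log_a: float
    b: float | None = None
    c: float | None = None
    e: float | None = None

    def __post_init__(self) -> None:
        for name in ("log_a", "b", "c", "e"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")

    @property
    def a(self) -> float:
        """Baseline odds multiplier, a = exp(log_a) > 0."""
        return math.exp(self.log_a)

    @property
    def included_terms(self) -> frozenset[str]:
        present = []
        if self.b is not None:
            present.append("PI")
        if self.c is not None:
            present.append("LW1")
        if self.e is not None:
            present.append("PIxLW1")
        return frozenset(present)

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_a": self.log_a,
                "b": self.b,
                "c": self.c,
                "e": self.e,
                "included_terms": sorted(self.included_terms, key=TERMS.index),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "ModelParameters":
        obj = json.loads(payload)
        params = cls(
            log_a=obj["log_a"], b=obj.get("b"), c=obj.get("c"), e=obj.get("e")
        )
        declared = frozenset(obj.get("included_terms", params.included_terms))
        if declared != params.included_terms:
            raise ValueError(
                "included_terms inconsistent with present coefficients: "
                f"{sorted(declared)} vs {sorted(params.included_terms)}"
            )
        return params


#: Published calibration for the cv Suncrest/GF677 peach orchard study the
#: bundled dataset comes from: bootstrap means of (log a, c, e) for the
#: selected model {L_W1, PI x L_W1}.
REFERENCE_PARAMS = ModelParameters(log_a=1.01, c=7.85e-3, e=-1.51e-2)


def _eta(params: ModelParameters, lw1, pi):
    """Exponent b*PI + c*L_W1 + e*PI*L_W1 with absent terms contributing 0."""
    eta = np.zeros(np.broadcast(lw1, pi).shape)
    if params.b is not None:
        eta = eta + params.b * pi
    if params.c is not None:
        eta = eta + params.c * lw1
    if params.e is not None:
        eta = eta + params.e * pi * lw1
    return eta


def predict_pls(params: ModelParameters, lw1, pi):
    """Probability of a bud developing into a long shoot.

    Accepts scalars or numpy arrays for ``lw1`` (meters, >= 0) and ``pi``
    (fraction in [0, 1]); broadcasting follows numpy rules.  Returns values
    strictly inside (0, 1).
    """
    lw1 = np.asarray(lw1, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if not (np.all(np.isfinite(lw1)) and np.all(np.isfinite(pi))):
        raise ValueError("lw1 and pi must be finite")
    if np.any(lw1 < 0):
        raise ValueError("lw1 must be >= 0")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    # 1/(1 + a*exp(eta)) == expit(-(log_a + eta)), numerically stable.
    out = expit(-(params.log_a + _eta(params, lw1, pi)))
    return float(out) if out.ndim == 0 else out


def logit_linearize(
    records: Iterable, terms: Sequence[str] = TERMS
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response for OLS on the linearized scale.

    Response is y = log((1 - P_LS)/P_LS); the design always carries an
    intercept column followed by the requested terms in canonical order
    (PI, LW1, PIxLW1).  Records with P_LS exactly 0 or 1 cannot be
    transformed and raise :class:`TransformError`.
    """
    records = list(records)
    unknown = set(terms) - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms: {sorted(unknown)}")
    pls = np.array([r.pls for r in records], dtype=float)
    bad = np.nonzero((pls <= 0.0) | (pls >= 1.0))[0]
    if bad.size:
        labels = [f"(tree {records[i].tree_id}, year {records[i].year})" for i in bad]
        raise TransformError(
            "P_LS must lie strictly in (0, 1) for the logit transform; "
            "offending records: " + ", ".join(labels)
        )
    lw1 = np.array([r.lw1 for r in records], dtype=float)
    pi = np.array([r.pi for r in records], dtype=float)
    y = np.log((1.0 - pls) / pls)
    columns = [np.ones_like(y)]
    term_cols = {"PI": pi, "LW1": lw1, "PIxLW1": pi * lw1}
    for t in TERMS:
        if t in terms:
            columns.append(term_cols[t])
    return np.column_stack(columns), y


def critical_pruning_intensity(params: ModelParameters) -> float:
    """Critical pruning intensity PI* = -c/e.

    Below PI* the long-shoot probability decreases with L_W1; above it, the
    probability increases with L_W1 (for c > 0, e < 0).
    """
    if params.c is None or params.e is None or params.e == 0.0:
        raise UndefinedCriticalValueError(
            "PI* = -c/e requires both c and a nonzero interaction coefficient e"
        )
    return -params.c / params.e


def _sign(x: float) -> int:
    if abs(x) <= _SIGN_TOL:
        return 0
    return 1 if x > 0 else -1


def dpls_dpi_sign(params: ModelParameters, lw1: float) -> int:
    """Sign of dP_LS/dPI at 1-yr-old wood length ``lw1``.

    P_LS is decreasing in the exponent, so the sign is that of
    ``-(b + e*lw1)``; returned symbolically (not by finite differences),
    with |.| <= 1e-9 reported as 0.
    """
    if not math.isfinite(lw1) or lw1 < 0:
        raise ValueError("lw1 must be finite and >= 0")
    slope = (params.b or 0.0) + (params.e or 0.0) * lw1
    return _sign(-slope)


def dpls_dlw1_sign(params: ModelParameters, pi: float) -> int:
    """Sign of dP_LS/dL_W1 at pruning intensity ``pi``; sign of -(c + e*pi)."""
    if not math.isfinite(pi) or not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    slope = (params.c or 0.0) + (params.e or 0.0) * pi
    return _sign(-slope)
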