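"""Nonparametric case bootstrap of the selected model's parameters.

Each replicate resamples whole tree-year rows with replacement (the 2005 and
2006 observations are pooled; no blocking by tree) and refits the model with
the term set held fixed — selection is not re-run per replicate, because the
uncertainty of interest is that of the selected model's coefficients.

Reproducibility: replicate ``r`` of a run seeded with ``seed`` draws its row
indices from ``numpy.random.default_rng([seed, r])``, so any single
replicate can be regenerated in isolation and a full run is bit-identical
for a given (seed, n_reps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .fitting import _canonical
from .model import logit_linearize

__all__ = ["BootstrapSummary", "bootstrap_parameters"]

logger = logging.getLogger(__name__)

_PARAM_NAMES = {"PI": "b", "LW1": "c", "PIxLW1": "e"}
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapSummary:
    """Replicate coefficient distribution and its summaries.

    ``replicates`` holds one row per retained replicate, with columns
    ``log_a`` plus the slope coefficients of the fixed term set.
    ``statistics`` indexes parameters and carries mean/sd/median/q05/q95
    (quantiles by linear interpolation of order statistics).
    ``correlations`` is the Pearson matrix of the replicate columns.
    """

    n_reps: int
    seed: int
    terms: tuple[str, ...]
    replicates: pd.DataFrame
    statistics: pd.DataFrame
    correlations: pd.DataFrame
    n_discarded: int

    @property
    def a_scale_correlations(self) -> pd.DataFrame:
        """Correlations with the intercept on the a = exp(log_a) scale."""
        reps = self.replicates.copy()
        reps["a"] = np.exp(reps.pop("log_a"))
        return reps.corr()

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "seed": self.seed,
            "terms": list(self.terms),
            "n_discarded": self.n_discarded,
            "statistics": {
                p: self.statistics.loc[p].to_dict() for p in self.statistics.index
            },
            "correlations": {
                p: self.correlations.loc[p].to_dict() for p in self.correlations.index
            },
        }


def bootstrap_parameters(
    records: Iterable,
    terms: Iterable[str],
    n_reps: int = 10_000,
    seed: int = 0,
) -> BootstrapSummary:
    """Case bootstrap of the OLS coefficients with a fixed term set.

    Resamples the n rows with replacement ``n_reps`` times, refits each
    replicate and summarises the coefficient distribution.  Replicates whose
    resampled design is rank deficient are discarded and redrawn (from a
    fresh child stream); more than 1% such replicates raises
    :class:`DegenerateDataError`.
    """
    records = list(records)
    terms = _canonical(terms)
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    X, y = logit_linearize(records, terms)
    n, p = X.shape
    names = ["log_a"] + [_PARAM_NAMES[t] for t in terms]

    out = np.empty((n_reps, p))
    n_discarded = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        for _ in range(_MAX_REDRAWS):
            idx = rng.integers(0, n, n)
            coefs, _, rank, _ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            if rank == p:
                out[r] = coefs
                break
            n_discarded += 1
            logger.debug("replicate %d rank-deficient; redrawing", r)
        else:  # pragma: no cover - requires pathological data
            raise DegenerateDataError(f"replicate {r}: no full-rank resample found")
    if n_discarded > 0.01 * n_reps:
        raise DegenerateDataError(
            f"{n_discarded} rank-deficient resamples out of {n_reps} (> 1%)"
        )

    reps = pd.DataFrame(out, columns=names)
    stats = pd.DataFrame(
        {
            "mean": reps.mean(),
            "sd": reps.std(ddof=1),
            "median": reps.quantile(0.5),
            "q05": reps.quantile(0.05),
            "q95": reps.quantile(0.95),
        }
    )
    return BootstrapSummary(
        n_reps=n_reps,
        seed=seed,
        terms=terms,
        replicates=reps,
        statistics=stats,
        correlations=reps.corr(),
        n_discarded=n_discarded,
    )
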