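"""Synthetic tree-year data with the statistical structure the model assumes.

Covariates are drawn uniformly over the spans observed in the bundled
orchard data (L_W1 in 100-360 m, PI in 0-0.8) and the long-shoot fraction is
generated from the probability model under one of two error mechanisms:

* ``LogitNormalNoise(sd)`` — Gaussian noise on the logit scale, matching the
  assumption of the OLS-on-logit estimator; used for recovery guarantees.
* ``BinomialNoise(ns)`` — the fraction is x/n_buds with x ~ Binomial(n_buds,
  p) and n_buds = round(ns * (1 - PI) * L_W1) buds on the wood left after
  pruning; matches the count-based biology and is used for robustness
  checks.  The empirical-logit adjustment (x + 0.5)/(n_buds + 1) keeps the
  observed fraction strictly inside (0, 1).

No tree/year correlation structure is simulated — the analysis pools rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_parameters
from .dataset import TreeYearRecord
from .fitting import fit_model, stepwise_backward_aic
from .model import ModelParameters, predict_pls
from .prediction import DEFAULT_SHOOTS_PER_METER

__all__ = [
    "LogitNormalNoise",
    "BinomialNoise",
    "SyntheticConfig",
    "generate",
    "recovery_experiment",
    "RecoveryReport",
]


@dataclass(frozen=True)
class LogitNormalNoise:
    """Gaussian noise of standard deviation ``sd`` on the logit scale."""

    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class BinomialNoise:
    """Binomial bud-count sampling with ``ns`` shoots per meter of wood."""

    ns: float = DEFAULT_SHOOTS_PER_METER

    def __post_init__(self) -> None:
        if not self.ns > 0:
            raise ValueError("ns must be > 0")


NoiseModel = Union[LogitNormalNoise, BinomialNoise]


@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for one synthetic dataset."""

    true_params: ModelParameters
    n_records: int
    noise: NoiseModel
    lw1_range: tuple[float, float] = (100.0, 360.0)
    pi_range: tuple[float, float] = (0.0, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 4:
            raise ValueError("n_records must be >= 4")
        lo, hi = self.lw1_range
        if not (0 < lo < hi):
            raise ValueError("lw1_range must be ordered and positive")
        lo, hi = self.pi_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("pi_range must be ordered within [0, 1]")


def _observe(rng: np.random.Generator, noise: NoiseModel, p: float, lw1: float, pi: float):
    """One noisy P_LS observation, or None if the record must be redrawn."""
    if isinstance(noise, LogitNormalNoise):
        if noise.sd == 0:
            return p
        logit = np.log(p / (1 - p)) + rng.normal(0.0, noise.sd)
        return 1.0 / (1.0 + np.exp(-logit))
    n_buds = int(round(noise.ns * (1.0 - pi) * lw1))
    if n_buds == 0:
        return None
    x = rng.binomial(n_buds, p)
    return (x + 0.5) / (n_buds + 1)


def generate(config: SyntheticConfig) -> list[TreeYearRecord]:
    """Draw ``n_records`` synthetic tree-year records.

    Covariates are uniform over the configured ranges; P_LS comes from the
    true model plus the configured noise.  Records whose binomial bud count
    rounds to zero are redrawn.  Fixed seed implies an identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_records):
        while True:
            lw1 = rng.uniform(*config.lw1_range)
            pi = rng.uniform(*config.pi_range)
            p = predict_pls(config.true_params, lw1, pi)
            pls = _observe(rng, config.noise, p, lw1, pi)
            if pls is not None and 0 < pls < 1:
                break
        records.append(TreeYearRecord(tree_id=i + 1, year=1, lw1=lw1, pi=pi, pls=float(pls)))
    return records


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery summary over repeated synthetic datasets."""

    n_datasets: int
    truth: ModelParameters
    bias: pd.Series
    relative_bias: pd.Series
    rmse: pd.Series
    selection_frequency: dict[tuple[str, ...], float]
    coverage: pd.Series = field(default=None)
    estimates: pd.DataFrame = field(default=None)


def recovery_experiment(
    config: SyntheticConfig,
    n_datasets: int,
    bootstrap_reps: int = 0,
) -> RecoveryReport:
    """Estimate bias/RMSE and term-selection frequencies by simulation.

    Each dataset is generated from ``config`` (seeded as [config.seed, k]),
    run through backward stepwise selection, and refit with the true term
    set to measure parameter recovery.  When ``bootstrap_reps`` > 0 a
    reduced-rep case bootstrap per dataset records whether the [q05, q95]
    interval covers the truth.
    """
    truth = config.true_params
    names = ["log_a"] + [
        n for n, v in (("b", truth.b), ("c", truth.c), ("e", truth.e)) if v is not None
    ]
    true_values = pd.Series(
        {"log_a": truth.log_a, "b": truth.b, "c": truth.c, "e": truth.e}
    )[names]
    true_terms = tuple(
        t for t, v in (("PI", truth.b), ("LW1", truth.c), ("PIxLW1", truth.e))
        if v is not None
    )

    rows, selections, covered = [], [], []
    for k in range(n_datasets):
        seed_k = np.random.default_rng([config.seed, k]).integers(2**31)
        data = generate(
            SyntheticConfig(
                true_params=truth,
                n_records=config.n_records,
                noise=config.noise,
                lw1_range=config.lw1_range,
                pi_range=config.pi_range,
                seed=int(seed_k),
            )
        )
        selections.append(stepwise_backward_aic(data).fit.terms)
        fit = fit_model(data, true_terms)
        est = {"log_a": fit.params.log_a, "b": fit.params.b, "c": fit.params.c,
               "e": fit.params.e}
        rows.append({n: est[n] for n in names})
        if bootstrap_reps > 0:
            bs = bootstrap_parameters(
                data, true_terms, n_reps=bootstrap_reps, seed=int(seed_k)
            )
            covered.append(
                {
                    n: bool(
                        bs.statistics.loc[n, "q05"]
                        <= true_values[n]
                        <= bs.statistics.loc[n, "q95"]
                    )
                    for n in names
                }
            )

    estimates = pd.DataFrame(rows)
    bias = estimates.mean() - true_values
    sel_freq: dict[tuple[str, ...], float] = {}
    for terms in selections:
        sel_freq[terms] = sel_freq.get(terms, 0.0) + 1.0 / n_datasets
    return RecoveryReport(
        n_datasets=n_datasets,
        truth=truth,
        bias=bias,
        relative_bias=bias / true_values.abs(),
        rmse=np.sqrt(((estimates - true_values) ** 2).mean()),
        selection_frequency=sel_freq,
        coverage=pd.DataFrame(covered).mean() if covered else None,
        estimates=estimates,
    )
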