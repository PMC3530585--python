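"""Long-shoot abundance prediction and optimal winter pruning intensity.

The expected number of long shoots on a virtual tree is

    N_LS = N_S * L_W1 * (1 - PI) * P_LS(L_W1, PI)

where N_S is the constant number of shoots emerging per meter of 1-yr-old
wood left after pruning (default 45.55 per meter).  Pruning trades wood
removed, the factor (1 - PI), against an increased long-shoot probability;
the product is maximized at an intermediate PI once the tree is large
enough.  The practical questions answered here: for a given L_W1, what is
the smallest PI that maximizes N_LS; below what L_W1 is any pruning
counterproductive; and how hard should one ever prune.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model import ModelParameters, predict_pls

__all__ = [
    "DEFAULT_SHOOTS_PER_METER",
    "PredictionGrid",
    "OptimalPruningCurve",
    "OnsetThreshold",
    "n_long_shoots",
    "prediction_surface",
    "optimal_pruning_intensity",
    "optimal_pruning_curve",
    "pruning_onset_threshold",
    "max_recommended_pi",
]

#: Shoots emerging per meter of 1-yr-old wood left after pruning.
DEFAULT_SHOOTS_PER_METER = 45.55

_TIE_TOL = 1e-9  # plateau width counted as a tie; smallest PI wins


@dataclass(frozen=True)
class PredictionGrid:
    """Dense evaluation of P_LS and N_LS over an (L_W1, PI) grid.

    Surfaces are indexed [i, j] for lw1_axis[i], pi_axis[j].
    """

    lw1_axis: np.ndarray
    pi_axis: np.ndarray
    pls_surface: np.ndarray
    nls_surface: np.ndarray
    ns: float


@dataclass(frozen=True)
class OptimalPruningCurve:
    """Minimal N_LS-maximizing pruning intensity per L_W1 value."""

    lw1: np.ndarray
    optimal_pi: np.ndarray
    nls_at_optimum: np.ndarray


@dataclass(frozen=True)
class OnsetThreshold:
    """Smallest L_W1 at which pruning starts to pay off.

    ``found`` is False when no crossing exists (then raw/rounded are None),
    e.g. when P_LS does not respond to PI at all.
    """

    found: bool
    raw: float | None = None
    rounded: float | None = None


def n_long_shoots(params: ModelParameters, ns: float, lw1, pi):
    """Expected long-shoot count N_S * L_W1 * (1 - PI) * P_LS (continuous)."""
    if not ns > 0:
        raise ValueError("ns must be > 0")
    lw1 = np.asarray(lw1, dtype=float)
    pi = np.asarray(pi, dtype=float)
    out = ns * lw1 * (1.0 - pi) * predict_pls(params, lw1, pi)
    return float(out) if np.ndim(out) == 0 else out


def prediction_surface(
    params: ModelParameters,
    ns: float = DEFAULT_SHOOTS_PER_METER,
    lw1_max: float = 600.0,
    lw1_steps: int = 121,
    pi_steps: int = 101,
) -> PredictionGrid:
    """Evaluate P_LS and N_LS over a regular grid [0, lw1_max] x [0, 1]."""
    if lw1_steps < 2 or pi_steps < 2:
        raise ValueError("need at least 2 grid steps per axis")
    lw1_axis = np.linspace(0.0, lw1_max, lw1_steps)
    pi_axis = np.linspace(0.0, 1.0, pi_steps)
    lw1g, pig = np.meshgrid(lw1_axis, pi_axis, indexing="ij")
    pls = predict_pls(params, lw1g, pig)
    nls = ns * lw1g * (1.0 - pig) * pls
    return PredictionGrid(
        lw1_axis=lw1_axis, pi_axis=pi_axis, pls_surface=pls, nls_surface=nls, ns=ns
    )


def optimal_pruning_intensity(
    params: ModelParameters,
    ns: float,
    lw1: float,
    grid_step: float = 1e-3,
) -> float:
    """Minimal PI in [0, 1] maximizing N_LS at the given L_W1.

    Dense-grid scan (default step 1e-3) followed by bounded golden-section
    refinement to 1e-6 around the grid maximizer.  A plateau within 1e-9 of
    the maximum is a tie and resolves to the smallest PI.
    """
    if not lw1 > 0:
        raise ValueError("lw1 must be > 0")
    pis = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    values = n_long_shoots(params, ns, lw1, pis)
    vmax = values.max()
    i0 = int(np.nonzero(values >= vmax - _TIE_TOL)[0][0])  # smallest tied PI
    lo = pis[max(i0 - 1, 0)]
    hi = pis[min(i0 + 1, len(pis) - 1)]
    best_pi, best_v = float(pis[i0]), float(values[i0])
    if hi > lo:
        res = minimize_scalar(
            lambda p: -n_long_shoots(params, ns, lw1, p),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if -res.fun > best_v:
            best_pi, best_v = float(res.x), float(-res.fun)
    # tie-break toward no pruning and smaller grid maximizers
    smaller = np.nonzero(values >= best_v - _TIE_TOL)[0]
    if smaller.size and pis[smaller[0]] < best_pi:
        best_pi = float(pis[smaller[0]])
    return best_pi


def optimal_pruning_curve(
    params: ModelParameters,
    ns: float = DEFAULT_SHOOTS_PER_METER,
    lw1_values=None,
) -> OptimalPruningCurve:
    """Minimal maximizing PI and the achieved N_LS along an L_W1 axis.

    Default axis: 1 m grid over (0, 600].
    """
    if lw1_values is None:
        lw1_values = np.arange(1.0, 601.0)
    lw1_values = np.asarray(lw1_values, dtype=float)
    opt = np.array(
        [optimal_pruning_intensity(params, ns, float(l)) for l in lw1_values]
    )
    nls = np.array(
        [n_long_shoots(params, ns, float(l), float(p)) for l, p in zip(lw1_values, opt)]
    )
    return OptimalPruningCurve(lw1=lw1_values, optimal_pi=opt, nls_at_optimum=nls)


def pruning_onset_threshold(
    params: ModelParameters,
    ns: float = DEFAULT_SHOOTS_PER_METER,
    lw1_upper: float = 10_000.0,
    tol: float = 0.01,
) -> OnsetThreshold:
    """Smallest L_W1 at which the optimal pruning intensity becomes positive.

    Pruning first pays off where the marginal gain at PI = 0 turns positive,
    i.e. where g(L_W1) = (1 - P_LS(L_W1, 0)) * (-e) * L_W1 - 1 crosses zero;
    the threshold is located by bisection to ``tol`` meters and reported
    both raw and rounded to the nearest 10 m.  If g never crosses zero in
    (0, lw1_upper], a not-found result is returned (never an exception).
    """
    e = params.e if params.e is not None else 0.0

    def marginal_gain(lw1: float) -> float:
        return (1.0 - predict_pls(params, lw1, 0.0)) * (-e) * lw1 - 1.0

    if e >= 0:
        return OnsetThreshold(found=False)
    # bracket the first sign change on a coarse scan
    grid = np.linspace(tol, lw1_upper, 4096)
    signs = np.array([marginal_gain(l) for l in grid])
    pos = np.nonzero(signs > 0)[0]
    if pos.size == 0:
        return OnsetThreshold(found=False)
    i = pos[0]
    if i == 0:
        raw = float(grid[0])
    else:
        raw = float(brentq(marginal_gain, grid[i - 1], grid[i], xtol=tol))
    return OnsetThreshold(found=True, raw=raw, rounded=round(raw / 10.0) * 10.0)


def max_recommended_pi(
    params: ModelParameters,
    ns: float = DEFAULT_SHOOTS_PER_METER,
    lw1_max: float = 600.0,
) -> float:
    """Supremum of the optimal pruning intensity over L_W1 in (0, lw1_max].

    Evaluated on a 1 m grid; the operational 'never prune harder than this'
    bound.
    """
    curve = optimal_pruning_curve(
        params, ns, lw1_values=np.arange(1.0, np.floor(lw1_max) + 1.0)
    )
    return float(curve.optimal_pi.max())
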