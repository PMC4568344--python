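"""Energy-minimizing gradient solvers and the step-length strategy.

The per-step balance vanishes when the energy gained from descent exactly
pays for lifting the centre of mass::

    (i/k) / sqrt(1 + i^2) + (1 - sqrt(1 - 1/(4 k^2))) = 0

Dropping the near-unity sqrt(1 + i^2) factor (|i| is small at the optimum)
gives the closed form

    i(k) = k * sqrt(1 - 1/(4 k^2)) - k  =  sqrt(k^2 - 1/4) - k

which is always negative: the optimum is a downhill slope.  Three solvers
are provided — the closed form, a root-find of the un-approximated balance,
and a brute-force argmin of the braking-adjusted cost curve — plus the exact
algebraic inverse k(i) used to recommend a step length for a given slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .params import (
    COMFORT_K_RANGE,
    G_DEFAULT,
    K_MIN,
    BodyParams,
    DomainError,
    GaitParams,
)

__all__ = [
    "OptimalGradientResult",
    "StepLengthAdvice",
    "EdgeArgminWarning",
    "optimal_gradient_closed_form",
    "optimal_gradient_exact",
    "optimal_gradient_numeric",
    "solve_optimal_gradient",
    "optimal_step_parameter",
    "recommend_step_length",
]

#: Root bracket for the exact solver; the optimum provably lies in (-0.5, 0)
#: for every k in the comfortable range.
_BRACKET = (-0.5 + 1e-9, -1e-12)

#: Beyond roughly -13% the optimal step parameter drops below k = 1, i.e. a
#: step longer than the leg — too wide to sustain as a strategy.
STRATEGY_LIMIT_GRADIENT = -0.13


class EdgeArgminWarning(UserWarning):
    """Numeric argmin landed on the grid boundary; the true minimum may
    lie outside the requested gradient window."""


@dataclass(frozen=True)
class OptimalGradientResult:
    """Optimal gradient for one step parameter by all three solvers."""

    k: float
    i_closed_form: float
    i_exact: float
    i_numeric: float
    epsilon_at_optimum: float          # epsilon at i_exact, J (per mass used)
    max_pairwise_disagreement: float   # fraction units


@dataclass(frozen=True)
class StepLengthAdvice:
    """Step-length recommendation for walking a given gradient."""

    gradient: float
    target_k: float | None       # k making this gradient optimal, if any
    step_length: float | None    # leg_length / target_k, metres
    within_comfort: bool
    clamped_k: float | None      # nearest comfort bound when outside
    clamped_step_length: float | None
    status: str


def _check_k(k: float) -> None:
    if not k >= K_MIN:
        raise DomainError(
            f"step parameter k must be >= {K_MIN}, got {k}"
        )


def optimal_gradient_closed_form(k: float) -> float:
    """Approximate optimal gradient sqrt(k^2 - 1/4) - k (fraction, <= 0)."""
    _check_k(k)
    return math.sqrt(k * k - 0.25) - k


def _balance_per_mgl(i: float, k: float) -> float:
    """U_tot / (m g l): the un-approximated per-step energy balance."""
    return (i / k) / math.sqrt(1.0 + i * i) + (
        1.0 - math.sqrt(1.0 - 1.0 / (4.0 * k * k))
    )


def optimal_gradient_exact(k: float, tol: float = 1e-12) -> float:
    """Optimal gradient retaining the sqrt(1 + i^2) factor.

    Solves U_tot(i) = 0 by bracketed root-finding on i in (-0.5, 0).
    Slightly more negative than the closed form; the gap quantifies the
    error of the small-gradient approximation.
    """
    if not k > K_MIN:
        raise DomainError(f"exact solver requires k > {K_MIN}, got {k}")
    if not tol > 0:
        raise DomainError(f"tol must be > 0, got {tol}")
    lo, hi = _BRACKET
    f_lo = _balance_per_mgl(lo, k)
    f_hi = _balance_per_mgl(hi, k)
    if f_lo * f_hi > 0:
        # only possible for k within ~0.003 of the geometric limit 0.5,
        # where the un-approximated root falls below -0.5
        raise ArithmeticError(
            f"no sign change in bracket {_BRACKET} for k={k}; the "
            "un-approximated optimum lies below -0.5 this close to k=0.5"
        )
    root = brentq(_balance_per_mgl, lo, hi, args=(k,), xtol=tol)
    assert abs(_balance_per_mgl(root, k)) < 1e-9
    return float(root)


def _epsilon_curve(
    i: np.ndarray, body: BodyParams, gait: GaitParams, g: float
) -> np.ndarray:
    """Vectorized braking-adjusted cost over a gradient grid."""
    l = body.leg_length
    d_osc = body.mass * g * l * (
        1.0 - math.sqrt(1.0 - 1.0 / (4.0 * gait.k**2))
    )
    u = body.mass * g * i * (l / gait.k) / np.sqrt(1.0 + i * i) + d_osc
    return np.where(u > 0, u, -u / gait.efficiency_factor)


def optimal_gradient_numeric(
    body: BodyParams,
    gait: GaitParams,
    grid_lo: float = -0.5,
    grid_hi: float = 0.5,
    n: int = 10_001,
    g: float = G_DEFAULT,
    refine_tol: float = 1e-7,
) -> float:
    """Brute-force argmin of the cost curve, refined by bounded minimization.

    Independent of the analytic solvers: evaluates epsilon on a grid of
    ``n`` gradients, takes the argmin and polishes it within the two
    neighbouring grid cells.  An argmin on the grid boundary is returned
    as-is with :class:`EdgeArgminWarning`.
    """
    if not grid_lo < grid_hi:
        raise DomainError(
            f"degenerate grid: need grid_lo < grid_hi, got "
            f"[{grid_lo}, {grid_hi}]"
        )
    if n < 1000:
        raise DomainError(f"need n >= 1000 grid points, got {n}")
    grid = np.linspace(grid_lo, grid_hi, n)
    eps = _epsilon_curve(grid, body, gait, g)
    j = int(np.argmin(eps))
    if j in (0, n - 1):
        warnings.warn(
            f"argmin at grid boundary i={grid[j]:g}; true minimum may be "
            "outside the window",
            EdgeArgminWarning,
            stacklevel=2,
        )
        return float(grid[j])
    res = minimize_scalar(
        lambda x: float(_epsilon_curve(np.asarray([x]), body, gait, g)[0]),
        bounds=(grid[j - 1], grid[j + 1]),
        method="bounded",
        options={"xatol": refine_tol},
    )
    return float(res.x)


def solve_optimal_gradient(
    k: float,
    body: BodyParams | None = None,
    efficiency_factor: float = 5.0,
    g: float = G_DEFAULT,
    n_grid: int = 10_001,
) -> OptimalGradientResult:
    """Run all three solvers for one k and report their agreement."""
    body = body if body is not None else BodyParams()
    gait = GaitParams(k=k, efficiency_factor=efficiency_factor)
    i_cf = optimal_gradient_closed_form(k)
    i_ex = optimal_gradient_exact(k)
    i_num = optimal_gradient_numeric(body, gait, n=n_grid, g=g)
    eps_at_opt = float(
        _epsilon_curve(np.asarray([i_ex]), body, gait, g)[0]
    )
    spread = max(
        abs(i_cf - i_ex), abs(i_cf - i_num), abs(i_ex - i_num)
    )
    return OptimalGradientResult(
        k=k,
        i_closed_form=i_cf,
        i_exact=i_ex,
        i_numeric=i_num,
        epsilon_at_optimum=eps_at_opt,
        max_pairwise_disagreement=spread,
    )


def optimal_step_parameter(i: float) -> float:
    """Step parameter k for which gradient ``i`` is optimal.

    Exact algebraic inverse of the closed form: squaring
    sqrt(k^2 - 1/4) = k + i gives k = -(1/4 + i^2) / (2 i), valid for
    i in (-0.5, 0).  Round-trips with the closed form to machine precision.
    """
    if not (-0.5 < i < 0):
        raise DomainError(
            f"no step length makes gradient {i} optimal: the closed-form "
            "optimum only spans (-0.5, 0)"
        )
    return -(0.25 + i * i) / (2.0 * i)


def recommend_step_length(
    i: float,
    body: BodyParams,
    comfort_range: tuple[float, float] = COMFORT_K_RANGE,
) -> StepLengthAdvice:
    """Step-length advice for walking a given gradient.

    Downhill gradients in (-0.5, 0) map to a unique optimal k; the advice
    flags whether it is comfortable (k in [1.15, 1.55] by default) and, if
    not, also reports the nearest comfortable k.  Uphill or level gradients
    have no oscillation-cancelling optimum and yield a structured
    no-optimum result rather than an error.
    """
    lo, hi = comfort_range
    if i >= 0:
        return StepLengthAdvice(
            gradient=i, target_k=None, step_length=None,
            within_comfort=False, clamped_k=None, clamped_step_length=None,
            status=(
                "no optimal step length: uphill/level walking has no "
                "gradient that cancels the centre-of-mass lift"
            ),
        )
    if i <= -0.5:
        return StepLengthAdvice(
            gradient=i, target_k=None, step_length=None,
            within_comfort=False, clamped_k=None, clamped_step_length=None,
            status=(
                "no optimal step length: gradient steeper than -50%, "
                "beyond any step-length optimum"
            ),
        )
    k = optimal_step_parameter(i)
    step = body.leg_length / k
    within = lo <= k <= hi
    clamped_k = None
    clamped_step = None
    status = "optimal step length is comfortable"
    if not within:
        clamped_k = lo if k < lo else hi
        clamped_step = body.leg_length / clamped_k
        status = (
            f"optimal k={k:.3f} outside comfort range [{lo}, {hi}]; "
            f"nearest comfortable k={clamped_k}"
        )
        if i < STRATEGY_LIMIT_GRADIENT:
            status += (
                "; beyond about -13% the optimal step (k <= 1) is too wide "
                "to sustain — consider reducing stride frequency instead"
            )
    return StepLengthAdvice(
        gradient=i, target_k=k, step_length=step, within_comfort=within,
        clamped_k=clamped_k, clamped_step_length=clamped_step, status=status,
    )
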