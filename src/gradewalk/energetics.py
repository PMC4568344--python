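"""Step geometry and the per-step potential-energy cost model.

During one step the centre of mass oscillates between a low point (double
support, both feet down) and a high point (single support, one straight
leg).  With leg length ``l`` and step length ``l/k`` the half-step ground
distance is ``l/(2k)``, and the joint height in double support follows from
a right triangle with the leg as hypotenuse::

    y' = l * sqrt(1 - 1/(4 k^2))
    delta_y = l - y' = l * (1 - sqrt(1 - 1/(4 k^2)))

Raising the centre of mass by ``delta_y`` each step costs
``dU_osc = m g delta_y``.  Walking on a gradient ``i`` additionally changes
height by ``dy = i * dx`` per step, with horizontal projection
``dx = (l/k) / sqrt(1 + i^2)``, giving ``dU_grad = m g i (l/k)/sqrt(1+i^2)``.

The total balance ``U_tot = dU_osc + dU_grad`` is converted to a positive
energy requirement by the braking-efficiency rule: positive balances must be
paid in full, while a negative balance (excess energy gained downhill) only
requires braking work a factor ~5 smaller in magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    G_DEFAULT,
    BodyParams,
    GaitParams,
    GradientValue,
)

__all__ = [
    "GaitGeometry",
    "EnergyBreakdown",
    "compute_geometry",
    "oscillation_energy",
    "gradient_energy",
    "braking_cost",
    "total_energy",
]


@dataclass(frozen=True)
class GaitGeometry:
    """Heights and step projections for one step, all in metres."""

    y_max: float      # centre-of-mass height in single support
    y_min: float      # centre-of-mass height in double support
    y_prime: float    # joint height in double support, l*sqrt(1 - 1/(4k^2))
    delta_y: float    # vertical oscillation per step, y_max - y_min
    dx: float         # horizontal projection of the step
    dy: float         # height gained per step on the gradient


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-step potential-energy terms in joules."""

    dU_osc: float     # cost of lifting the centre of mass
    dU_grad: float    # cost (signed) of the gradient
    U_tot: float      # dU_osc + dU_grad
    epsilon: float    # braking-adjusted positive requirement, >= 0
    g: float = G_DEFAULT


def compute_geometry(
    body: BodyParams, gait: GaitParams, gradient: GradientValue
) -> GaitGeometry:
    """Step geometry for one walker at one step parameter and gradient.

    ``delta_y`` is computed as ``l - y'`` so it is exactly independent of
    the trunk offset ``y0`` (which only shifts ``y_max`` and ``y_min``
    together) and of the gradient.
    """
    l = body.leg_length
    y_prime = l * math.sqrt(1.0 - 1.0 / (4.0 * gait.k**2))
    y_max = body.trunk_offset + l
    y_min = body.trunk_offset + y_prime
    delta_y = l - y_prime
    i = gradient.i
    dx = (l / gait.k) / math.sqrt(1.0 + i * i)
    dy = i * dx
    return GaitGeometry(
        y_max=y_max, y_min=y_min, y_prime=y_prime,
        delta_y=delta_y, dx=dx, dy=dy,
    )


def oscillation_energy(
    body: BodyParams, gait: GaitParams, g: float = G_DEFAULT
) -> float:
    """Per-step cost of the centre-of-mass oscillation, m*g*delta_y (J)."""
    geom = compute_geometry(body, gait, GradientValue(0.0))
    return body.mass * g * geom.delta_y


def gradient_energy(
    body: BodyParams,
    gait: GaitParams,
    gradient: GradientValue,
    g: float = G_DEFAULT,
) -> float:
    """Per-step potential energy of the gradient, m*g*i*(l/k)/sqrt(1+i^2).

    Positive uphill, negative downhill; odd in ``i`` since i/sqrt(1+i^2)
    is an odd function.
    """
    i = gradient.i
    step = body.leg_length / gait.k
    return body.mass * g * i * step / math.sqrt(1.0 + i * i)


def braking_cost(u_tot: float, efficiency_factor: float = 5.0) -> float:
    """Piecewise braking-efficiency function epsilon.

    A positive energy balance must be supplied by positive muscular work
    and is returned unchanged.  A negative balance means the body gains
    energy from descent and must brake; braking (negative) work is cheaper
    by ``efficiency_factor``, so the requirement is ``-u_tot / factor``.
    Both branches vanish at ``u_tot = 0``, so epsilon is continuous.
    """
    if u_tot > 0:
        return u_tot
    if u_tot < 0:
        return -u_tot / efficiency_factor
    return 0.0


def total_energy(
    body: BodyParams,
    gait: GaitParams,
    gradient: GradientValue,
    g: float = G_DEFAULT,
) -> EnergyBreakdown:
    """Full per-step energy breakdown: oscillation, gradient, total, epsilon."""
    d_osc = oscillation_energy(body, gait, g)
    d_grad = gradient_energy(body, gait, gradient, g)
    u_tot = d_osc + d_grad
    eps = braking_cost(u_tot, gait.efficiency_factor)
    return EnergyBreakdown(
        dU_osc=d_osc, dU_grad=d_grad, U_tot=u_tot, epsilon=eps, g=g
    )
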