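"""Order-of-magnitude comparison of kinetic vs potential energy in walking.

At typical walking speed (~1.25 m/s) the centre of mass barely changes
speed between steps, so the kinetic energy that must actually be re-supplied
per step is small — roughly (v_high^2 - v_low^2)/2 per unit mass for a
braking/re-acceleration band of ~0.1 m/s.  The potential-energy oscillation
g*delta_y for an 8-10 cm centre-of-mass excursion is several times larger,
which justifies a potential-energy-only cost model at low speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import G_DEFAULT, DomainError

__all__ = [
    "MagnitudeReport",
    "kinetic_energy_per_mass",
    "per_step_kinetic_cost",
    "potential_oscillation_per_mass",
    "magnitude_report",
]


@dataclass(frozen=True)
class MagnitudeReport:
    """Scalar magnitude estimates, all per unit mass (J/kg)."""

    ke_total_per_mass: float        # v^2/2 at cruise speed
    ke_per_step_per_mass: float     # from the per-step speed fluctuation
    pe_per_step_per_mass: float     # g * delta_y
    pe_ke_ratio: float | None       # None when the KE fluctuation is zero

    def format_table(self) -> str:
        """Two-decimal table of the four quantities, ready for printing.

        Values are truncated (not rounded) to two decimals so that
        order-of-magnitude figures are never overstated: 0.125 J/kg prints
        as 0.12.
        """
        lines = [
            f"total kinetic energy      {_trunc2(self.ke_total_per_mass)} J/kg",
            f"kinetic cost per step     {_trunc2(self.ke_per_step_per_mass)} J/kg",
            f"potential cost per step   {_trunc2(self.pe_per_step_per_mass)} J/kg",
        ]
        if self.pe_ke_ratio is None:
            lines.append("PE/KE ratio               undefined (no speed "
                         "fluctuation)")
        else:
            lines.append(f"PE/KE ratio               {_trunc2(self.pe_ke_ratio)}")
        return "\n".join(lines)


def _trunc2(x: float) -> str:
    """Truncate toward zero at two decimals; tolerant of float dust."""
    return f"{math.floor(x * 100 + 1e-9) / 100:.2f}"


def kinetic_energy_per_mass(v: float) -> float:
    """Kinetic energy per unit mass v^2/2 (J/kg) at cruise speed v (m/s)."""
    if v < 0:
        raise DomainError(f"speed must be >= 0 m/s, got {v}")
    return 0.5 * v * v


def per_step_kinetic_cost(v_low: float, v_high: float) -> float:
    """Kinetic energy re-supplied per step, (v_high^2 - v_low^2)/2 (J/kg).

    The walker brakes from v_high to v_low and accelerates back each step;
    only the difference of the two kinetic energies is paid.
    """
    if v_low < 0 or v_high < v_low:
        raise DomainError(
            f"need 0 <= v_low <= v_high, got ({v_low}, {v_high})"
        )
    return 0.5 * (v_high * v_high - v_low * v_low)


def potential_oscillation_per_mass(
    delta_y: float, g: float = G_DEFAULT
) -> float:
    """Potential energy per step per unit mass, g*delta_y (J/kg)."""
    if delta_y < 0:
        raise DomainError(
            f"oscillation amplitude must be >= 0 m, got {delta_y}"
        )
    return g * delta_y


def magnitude_report(
    v: float = 1.25,
    dv: float = 0.10,
    delta_y: float = 0.10,
    g: float = G_DEFAULT,
) -> MagnitudeReport:
    """Assemble the kinetic-vs-potential comparison for one walking condition.

    The per-step speed fluctuation ``dv`` is centred on the cruise speed
    (v - dv/2 to v + dv/2), matching the worked convention of a 1.25 m/s
    walker fluctuating between 1.20 and 1.30 m/s.
    """
    ke_total = kinetic_energy_per_mass(v)
    ke_step = per_step_kinetic_cost(v - dv / 2.0, v + dv / 2.0)
    pe_step = potential_oscillation_per_mass(delta_y, g)
    ratio = pe_step / ke_step if ke_step > 0 else None
    return MagnitudeReport(
        ke_total_per_mass=ke_total,
        ke_per_step_per_mass=ke_step,
        pe_per_step_per_mass=pe_step,
        pe_ke_ratio=ratio,
    )
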