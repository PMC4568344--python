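"""Input parameter types and validation for the gradient-walking model.

The model describes a walker by three scalars: body mass ``m`` (kg), leg
length ``l`` (m, acetabular joint to ground) and trunk offset ``y0`` (m,
centre of mass to acetabular joint).  Gait is described by the dimensionless
step parameter ``k`` (step length = ``l/k``) and a braking-efficiency factor
(negative work is roughly five times cheaper than positive work).  The
gradient ``i`` is rise over run as a signed fraction; negative is downhill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: Standard gravitational acceleration, m s^-2.
G_DEFAULT = 9.81

#: Smallest step parameter for which the step geometry is real:
#: below k = 1/2 the half-step exceeds the leg length.
K_MIN = 0.5

#: Comfortable step-parameter range, k = 1.35 +/- 0.20.
COMFORT_K_RANGE = (1.15, 1.55)

#: Alternative comfort bounds quoted in the step-length strategy discussion.
COMFORT_K_RANGE_ALT = (1.10, 1.50)

#: Default ratio of positive-work cost to braking (negative-work) cost.
DEFAULT_EFFICIENCY_FACTOR = 5.0


class DomainError(ValueError):
    """A parameter lies outside the model's mathematical domain."""


class ComfortRangeWarning(UserWarning):
    """Step parameter is mathematically valid but outside the comfortable
    range k = 1.35 +/- 0.20; results describe an awkward gait."""


@dataclass(frozen=True)
class BodyParams:
    """Anthropometric constants of one walker.

    Parameters
    ----------
    mass:
        Body mass in kg.  Defaults to 1 so that energies are per unit mass.
    leg_length:
        Leg length ``l`` in metres; must be positive.
    trunk_offset:
        Vertical distance ``y0`` from the centre of mass to the acetabular
        joint, in metres.  It shifts every height by a constant and cancels
        in all energy quantities.
    """

    mass: float = 1.0
    leg_length: float = 0.9
    trunk_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.leg_length > 0:
            raise DomainError(
                f"leg_length must be > 0 m, got {self.leg_length}"
            )
        if self.mass < 0:
            raise DomainError(f"mass must be >= 0 kg, got {self.mass}")
        if self.trunk_offset < 0:
            raise DomainError(
                f"trunk_offset must be >= 0 m, got {self.trunk_offset}"
            )


@dataclass(frozen=True)
class GaitParams:
    """Step parameter and braking-efficiency factor.

    ``k`` is leg length divided by step length; ``k >= 0.5`` is required for
    the step triangle to close (the constraint comes from
    ``sqrt(1 - 1/(4 k^2))``).  Values outside the comfortable range
    [1.15, 1.55] emit :class:`ComfortRangeWarning` but are accepted.
    """

    k: float
    efficiency_factor: float = DEFAULT_EFFICIENCY_FACTOR

    def __post_init__(self) -> None:
        if not self.k >= K_MIN:
            raise DomainError(
                f"step parameter k must be >= {K_MIN} "
                f"(sqrt(1 - 1/(4 k^2)) is not real below that), got {self.k}"
            )
        if not self.efficiency_factor > 1:
            raise DomainError(
                "efficiency_factor must be > 1 "
                f"(braking must be cheaper than positive work), "
                f"got {self.efficiency_factor}"
            )
        lo, hi = COMFORT_K_RANGE
        if not lo <= self.k <= hi:
            warnings.warn(
                f"k={self.k} is outside the comfortable range "
                f"[{lo}, {hi}] (1.35 +/- 0.20)",
                ComfortRangeWarning,
                stacklevel=3,
            )

    @property
    def step_length_factor(self) -> float:
        """Step length as a fraction of leg length, 1/k."""
        return 1.0 / self.k


@dataclass(frozen=True)
class GradientValue:
    """Signed gradient as a rise-over-run fraction (positive = uphill)."""

    i: float

    def __post_init__(self) -> None:
        if not abs(self.i) < 5:
            raise DomainError(
                f"|gradient| must be < 5 (fraction units; the model is "
                f"intended for |i| < ~0.3), got {self.i}"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.i
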