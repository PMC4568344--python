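"""Step geometry and per-step potential-energy cost model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradewalk import (
    BodyParams,
    DomainError,
    GaitParams,
    GradientValue,
    braking_cost,
    compute_geometry,
    gradient_energy,
    oscillation_energy,
    total_energy,
)

# frozen oracle values: l*(1 - sqrt(1 - 1/(4 k^2))) evaluated independently
DELTA_Y_L09_K135 = 0.06400425306770313
OSC_M70 = 43.951720581591744          # 70 * 9.81 * DELTA_Y_L09_K135
GRAD_M1_L1_K1_I01 = 0.9761314835959995  # 9.81 * 0.1 / sqrt(1.01)


class TestGeometry:
    @pytest.mark.parametrize(
        "l, k, expect_dy",
        [
            (1.0, 0.5, 1.0),          # widest step: y' = 0, full-leg drop
            (0.9, 1e6, 0.0),          # vanishing step: no oscillation
            (0.9, 1.35, DELTA_Y_L09_K135),
        ],
    )
    def test_vertical_oscillation(self, l, k, expect_dy):
        geom = compute_geometry(
            BodyParams(leg_length=l), GaitParams(k), GradientValue(0.0)
        )
        assert geom.delta_y == pytest.approx(expect_dy, abs=1e-9)

    def test_widest_step_degenerates(self):
        geom = compute_geometry(
            BodyParams(leg_length=1.0, trunk_offset=0.5),
            GaitParams(0.5),
            GradientValue(0.0),
        )
        assert geom.y_prime == 0.0
        assert geom.dy == 0.0
        assert geom.y_max == 1.5 and geom.y_min == 0.5

    @settings(derandomize=True, max_examples=200)
    @given(
        y0=st.floats(0.0, 2.0),
        l=st.floats(0.3, 1.2),
        k=st.floats(0.5, 5.0),
    )
    def test_trunk_offset_cancels(self, y0, l, k):
        """delta_y is bit-identical whatever the trunk offset."""
        ref = compute_geometry(
            BodyParams(leg_length=l), GaitParams(k), GradientValue(0.0)
        )
        shifted = compute_geometry(
            BodyParams(leg_length=l, trunk_offset=y0),
            GaitParams(k),
            GradientValue(0.0),
        )
        assert shifted.delta_y == ref.delta_y
        assert shifted.y_max - shifted.y_min == pytest.approx(
            ref.delta_y, rel=1e-12
        )

    @settings(derandomize=True, max_examples=200)
    @given(
        l=st.floats(0.3, 1.2),
        k=st.floats(0.5, 5.0),
        i=st.floats(-0.5, 0.5),
    )
    def test_step_triangle_closes(self, l, k, i):
        """dx^2 + dy^2 recovers the squared step length (Pythagoras)."""
        geom = compute_geometry(
            BodyParams(leg_length=l), GaitParams(k), GradientValue(i)
        )
        assert geom.dx**2 + geom.dy**2 == pytest.approx(
            (l / k) ** 2, rel=1e-12
        )
        assert 0.0 <= geom.delta_y <= l
        assert geom.y_max >= geom.y_min

    def test_oscillation_independent_of_gradient(self, body):
        gait = GaitParams(1.35)
        flat = compute_geometry(body, gait, GradientValue(0.0))
        steep = compute_geometry(body, gait, GradientValue(-0.3))
        assert flat.delta_y == steep.delta_y

    @pytest.mark.parametrize(
        "bad",
        [
            dict(body=dict(leg_length=-1.0)),
            dict(body=dict(leg_length=0.0)),
            dict(body=dict(mass=-5.0)),
            dict(gait=dict(k=0.49)),
            dict(gait=dict(k=1.35, efficiency_factor=0.5)),
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(DomainError):
            BodyParams(**bad.get("body", {}))
            GaitParams(**bad.get("gait", {"k": 1.35}))


class TestEnergies:
    @pytest.mark.parametrize(
        "m, l, k, expect",
        [
            (0.0, 0.9, 1.35, 0.0),
            (1.0, 1.0, 0.5, 9.81),
            (70.0, 0.9, 1.35, OSC_M70),
        ],
    )
    def test_oscillation_energy(self, m, l, k, expect):
        val = oscillation_energy(
            BodyParams(mass=m, leg_length=l), GaitParams(k)
        )
        assert val == pytest.approx(expect, abs=1e-9)

    def test_oscillation_equals_mg_delta_y(self, heavy_body):
        gait = GaitParams(1.35)
        geom = compute_geometry(heavy_body, gait, GradientValue(0.0))
        assert oscillation_energy(heavy_body, gait) == (
            heavy_body.mass * 9.81 * geom.delta_y
        )

    @pytest.mark.parametrize(
        "i, expect",
        [
            (0.0, 0.0),
            (0.1, GRAD_M1_L1_K1_I01),
        ],
    )
    def test_gradient_energy(self, i, expect):
        val = gradient_energy(
            BodyParams(mass=1.0, leg_length=1.0),
            GaitParams(1.0),
            GradientValue(i),
        )
        assert val == pytest.approx(expect, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(i=st.floats(1e-6, 0.5), k=st.floats(0.5, 3.0))
    def test_gradient_energy_antisymmetric(self, i, k):
        body = BodyParams(mass=1.0, leg_length=0.9)
        up = gradient_energy(body, GaitParams(k), GradientValue(i))
        down = gradient_energy(body, GaitParams(k), GradientValue(-i))
        assert up + down == 0.0
        assert up > 0.0

    def test_uphill_costs_oscillation_plus_climb(self, heavy_body):
        bd = total_energy(heavy_body, GaitParams(1.35), GradientValue(0.10))
        assert bd.U_tot == bd.dU_osc + bd.dU_grad
        assert bd.epsilon == bd.U_tot > 0


class TestBrakingCost:
    @pytest.mark.parametrize(
        "u, factor, expect",
        [
            (50.0, 5.0, 50.0),     # positive balance paid in full
            (-100.0, 5.0, 20.0),   # 100 J surplus braked for 20 J
            (0.0, 5.0, 0.0),       # both branches agree at the kink
            (-100.0, 4.0, 25.0),
        ],
    )
    def test_piecewise_branches(self, u, factor, expect):
        assert braking_cost(u, factor) == expect

    def test_continuous_at_branch_point(self):
        assert braking_cost(1e-12) == pytest.approx(0.0, abs=1e-11)
        assert braking_cost(-1e-12) == pytest.approx(0.0, abs=1e-11)


class TestCostCurveShape:
    """The braking-adjusted cost is a non-negative V in the gradient."""

    @pytest.mark.parametrize("k", [1.0, 1.25, 1.5])
    def test_v_shape_nonnegative(self, k, body):
        gait = GaitParams(k)
        grid = np.linspace(-0.5, 0.5, 10_001)
        eps = np.array([
            total_energy(body, gait, GradientValue(i)).epsilon for i in grid
        ])
        assert (eps >= 0).all()
        j = int(np.argmin(eps))
        assert 0 < j < len(grid) - 1
        assert (np.diff(eps[: j + 1]) < 0).all()   # strictly falling
        assert (np.diff(eps[j:]) > 0).all()        # strictly rising

    def test_branch_slopes_balance_through_efficiency(self, body):
        """|left slope| * factor matches the right slope near the optimum;
        only the (1 + i^2)^(3/2) factor breaks the symmetry, so the
        mismatch stays under 2% close to the minimum and under 3.5%
        anywhere in |i| <= 0.15."""
        gait = GaitParams(1.35)
        from gradewalk import optimal_gradient_exact

        i_opt = optimal_gradient_exact(1.35)
        d = 1e-5

        def eps(i):
            return total_energy(body, gait, GradientValue(i)).epsilon

        for off, rel in ((0.005, 0.02), (0.02, 0.02), (0.05, 0.035)):
            left = abs(
                (eps(i_opt - off + d) - eps(i_opt - off - d)) / (2 * d)
            )
            right = (
                eps(i_opt + off + d) - eps(i_opt + off - d)
            ) / (2 * d)
            assert abs(i_opt - off) <= 0.15 and abs(i_opt + off) <= 0.15
            assert left * gait.efficiency_factor == pytest.approx(
                right, rel=rel
            )

    def test_epsilon_scales_linearly_with_mass(self, body, heavy_body):
        gait = GaitParams(1.25)
        i = GradientValue(-0.2)
        e1 = total_energy(body, gait, i).epsilon
        e70 = total_energy(heavy_body, gait, i).epsilon
        assert e70 == pytest.approx(70.0 * e1, rel=1e-12)
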