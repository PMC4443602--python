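"""One-compartment kinetics: rates, steady state, trajectories, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from dustdose.kinetics import (ClearanceSpec, burden_trajectory,
                               deposition_rate, noaec_from_threshold,
                               rate_from_half_time, steady_state_burden)
from dustdose.quantities import Q


class TestRateFromHalfTime:
    @pytest.mark.parametrize("t_half,expected", [
        (60, 0.0115525), (math.log(2), 1.0), (400, 0.0017329),
    ])
    def test_values(self, t_half, expected):
        assert rate_from_half_time(Q(t_half, "day")).magnitude_in(
            "1/day") == pytest.approx(expected, rel=1e-4)

    def test_clearance_spec_invariant(self):
        spec = ClearanceSpec.from_half_time(Q(60, "day"))
        assert float(spec.rate * spec.half_time) == pytest.approx(
            math.log(2), rel=1e-12)
        with pytest.raises(ValueError, match="ln"):
            ClearanceSpec(half_time=Q(60, "day"), rate=Q(0.01, "1/day"))

    def test_non_positive_half_time(self):
        with pytest.raises(ValueError):
            rate_from_half_time(Q(0, "day"))


class TestDepositionRate:
    def test_mass_rate(self):
        r = deposition_rate(Q(1, "mg/m^3"), 0.075, Q(0.29, "m^3/day"))
        assert r.magnitude_in("mg/day") == pytest.approx(0.02175, rel=1e-10)

    def test_volume_rate_divides_by_density(self):
        r = deposition_rate(Q(1, "mg/m^3"), 0.075, Q(0.29, "m^3/day"),
                            density=Q(1, "g/cm^3"))
        assert r.magnitude_in("ul/day") == pytest.approx(0.02175, rel=1e-10)

    def test_zero_concentration(self):
        r = deposition_rate(Q(0, "mg/m^3"), 0.075, Q(0.29, "m^3/day"))
        assert r.canonical == 0

    def test_fraction_domain(self):
        with pytest.raises(ValueError):
            deposition_rate(Q(1, "mg/m^3"), 1.5, Q(0.29, "m^3/day"))


class TestSteadyState:
    def test_mass_burden(self):
        b = steady_state_burden(Q(0.02175, "mg/day"),
                                ClearanceSpec.from_half_time(Q(60, "day")))
        assert b.magnitude_in("mg") == pytest.approx(1.8827, abs=1e-4)

    def test_volume_burden(self):
        b = steady_state_burden(Q(0.069, "ul/day"),
                                ClearanceSpec.from_half_time(Q(60, "day")))
        assert b.magnitude_in("ul") == pytest.approx(5.973, abs=1e-3)

    def test_zero_rate(self):
        b = steady_state_burden(Q(0, "mg/day"),
                                ClearanceSpec.from_half_time(Q(60, "day")))
        assert b.canonical == 0

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=1e-4, max_value=10),
           st.floats(min_value=1, max_value=1000),
           st.floats(min_value=0.1, max_value=10))
    def test_linear_in_rate_and_half_time(self, d, t_half, scale):
        base = steady_state_burden(
            Q(d, "mg/day"), ClearanceSpec.from_half_time(Q(t_half, "day")))
        in_rate = steady_state_burden(
            Q(d * scale, "mg/day"), ClearanceSpec.from_half_time(Q(t_half, "day")))
        in_half = steady_state_burden(
            Q(d, "mg/day"), ClearanceSpec.from_half_time(Q(t_half * scale, "day")))
        assert in_rate.magnitude_in("mg") == pytest.approx(
            base.magnitude_in("mg") * scale, rel=1e-10)
        assert in_half.magnitude_in("mg") == pytest.approx(
            base.magnitude_in("mg") * scale, rel=1e-10)


class TestTrajectory:
    def test_starts_at_zero_and_approaches_steady_state(self):
        clearance = ClearanceSpec.from_half_time(Q(60, "day"))
        state = burden_trajectory(Q(0.02175, "mg/day"), clearance,
                                  [0, 60, 20 * 60])
        t, b = state.trajectory
        assert b[0] == 0
        # one half-time reaches half of steady state
        assert b[1] == pytest.approx(
            state.steady_state_burden.magnitude_in("mg") / 2, rel=1e-10)
        assert b[1] == pytest.approx(0.9414, abs=1e-4)
        assert b[-1] == pytest.approx(
            state.steady_state_burden.magnitude_in("mg"), rel=1e-6)

    def test_monotone_and_bounded(self):
        clearance = ClearanceSpec.from_half_time(Q(60, "day"))
        state = burden_trajectory(Q(0.02175, "mg/day"), clearance,
                                  np.linspace(0, 600, 101))
        _, b = state.trajectory
        assert (np.diff(b) > 0).all()
        assert (b <= state.steady_state_burden.magnitude_in("mg")).all()

    def test_unsorted_times_rejected(self):
        clearance = ClearanceSpec.from_half_time(Q(60, "day"))
        with pytest.raises(ValueError, match="increasing"):
            burden_trajectory(Q(1, "mg/day"), clearance, [0, 2, 1])

    @pytest.mark.parametrize("d,t_half", [(0.02175, 60), (0.5, 255), (3.0, 7)])
    def test_agrees_with_numeric_ode_oracle(self, d, t_half):
        """Analytic solution vs independent stiff-safe numeric integration of
        dB/dt = D - kB, to 1e-8 relative at every grid point."""
        clearance = ClearanceSpec.from_half_time(Q(t_half, "day"))
        times = np.linspace(0, 6 * t_half, 25)
        state = burden_trajectory(Q(d, "mg/day"), clearance, times)
        k = clearance.rate.magnitude_in("1/day")
        sol = solve_ivp(lambda t, b: d - k * b, (0, times[-1]), [0.0],
                        t_eval=times, rtol=1e-11, atol=1e-14, method="LSODA")
        assert sol.success
        analytic = state.trajectory[1]
        np.testing.assert_allclose(analytic[1:], sol.y[0][1:], rtol=1e-8)


class TestNoaecInversion:
    def test_reference_rat_scenario(self):
        noaec = noaec_from_threshold(Q(1, "ul/kg"),
                                     ClearanceSpec.from_half_time(Q(60, "day")),
                                     Q(0.29, "m^3/(day*kg)"), 0.075,
                                     density=Q(1, "g/cm^3"))
        assert noaec.magnitude_in("mg/m^3") == pytest.approx(0.5311, abs=1e-4)

    def test_corrected_threshold_scenario(self):
        noaec = noaec_from_threshold(Q(4.2, "ul/kg"),
                                     ClearanceSpec.from_half_time(Q(60, "day")),
                                     Q(0.29, "m^3/(day*kg)"), 0.063,
                                     density=Q(1, "g/cm^3"))
        assert noaec.magnitude_in("mg/m^3") == pytest.approx(2.6557, abs=1e-4)

    def test_zero_threshold(self):
        noaec = noaec_from_threshold(Q(0, "ul/kg"),
                                     ClearanceSpec.from_half_time(Q(60, "day")),
                                     Q(0.29, "m^3/(day*kg)"), 0.075,
                                     density=Q(1, "g/cm^3"))
        assert noaec.canonical == 0

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=10, max_value=500),
           st.floats(min_value=0.05, max_value=20),
           st.floats(min_value=0.01, max_value=0.5),
           st.floats(min_value=0.5, max_value=6))
    def test_round_trip_recovers_threshold(self, thresh, t_half, ve, frac, rho):
        """noaec_from_threshold then deposition_rate then steady_state_burden
        reproduces the threshold burden to 1e-10 relative."""
        clearance = ClearanceSpec.from_half_time(Q(t_half, "day"))
        noaec = noaec_from_threshold(Q(thresh, "ul/kg"), clearance,
                                     Q(ve, "m^3/(day*kg)"), frac,
                                     density=Q(rho, "g/cm^3"))
        rate = deposition_rate(noaec, frac, Q(ve, "m^3/(day*kg)"),
                               density=Q(rho, "g/cm^3"))
        burden = steady_state_burden(rate, clearance)
        assert burden.magnitude_in("ul/kg") == pytest.approx(thresh, rel=1e-10)
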