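"""Hodgkin-Huxley kinetics and membrane current densities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from neurostimfem import membrane as mb


class TestRates:
    def test_rest_values(self):
        an, bn, am, bm, ah, bh = mb.hh_rates(0.0)
        assert ah == pytest.approx(0.07)
        assert bn == pytest.approx(0.125)
        assert bm == pytest.approx(4.0)
        # alpha_n(0) = 0.1 / (e - 1)
        assert an == pytest.approx(0.1 / (np.e - 1.0), rel=1e-12)
        assert an == pytest.approx(0.05820, abs=5e-6)

    @pytest.mark.parametrize("v_sing,idx,limit", [(-10.0, 0, 0.1), (-25.0, 2, 1.0)])
    def test_removable_singularities(self, v_sing, idx, limit):
        """alpha_n and alpha_m are continuous through their singular points."""
        at = mb.hh_rates(v_sing)[idx]
        assert at == pytest.approx(limit, rel=1e-12)
        lo = mb.hh_rates(v_sing - 1e-6)[idx]
        hi = mb.hh_rates(v_sing + 1e-6)[idx]
        assert abs(lo - at) < 1e-6 and abs(hi - at) < 1e-6

    def test_steady_state_against_ode_oracle(self):
        """Long-time integration of the gate ODEs converges to alpha/(alpha+beta)."""
        an, bn, am, bm, ah, bh = mb.hh_rates(0.0)
        expect = {
            "n": mb.gate_steady_state(an, bn),
            "m": mb.gate_steady_state(am, bm),
            "h": mb.gate_steady_state(ah, bh),
        }
        # frozen reference values for the resting state
        assert expect["n"] == pytest.approx(0.3177, abs=1e-4)
        assert expect["m"] == pytest.approx(0.0529, abs=1e-4)
        assert expect["h"] == pytest.approx(0.5961, abs=1e-4)
        for (a, b), key in (((an, bn), "n"), ((am, bm), "m"), ((ah, bh), "h")):
            sol = solve_ivp(lambda t, x: a * (1 - x) - b * x, (0.0, 200.0),
                            [0.0], rtol=1e-10, atol=1e-12)
            assert sol.y[0, -1] == pytest.approx(expect[key], abs=1e-6)

    def test_steady_state_degenerate_cases(self):
        assert mb.gate_steady_state(0.3, 0.3) == pytest.approx(0.5)
        assert mb.gate_steady_state(0.7, 0.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            mb.gate_steady_state(0.0, 0.0)


class TestStepGates:
    def test_fixed_point_preserved(self):
        g0 = mb.resting_gates(-65e-3)
        g1 = mb.step_gates(g0, 0.0, dt_ms=0.5)
        assert g1.n == pytest.approx(g0.n, rel=1e-12)
        assert g1.m == pytest.approx(g0.m, rel=1e-12)
        assert g1.h == pytest.approx(g0.h, rel=1e-12)

    def test_large_dt_reaches_steady_state(self):
        g = mb.GateState(n=0.0, m=1.0, h=0.0)
        out = mb.step_gates(g, -40.0, dt_ms=1e9)
        an, bn, am, bm, ah, bh = mb.hh_rates(-40.0)
        assert out.n == pytest.approx(mb.gate_steady_state(an, bn), rel=1e-6)
        assert out.m == pytest.approx(mb.gate_steady_state(am, bm), rel=1e-6)

    def test_small_steps_match_adaptive_ode(self):
        """1e4 backward-Euler steps at dt = 1 us track the exact relaxation."""
        vt = 0.0
        an, bn, *_ = mb.hh_rates(vt)
        g = mb.GateState(n=0.0, m=0.0, h=0.0)
        for _ in range(10_000):
            g = mb.step_gates(g, vt, dt_ms=1e-3)
        sol = solve_ivp(lambda t, x: an * (1 - x) - bn * x, (0.0, 10.0), [0.0],
                        rtol=1e-11, atol=1e-13)
        assert g.n == pytest.approx(sol.y[0, -1], abs=1e-4)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-120, 120), st.floats(1e-6, 1e3),
           st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_gates_stay_bounded(self, vt, dt, n, m, h):
        out = mb.step_gates(mb.GateState(n=n, m=m, h=h), vt, dt)
        for x in (out.n, out.m, out.h):
            assert 0.0 <= x <= 1.0


class TestCurrentDensity:
    def test_passive_rest_is_zero(self):
        p = mb.MembraneParams()
        Im, Ic, Il, IK, INa = mb.membrane_current_density(p.El, p.El, 1e-4,
                                                          None, p)
        assert Im == 0.0 and Ic == 0.0 and Il == 0.0

    def test_reversal_potential_nulls_channel(self):
        p = mb.MembraneParams(gl=0.0, gNa_bar=0.0, active=True)
        g = mb.GateState(n=0.7, m=0.1, h=0.5)
        Im, Ic, Il, IK, INa = mb.membrane_current_density(p.EK, p.EK, 1e-4, g, p)
        assert IK == pytest.approx(0.0, abs=1e-15)
        assert Im == pytest.approx(0.0, abs=1e-15)

    def test_capacitive_step_arithmetic(self):
        p = mb.MembraneParams(cm=0.01, gl=0.0)
        Im, Ic, *_ = mb.membrane_current_density(10e-3, 0.0, 1e-4, None, p)
        assert Ic == pytest.approx(1.0)

    def test_components_sum_exactly(self, rng):
        p = mb.MembraneParams(active=True)
        g = mb.resting_gates(-65e-3)
        for _ in range(20):
            vn, vo = rng.normal(scale=50e-3, size=2)
            Im, Ic, Il, IK, INa = mb.membrane_current_density(vn, vo, 2e-5, g, p)
            assert Im == Ic + Il + IK + INa

    def test_unit_conversions(self):
        assert mb.uF_per_cm2(1.0) == pytest.approx(0.01)
        assert mb.mS_per_cm2(1.0) == pytest.approx(10.0)
        assert mb.ohm_cm(100.0) == pytest.approx(1.0)
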