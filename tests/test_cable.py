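"""Compartmental cable solver: discretization, integration, thresholds."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neurostimfem import cable
from neurostimfem.cable import (Waveform, auto_timestep, compartmentalize,
                                find_threshold, simulate, straight_fiber,
                                fiber_with_soma)
from neurostimfem.membrane import MembraneParams, mS_per_cm2, ohm_cm, uF_per_cm2

PASSIVE = MembraneParams(cm=uF_per_cm2(1.0), gl=mS_per_cm2(1e-4), El=-65e-3)
RA = ohm_cm(100.0)


def paper_fiber_model(dx=1e-6):
    return compartmentalize(straight_fiber(260e-6, 2e-6), dx, Ra=RA,
                            params=PASSIVE)


class TestCompartmentalize:
    def test_fiber_compartment_count(self):
        model = paper_fiber_model()
        assert model.n == 260
        assert np.allclose(model.lengths, 1e-6)

    def test_uniform_axial_conductance(self):
        model = paper_fiber_model()
        g_exact = (math.pi * (2e-6) ** 2 / 4) / (RA * 1e-6)
        assert np.allclose(model.g_axial, g_exact, rtol=1e-12)

    def test_diameter_change_uses_series_resistance(self):
        m = fiber_with_soma(60e-6, 2e-6, 20e-6)
        model = compartmentalize(m, 10e-6, Ra=RA)
        # conductance across the fiber/soma junction: half-compartment
        # resistances in series
        i = np.nonzero(model.diameters > 10e-6)[0][0]
        edges = [tuple(e) for e in model.edges]
        k = edges.index((i - 1, i)) if (i - 1, i) in edges else \
            edges.index((i, i - 1))
        r1 = RA * (model.lengths[i - 1] / 2) / (math.pi * (2e-6) ** 2 / 4)
        r2 = RA * (model.lengths[i] / 2) / (math.pi * (20e-6) ** 2 / 4)
        assert model.g_axial[k] == pytest.approx(1 / (r1 + r2), rel=1e-12)

    def test_halving_dx_changes_response_below_1pct(self):
        """The discretization criterion: dx -> dx/2 moves Vm by < 1%."""
        y = np.linspace(-130e-6, 130e-6, 2000)
        ve_fn = lambda yy: -10e-3 * np.exp(-(yy / 60e-6) ** 2)
        out = {}
        for dx in (1e-6, 0.5e-6):
            model = paper_fiber_model(dx)
            ve = ve_fn(model.centers[:, 1] - 130e-6)
            tr = simulate(model, ve, Waveform.rect(0, 1e-3), 5e-5, 1e-3,
                          PASSIVE.El)
            out[dx] = np.interp(np.linspace(0, 1, 101),
                                np.linspace(0, 1, model.n), tr.vm[-1])
        scale = np.abs(out[1e-6] - PASSIVE.El).max()
        assert np.max(np.abs(out[1e-6] - out[0.5e-6])) / scale < 0.01


class TestSimulate:
    def test_rest_is_fixed_point(self):
        model = paper_fiber_model(dx=5e-6)
        tr = simulate(model, np.zeros(model.n), Waveform.rect(0, 1e-3, 0.0),
                      5e-5, 2e-3, PASSIVE.El)
        assert np.max(np.abs(tr.vm - PASSIVE.El)) < 1e-12

    def test_gauge_invariance(self, rng):
        """Adding a constant to Ve leaves the response unchanged exactly."""
        model = paper_fiber_model(dx=5e-6)
        ve = rng.normal(scale=5e-3, size=model.n)
        w = Waveform.rect(0, 1e-3)
        a = simulate(model, ve, w, 5e-5, 1e-3, PASSIVE.El)
        b = simulate(model, ve + 0.123, w, 5e-5, 1e-3, PASSIVE.El)
        assert np.max(np.abs(a.vm - b.vm)) < 1e-12

    def test_passive_linearity(self, rng):
        model = paper_fiber_model(dx=5e-6)
        ve = rng.normal(scale=5e-3, size=model.n)
        w = Waveform.rect(0, 1e-3)
        a = simulate(model, ve, w, 5e-5, 1e-3, PASSIVE.El)
        b = simulate(model, 2 * ve, w, 5e-5, 1e-3, PASSIVE.El)
        assert np.allclose(b.vm - PASSIVE.El, 2 * (a.vm - PASSIVE.El),
                           atol=1e-13)

    def test_three_compartment_matches_dense_ode(self):
        """Backward Euler at small dt against an adaptive solver, < 0.1%."""
        model = compartmentalize(straight_fiber(30e-6, 2e-6), 10e-6, Ra=RA,
                                 params=PASSIVE)
        assert model.n == 3
        ve = np.array([-5e-3, -1e-3, 2e-3])
        L = model.laplacian().toarray()
        A = model.areas
        p = model.params

        def rhs(t, v):
            e = ve if t <= 1e-3 else np.zeros(3)
            return (-L @ (v + e) - A * p.gl * (v - p.El)) / (p.cm * A)

        ref = solve_ivp(rhs, (0, 1e-3), np.full(3, p.El), rtol=1e-11,
                        atol=1e-14, method="LSODA")
        tr = simulate(model, ve, Waveform.rect(0, 1e-3), 1e-7, 1e-3, p.El)
        scale = np.abs(ref.y[:, -1] - p.El).max()
        assert np.max(np.abs(tr.vm[-1] - ref.y[:, -1])) / scale < 1e-3

    def test_mirror_property_small_case(self):
        """Passive fiber: end-of-pulse deviation mirrors the mean-centered field."""
        model = paper_fiber_model(dx=2e-6)
        y = model.centers[:, 1]
        ve = -12e-3 / (1 + ((y - y.mean()) / 50e-6) ** 2)
        tr = simulate(model, ve, Waveform.rect(0, 1e-3), 5e-5, 1e-3, PASSIVE.El)
        dev = tr.vm[-1] - PASSIVE.El
        target = -(ve - ve.mean())
        r = np.corrcoef(dev, target)[0, 1]
        assert r > 0.99
        assert np.max(np.abs(dev - target)) / (ve.max() - ve.min()) < 0.05

    def test_ve_length_validated(self):
        model = paper_fiber_model(dx=5e-6)
        with pytest.raises(ValueError):
            simulate(model, np.zeros(3), Waveform.rect(0, 1e-3), 5e-5, 1e-3,
                     PASSIVE.El)


class TestAutoTimestep:
    def test_accepts_typical_dt(self):
        model = paper_fiber_model(dx=2e-6)
        y = model.centers[:, 1]
        ve = -10e-3 * np.exp(-((y - y.mean()) / 50e-6) ** 2)
        dt = auto_timestep(model, ve, Waveform.rect(0, 1e-3), 1e-3,
                           PASSIVE.El, dt0=5e-5)
        assert dt == pytest.approx(5e-5)

    def test_backward_euler_first_order(self):
        """Single-compartment RC step response: error halves with dt."""
        model = compartmentalize(straight_fiber(10e-6, 2e-6), 10e-6, Ra=RA,
                                 params=MembraneParams(cm=0.01,
                                                       gl=mS_per_cm2(0.5),
                                                       El=0.0))
        tau = model.params.cm / model.params.gl

        def vm_end(dt):
            # forcing through a constant Ve makes no difference on a single
            # compartment (gauge); force through initial condition instead
            tr = simulate(model, np.zeros(1), Waveform.rect(0, 1.0, 0.0),
                          dt, 5e-3, V_init=10e-3)
            return tr.vm[-1, 0]

        exact = 10e-3 * math.exp(-5e-3 / tau)
        e1 = abs(vm_end(5e-4) - exact)
        e2 = abs(vm_end(2.5e-4) - exact)
        assert e1 / e2 == pytest.approx(2.0, rel=0.2)


def point_source_ve(centers, source, I=1e-6, sigma=0.2):
    r = np.linalg.norm(centers - source, axis=1)
    return I / (4 * math.pi * sigma * r)


class TestThreshold:
    def active_model(self, dx=2e-6):
        p = MembraneParams(cm=uF_per_cm2(1.0), gl=mS_per_cm2(0.3),
                           El=-65e-3, active=True)
        return compartmentalize(straight_fiber(120e-6, 2e-6), dx, Ra=RA,
                                params=p)

    def test_passive_never_spikes(self):
        model = paper_fiber_model(dx=5e-6)
        ve = point_source_ve(model.centers, [0, 130e-6, -30e-6])
        res = find_threshold(model, ve, Waveform.rect(0, 2e-4, -1.0),
                             detect=-20e-3, bracket=(0.01, 1.0), dt=2e-5)
        assert res.above_bracket and not res.converged

    def test_threshold_monotone_in_distance(self):
        """Brute-force check: farther electrode needs a larger amplitude."""
        model = self.active_model()
        thr = {}
        for z in (20e-6, 60e-6):
            ve = point_source_ve(model.centers, [0, 60e-6, -z])
            res = find_threshold(model, ve, Waveform.rect(0, 2e-4, -1.0),
                                 detect=-10e-3, bracket=(0.01, 300.0),
                                 dt=2e-5, T=2e-3)
            assert not res.above_bracket
            thr[z] = res.amplitude
        assert thr[60e-6] > thr[20e-6]

    def test_all_or_none_detection_insensitivity(self):
        """Moving the detection voltage barely moves the threshold."""
        model = self.active_model()
        ve = point_source_ve(model.centers, [0, 60e-6, -30e-6])
        amps = {}
        for detect in (-20e-3, -10e-3):
            res = find_threshold(model, ve, Waveform.rect(0, 2e-4, -1.0),
                                 detect=detect, bracket=(0.01, 300.0),
                                 dt=2e-5, T=2e-3, tol=0.005)
            amps[detect] = res.amplitude
        rel = abs(amps[-10e-3] - amps[-20e-3]) / amps[-20e-3]
        assert rel < 0.02
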