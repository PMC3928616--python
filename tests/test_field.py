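"""Poisson field solver: analytic oracles, BC limits, conservation."""

import math

import numpy as np
import pytest

from neurostimfem.field import (BoundaryCondition, ConductivityMap,
                                FieldProblem, approx_electrode_current,
                                calibrate_stimulus, gradient_boundary_current,
                                integrate_boundary_current, sample_potential,
                                solve_field)
from neurostimfem.geometry import box_mesh, half_ball_mesh, spherical_shell_mesh

SIGMA = 0.2


@pytest.fixture(scope="module")
def slab():
    return box_mesh(20e-6, 20e-6, 100e-6, 4, 4, 20)


@pytest.fixture(scope="module")
def shell():
    return spherical_shell_mesh(2e-6, 5e-3, subdivisions=1, n_layers=30)


def slab_problem(slab, g1, g2, V0, order=1):
    return FieldProblem(
        mesh=slab, conductivity=ConductivityMap(default=SIGMA),
        bcs={"z0": BoundaryCondition.robin(g1, V0),
             "z1": BoundaryCondition.robin(g2, 0.0)},
        element_order=order)


class TestSlabOracle:
    """1D series-resistance closed form: J = V0 / (1/g1 + L/sigma + 1/g2)."""

    @pytest.mark.parametrize("order", [1, 2])
    def test_double_robin_series_resistance(self, slab, order):
        g1, g2, V0, L = 500.0, 2000.0, 0.5, 100e-6
        sol = solve_field(slab_problem(slab, g1, g2, V0, order))
        J = V0 / (1 / g1 + L / SIGMA + 1 / g2)
        area = 20e-6 * 20e-6
        assert integrate_boundary_current(sol, "z0") == \
            pytest.approx(J * area, rel=1e-6)
        assert integrate_boundary_current(sol, "z1") == \
            pytest.approx(-J * area, rel=1e-6)
        # gradient-quadrature flux agrees within 1%
        assert gradient_boundary_current(sol, "z0") == \
            pytest.approx(J * area, rel=0.01)

    def test_zero_forcing_zero_field(self, slab):
        sol = solve_field(slab_problem(slab, 500.0, 2000.0, 0.0))
        assert np.max(np.abs(sol.u)) < 1e-15
        for tag in ("z0", "z1", "x0"):
            if tag in ("x0",):
                continue
            assert abs(integrate_boundary_current(sol, tag)) < 1e-18

    def test_superposition_and_linearity(self, slab):
        a = solve_field(slab_problem(slab, 500.0, 2000.0, 0.25))
        b = solve_field(slab_problem(slab, 500.0, 2000.0, 0.5))
        assert np.allclose(2 * a.u, b.u, atol=1e-12)

    def test_robin_to_insulating_limit(self, slab):
        sol = solve_field(slab_problem(slab, 1e-9, 2000.0, 1.0))
        assert abs(integrate_boundary_current(sol, "z0")) < 1e-12

    def test_all_neumann_rejected(self, slab):
        with pytest.raises(ValueError, match="robin or dirichlet"):
            FieldProblem(mesh=slab, conductivity=ConductivityMap(default=SIGMA),
                         bcs={"z0": BoundaryCondition.insulating()})


@pytest.fixture(scope="module")
def solution(shell):
    prob = FieldProblem(mesh=shell,
                        conductivity=ConductivityMap(default=SIGMA),
                        bcs={"inner": BoundaryCondition.robin(1e8, 1.0),
                             "outer": BoundaryCondition.dirichlet(0.0)},
                        element_order=2)
    return calibrate_stimulus(prob, "inner", 1e-6)


class TestPointSourceOracle:
    """Spherical shell: V(r) = I/(4 pi sigma) (1/r - 1/R_out)."""

    def test_matches_closed_form_within_2pct(self, solution, shell):
        V0, sol = solution
        I = 1e-6
        # sample along rays through mesh vertices, where the faceted sphere
        # carries no geometric radius deficit
        dirs = shell.nodes[:4]
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        for r in (10e-6, 50e-6, 200e-6, 1e-3):
            v = sol.evaluate(r * dirs).mean()
            exact = I / (4 * math.pi * SIGMA) * (1 / r - 1 / 5e-3)
            assert v == pytest.approx(exact, rel=0.02)

    def test_maximum_principle(self, solution, rng):
        """No interior sources: V lies between the boundary extremes."""
        _, sol = solution
        r = np.exp(rng.uniform(np.log(3e-6), np.log(4e-3), 200))
        d = rng.normal(size=(200, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        v = sol.evaluate(r[:, None] * d)
        vmax = sol.evaluate([[2.05e-6, 0, 0]])[0]
        assert np.all(v <= vmax * 1.001)
        assert np.all(v >= -1e-9)

    def test_conservation_between_boundaries(self, solution):
        _, sol = solution
        I_in = integrate_boundary_current(sol, "inner")
        I_out = integrate_boundary_current(sol, "outer")
        assert I_in + I_out == pytest.approx(0.0, abs=0.02 * abs(I_in))
        # gradient quadrature agrees with the consistent flux to a few %
        assert gradient_boundary_current(sol, "outer") == \
            pytest.approx(I_out, rel=0.05)

    def test_calibration_two_pass_delivers_target(self, solution):
        _, sol = solution
        # the larger electrode (outer) carries the calibrated current
        assert -integrate_boundary_current(sol, "outer") == \
            pytest.approx(1e-6, rel=5e-3)


class TestDiskAccessResistance:
    def test_quarter_sigma_a(self):
        a, R = 5e-6, 200e-6
        m = half_ball_mesh(a, R, seed=0)
        prob = FieldProblem(mesh=m, conductivity=ConductivityMap(default=SIGMA),
                            bcs={"disk": BoundaryCondition.dirichlet(1.0),
                                 "outer": BoundaryCondition.dirichlet(0.0)},
                            element_order=2)
        sol = solve_field(prob)
        I = -gradient_boundary_current(sol, "outer")
        exact = 1 / (4 * SIGMA * a) - 1 / (2 * math.pi * SIGMA * R)
        assert 1.0 / I == pytest.approx(exact, rel=0.05)


class TestSampling:
    def test_nodal_values_reproduced_exactly(self, slab):
        sol = solve_field(slab_problem(slab, 500.0, 2000.0, 0.5))
        nodes = slab.nodes[::7]
        v = sample_potential(sol, nodes)
        assert np.allclose(v, sol.u[::7], atol=1e-14)

    def test_point_outside_domain_reported(self, slab):
        sol = solve_field(slab_problem(slab, 500.0, 2000.0, 0.5))
        with pytest.raises(ValueError, match="outside"):
            sol.evaluate([[1.0, 1.0, 1.0]])

    def test_tsv_export(self, slab, tmp_path):
        sol = solve_field(slab_problem(slab, 500.0, 2000.0, 0.5))
        out = tmp_path / "pots.tsv"
        pts = slab.nodes[:5]
        v = sample_potential(sol, pts, export_path=out)
        data = np.loadtxt(out, skiprows=1)
        assert np.allclose(data[:, 3], v)


@pytest.fixture(scope="module")
def calibrated(mea_mesh, mea_params):
    stim = mea_params.central_electrode
    prob = FieldProblem(
        mesh=mea_mesh, conductivity=ConductivityMap(default=SIGMA),
        bcs={stim: BoundaryCondition.robin(500.0, V0=1.0),
             "ground_surface": BoundaryCondition.robin(500.0, 0.0)},
        element_order=2)
    V0, sol = calibrate_stimulus(prob, stim, -1e-6)
    return stim, V0, sol


class TestMEAField:

    def test_ground_return_matches_target(self, calibrated):
        _, _, sol = calibrated
        assert integrate_boundary_current(sol, "ground_surface") == \
            pytest.approx(1e-6, rel=0.02)

    def test_conservation_stim_vs_ground(self, calibrated):
        stim, _, sol = calibrated
        I_s = integrate_boundary_current(sol, stim)
        I_g = integrate_boundary_current(sol, "ground_surface")
        assert abs(I_s + I_g) < 0.02 * abs(I_s)

    def test_approximate_formula_within_20pct(self, calibrated, mea_mesh,
                                              mea_params):
        """sigma V0 / d * S (= g V0 S) vs the integrated current."""
        stim, V0, sol = calibrated
        I_approx = approx_electrode_current(sol.problem, stim, V0)
        I_int = integrate_boundary_current(sol, stim)
        assert I_approx == pytest.approx(I_int, rel=0.2)

    def test_profile_monotone_decay(self, calibrated, mea_params):
        stim, _, sol = calibrated
        cx, cy = mea_params.electrode_center(stim)
        ys = np.linspace(0, 120e-6, 41)
        pts = np.column_stack([np.full(41, cx), cy + ys, np.full(41, 50e-6)])
        v = np.abs(sol.evaluate(pts))
        # |V| decays away from the electrode center; allow 0.5% of the peak
        # for quadratic-interpolation wiggle between elements
        assert np.all(np.diff(v) < 5e-3 * v[0])
        assert v[-1] < 0.5 * v[0]

    def test_disconnected_electrode_calibration_error(self, slab):
        """A stimulation tag with no facets drives no current -> clear error."""
        from neurostimfem.mesh import Mesh
        import numpy as _np
        m = Mesh(nodes=slab.nodes, tets=slab.tets,
                 facet_tags={**slab.facet_tags,
                             "probe": _np.zeros((0, 3), dtype=int)})
        prob = FieldProblem(mesh=m, conductivity=ConductivityMap(default=SIGMA),
                            bcs={"probe": BoundaryCondition.robin(500.0, 1.0),
                                 "z1": BoundaryCondition.robin(2000.0, 0.0)},
                            element_order=1)
        with pytest.raises(RuntimeError, match="alibration"):
            calibrate_stimulus(prob, "probe", 1e-6)
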