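"""Whole-FEM thin-film solver: equilibrium, conservation, symmetry."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from neurostimfem import coupled
from neurostimfem.cable import Waveform
from neurostimfem.field import BoundaryCondition
from neurostimfem.geometry import NeuronGeometrySpec, box_with_capsule
from neurostimfem.membrane import MembraneParams, mS_per_cm2, ohm_cm, uF_per_cm2

PASSIVE = MembraneParams(cm=uF_per_cm2(1.0), gl=mS_per_cm2(1e-4), El=-65e-3)
EL = PASSIVE.El


@pytest.fixture(scope="module")
def capsule_mesh():
    """A 40-um capsule centered in a 60-um box (uniform-field fixture)."""
    spec = NeuronGeometrySpec(p0=(30e-6, 10e-6, 30e-6),
                              p1=(30e-6, 50e-6, 30e-6), fiber_diameter=2e-6)
    return spec, box_with_capsule((60e-6, 60e-6, 60e-6), spec, seed=1)


def uniform_field_problem(mesh, V_drive=10e-3, membrane=PASSIVE):
    bcs = {"y0": BoundaryCondition.robin(1e8, V0=1.0),
           "y1": BoundaryCondition.robin(1e8, V0=0.0)}
    return coupled.build_coupled_problem(mesh, 0.2, 1.0, membrane, bcs,
                                         stim_tag="y0", V0=V_drive)


class TestBuild:
    def test_membrane_dofs_duplicated(self, capsule_mesh):
        _, mesh = capsule_mesh
        prob = uniform_field_problem(mesh)
        n_mem = len(prob.mem_nodes)
        assert prob.ndof == prob.n_ext + prob.n_int
        # every membrane node appears in both blocks
        assert prob.n_ext + prob.n_int == \
            len(np.union1d(prob.ext_nodes, prob.int_nodes)) + n_mem

    def test_sigma_int_from_ra(self):
        assert 1.0 / ohm_cm(100.0) == pytest.approx(1.0)

    def test_missing_tags_rejected(self, capsule_mesh):
        _, mesh = capsule_mesh
        from neurostimfem.mesh import Mesh
        bare = Mesh(nodes=mesh.nodes, tets=mesh.tets,
                    facet_tags={k: v for k, v in mesh.facet_tags.items()
                                if k != "membrane"},
                    subdomain_tags=mesh.subdomain_tags)
        with pytest.raises(ValueError, match="membrane"):
            uniform_field_problem(bare)


class TestStep:
    def test_rest_is_equilibrium(self, capsule_mesh):
        _, mesh = capsule_mesh
        prob = uniform_field_problem(mesh)
        states = coupled.solve_transient(prob, Waveform.rect(0, 1e-3, 0.0),
                                         5e-5, 5e-4)
        end = states[-1]
        assert np.max(np.abs(end.V)) < 1e-12
        assert np.max(np.abs(end.Vint - EL)) < 1e-9

    def test_closed_membrane_current_balance(self, capsule_mesh):
        """Source-free intracellular domain: net Im integrates to ~0."""
        _, mesh = capsule_mesh
        prob = uniform_field_problem(mesh)
        state = coupled.initial_state(prob)
        dt = 5e-5
        for k in range(5):
            new = coupled.step(prob, state, f_t=1.0, dt=dt)
            net, absint = coupled.membrane_current_integrals(prob, new, state, dt)
            assert abs(net) < 0.01 * max(absint, 1e-30)
            state = new

    def test_passive_linearity(self, capsule_mesh):
        _, mesh = capsule_mesh
        w = Waveform.rect(0, 1e-3)
        a = coupled.solve_transient(uniform_field_problem(mesh, 10e-3), w,
                                    5e-5, 5e-4)[-1]
        b = coupled.solve_transient(uniform_field_problem(mesh, 20e-3), w,
                                    5e-5, 5e-4)[-1]
        pa = uniform_field_problem(mesh)
        assert np.allclose(b.Vint - EL, 2 * (a.Vint - EL), atol=1e-12)
        assert np.allclose(b.V, 2 * a.V, atol=1e-12)

    def test_uniform_field_antisymmetric_vm(self, capsule_mesh):
        """Axial uniform field polarizes a symmetric capsule antisymmetrically."""
        _, mesh = capsule_mesh
        prob = uniform_field_problem(mesh)
        end = coupled.solve_transient(prob, Waveform.rect(0, 1e-3), 5e-5,
                                      1e-3)[-1]
        vm = end.vm_membrane(prob) - EL
        nodes = mesh.nodes[prob.mem_nodes]
        mirror = nodes.copy()
        mirror[:, 1] = 60e-6 - nodes[:, 1]
        d, idx = cKDTree(nodes).query(mirror)
        resid = vm + vm[idx]
        assert np.abs(resid).max() < 0.03 * np.abs(vm).max()

    def test_gate_fields_bounded_active_run(self, capsule_mesh):
        _, mesh = capsule_mesh
        active = MembraneParams(cm=uF_per_cm2(1.0), gl=mS_per_cm2(0.3),
                                El=-65e-3, active=True)
        prob = uniform_field_problem(mesh, V_drive=50e-3, membrane=active)
        end = coupled.solve_transient(prob, Waveform.rect(0, 1e-3), 5e-5,
                                      5e-4)[-1]
        for g in (end.gates.n, end.gates.m, end.gates.h):
            assert np.all((g >= 0) & (g <= 1))


class TestProfiles:
    def test_profile_at_rest_is_el(self, capsule_mesh):
        _, mesh = capsule_mesh
        prob = uniform_field_problem(mesh)
        state = coupled.initial_state(prob)
        prof = coupled.extract_membrane_profile(prob, state, "bottom")
        assert np.allclose(prof.vm, EL, atol=1e-12)
        assert np.all(np.diff(prof.arclength) > 0)

    def test_bottom_top_sides_disjoint(self, capsule_mesh):
        _, mesh = capsule_mesh
        prob = uniform_field_problem(mesh)
        state = coupled.initial_state(prob)
        bot = coupled.extract_membrane_profile(prob, state, "bottom")
        top = coupled.extract_membrane_profile(prob, state, "top")
        assert len(bot.arclength) > 5 and len(top.arclength) > 5
        with pytest.raises(ValueError):
            coupled.extract_membrane_profile(prob, state, "sideways")
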