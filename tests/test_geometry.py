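"""Mesh generation: tagging, topology, quality, refinement."""

import math

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components
import scipy.sparse as sp

from neurostimfem.geometry import (MEAParams, NeuronGeometrySpec, GeometryError,
                                   build_mea_chamber, embed_neuron_surface,
                                   box_mesh, half_ball_mesh, refine_near,
                                   spherical_shell_mesh, MIN_TARGET_EDGE)
from neurostimfem.mesh import triangle_areas


class TestMEAParams:
    def test_sixty_electrodes(self, mea_params):
        assert len(mea_params.electrode_centers()) == 60

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MEAParams(electrode_diameter=200e-6)  # > pitch
        with pytest.raises(ValueError):
            MEAParams(ground_gap=0.0)

    def test_central_electrode_deterministic(self, mea_params):
        assert mea_params.central_electrode == "electrode_3_3"


class TestChamberMesh:
    def test_tag_census(self, mea_mesh):
        etags = [t for t in mea_mesh.facet_tags if t.startswith("electrode_")]
        assert len(etags) == 60
        assert "ground_surface" in mea_mesh.facet_tags
        assert "insulating" in mea_mesh.facet_tags

    def test_exterior_boundary_fully_tagged(self, mea_mesh):
        assert len(mea_mesh.tagged_untagged_boundary()) == 0

    def test_quality_and_invariants(self, mea_mesh):
        q = mea_mesh.check()   # raises on violation
        assert q.min_volume > 0
        assert 0 < q.min_dihedral_deg < 90

    def test_substrate_area_converges_to_disk(self, mea_params):
        analytic = math.pi * mea_params.chamber_radius ** 2

        def substrate_area(mesh):
            tris, _ = mesh.boundary_facets()
            cent = mesh.nodes[tris].mean(axis=1)
            bot = np.abs(cent[:, 2]) < 1e-9
            return triangle_areas(mesh.nodes, tris[bot]).sum()

        coarse = build_mea_chamber(mea_params, seed=0, h_max=3.0e-4)
        fine = build_mea_chamber(mea_params, seed=0, h_max=1.5e-4)
        err_c = abs(substrate_area(coarse) / analytic - 1)
        err_f = abs(substrate_area(fine) / analytic - 1)
        assert err_c < 0.02
        assert err_f < err_c

    def test_electrode_area_matches_disk(self, mea_mesh, mea_params):
        disk = math.pi * (mea_params.electrode_diameter / 2) ** 2
        for tag in ("electrode_3_3", "electrode_0_1"):
            assert mea_mesh.facet_area(tag) == pytest.approx(disk, rel=0.02)

    def test_monopolar_ground_disabled(self):
        params = MEAParams(ground_surface_enabled=False)
        mesh = build_mea_chamber(params, seed=0)
        assert "ground_surface" not in mesh.facet_tags
        assert len(mesh.tagged_untagged_boundary()) == 0


class TestNeuronEmbedding:
    def test_membrane_watertight(self, fiber_mesh):
        assert fiber_mesh.is_watertight("membrane")

    def test_interface_separates_subdomains(self, fiber_mesh):
        owners = fiber_mesh.facet_owners(fiber_mesh.facet_tags["membrane"])
        intra = set(fiber_mesh.subdomain_tags["intracellular"].tolist())
        for pair in owners:
            assert len(pair) == 2
            assert (pair[0] in intra) != (pair[1] in intra)

    def test_capsule_volume(self, fiber_mesh, fiber_spec):
        vol = fiber_mesh.subdomain_volume("intracellular")
        assert vol == pytest.approx(fiber_spec.analytic_volume(), rel=0.03)

    def test_soma_single_connected_intracellular(self, mea_params):
        stim = mea_params.central_electrode
        cx, cy = mea_params.electrode_center(stim)
        spec = NeuronGeometrySpec.fiber_above((cx, cy), 50e-6, 260e-6, 2e-6,
                                              soma_diameter=20e-6)
        mesh = embed_neuron_surface(mea_params, spec, seed=0, h_stim=5e-6)
        intra = mesh.subdomain_tags["intracellular"]
        # adjacency of intracellular tets through shared faces
        sub = {int(t): k for k, t in enumerate(intra)}
        faces = {}
        rows, cols = [], []
        local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        for t in intra:
            for lf in local:
                key = tuple(sorted(mesh.tets[t][list(lf)]))
                if key in faces:
                    rows.append(sub[int(t)]); cols.append(faces[key])
                else:
                    faces[key] = sub[int(t)]
        n = len(intra)
        A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        ncomp, _ = connected_components(A + A.T, directed=False)
        assert ncomp == 1

    def test_neuron_touching_boundary_rejected(self, mea_params):
        spec = NeuronGeometrySpec.fiber_above((0, 0), 0.5e-6, 260e-6, 2e-6)
        with pytest.raises(GeometryError):
            embed_neuron_surface(mea_params, spec, seed=0)

    def test_soma_must_exceed_fiber(self):
        with pytest.raises(ValueError):
            NeuronGeometrySpec.fiber_above((0, 0), 50e-6, 260e-6, 2e-6,
                                           soma_diameter=1e-6)


class TestRefineNear:
    def test_noop_when_already_satisfied(self, mea_mesh):
        out = refine_near(mea_mesh, ((0, 0, 5e-4), 1e-4), target_edge=1.0)
        assert out is mea_mesh

    def test_electrode_refined_to_target(self, mea_params):
        mesh = build_mea_chamber(mea_params, seed=0, h_stim=8e-6)
        tag = mea_params.central_electrode
        out = refine_near(mesh, tag, 5e-6)
        assert out.max_edge_of_facets(out.facet_tags[tag]) <= 5e-6

    def test_below_minimum_refused(self, mea_mesh):
        with pytest.raises(ValueError, match="minimum"):
            refine_near(mea_mesh, ((0, 0, 0), 1e-5), MIN_TARGET_EDGE / 10)


class TestStructuredMeshes:
    def test_box_mesh_volume_and_tags(self):
        m = box_mesh(1e-5, 2e-5, 3e-5, 3, 4, 5)
        assert m.volumes().sum() == pytest.approx(6e-15, rel=1e-12)
        assert set(m.facet_tags) == {"x0", "x1", "y0", "y1", "z0", "z1"}
        assert m.facet_area("z0") == pytest.approx(2e-10, rel=1e-12)
        m.check()

    def test_shell_mesh_conforming(self):
        m = spherical_shell_mesh(1e-6, 1e-5, subdivisions=1, n_layers=5)
        m.check()
        vol = 4 / 3 * math.pi * ((1e-5) ** 3 - (1e-6) ** 3)
        # inscribed polyhedral shell: a few % below the analytic volume
        assert m.volumes().sum() == pytest.approx(vol, rel=0.1)
        assert m.is_watertight("inner") and m.is_watertight("outer")

    def test_half_ball_tags(self):
        m = half_ball_mesh(5e-6, 100e-6, seed=0)
        m.check()
        assert set(m.facet_tags) == {"disk", "plane", "outer"}
        assert m.facet_area("disk") == pytest.approx(math.pi * 25e-12, rel=0.02)
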