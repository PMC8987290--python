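"""Elasticity correctness: element identities, patch test, bar solution,
contact behavior, DVF rasterization and warping."""

import numpy as np
import pytest
import trimesh

from spacersim import fem, meshing, phantom
from spacersim.grid import VoxelGrid
from spacersim.meshing import TetModel, structured_box_tet_model

MATS = {"tissue": fem.Material(5.0, 0.3)}


def single_tet_model():
    nodes = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    return TetModel(
        nodes=nodes,
        tets=np.array([[0, 1, 2, 3]]),
        material_tag=np.array([1]),
        tag_names={1: "tissue"},
    )


class TestAssembly:
    def test_rigid_translation_gives_zero_force(self):
        K = fem.assemble_stiffness(single_tet_model(), MATS).toarray()
        for axis in range(3):
            u = np.zeros(12)
            u[axis::3] = 1.0  # uniform translation
            np.testing.assert_allclose(K @ u, 0.0, atol=1e-12)

    def test_symmetry(self):
        model = structured_box_tet_model((6.0, 4.0, 4.0), h=2.0)
        K = fem.assemble_stiffness(model, MATS)
        diff = (K - K.T).toarray()
        assert np.abs(diff).max() <= 1e-10 * np.abs(K.toarray()).max()

    def test_positive_semidefinite_with_rigid_nullspace(self):
        K = fem.assemble_stiffness(single_tet_model(), MATS).toarray()
        w = np.linalg.eigvalsh(K)
        assert w[0] >= -1e-10
        assert np.sum(np.abs(w) < 1e-9) == 6  # 3 translations + 3 rotations

    def test_missing_material_raises(self):
        model = single_tet_model()
        with pytest.raises(KeyError):
            fem.assemble_stiffness(model, {"other": fem.Material(1.0, 0.3)})


class TestBarAndPatch:
    def test_uniaxial_bar_reaction(self):
        # roller-supported bar: exact solution is homogeneous uniaxial
        # stress, reaction = E A delta / L independent of the mesh
        E, nu, L, W, H, delta = 5.0, 0.45, 20.0, 4.0, 4.0, 1.0
        model = structured_box_tet_model((L, W, H), h=2.0)
        K = fem.assemble_stiffness(model, {"tissue": fem.Material(E, nu)})
        x = model.nodes[:, 0]
        left = np.flatnonzero(np.isclose(x, 0.0))
        right = np.flatnonzero(np.isclose(x, L))
        corner = left[np.argmin(model.nodes[left, 1] + model.nodes[left, 2])]
        dof = np.concatenate(
            [3 * left, 3 * right, [3 * corner + 1, 3 * corner + 2]]
        )
        vals = np.concatenate(
            [np.zeros(left.size), np.full(right.size, delta), [0.0, 0.0]]
        )
        u = fem.solve_dirichlet(K, dof, vals)
        reaction = float(np.sum((K @ u)[3 * right]))
        assert reaction == pytest.approx(E * W * H * delta / L, rel=0.02)

    def test_patch_reproduces_affine_field(self):
        model = structured_box_tet_model((6.0, 6.0, 6.0), h=2.0)
        A = np.array([[0.01, 0.002, 0.0], [0.0, -0.005, 0.003], [0.001, 0.0, 0.008]])
        b = np.array([0.1, -0.2, 0.05])
        exact = model.nodes @ A.T + b
        on_boundary = np.any(
            np.isclose(model.nodes, 0.0) | np.isclose(model.nodes, 6.0), axis=1
        )
        bidx = np.flatnonzero(on_boundary)
        dof = (3 * bidx[:, None] + np.arange(3)).ravel()
        K = fem.assemble_stiffness(model, MATS)
        u = fem.solve_dirichlet(K, dof, exact[bidx].ravel()).reshape(-1, 3)
        np.testing.assert_allclose(u, exact, rtol=0, atol=1e-8 * np.abs(exact).max())


def _slab_and_dummy():
    slab = structured_box_tet_model((30.0, 30.0, 6.0), h=2.0)
    bottom = np.flatnonzero(np.isclose(slab.nodes[:, 2], 0.0))
    slab.node_sets["base_fixed"] = bottom
    dummy = structured_box_tet_model((4.0, 4.0, 4.0), h=2.0, origin=(100.0, 100.0, 100.0))
    dummy.node_sets["pin"] = np.array([0])
    return slab, dummy


class TestInsertion:
    def test_no_contact_means_no_displacement(self):
        slab, dummy = _slab_and_dummy()
        ball = trimesh.creation.icosphere(subdivisions=2, radius=4.0)
        ball.apply_translation([15.0, 15.0, 30.0])  # far above the slab
        plan = fem.InsertionPlan(ball, [0, 0, -1.0], travel_mm=2.0, n_steps=4)
        disp, _ = fem.solve_insertion(slab, dummy, plan, MATS)
        assert np.abs(disp["duodenum"]).max() == 0.0

    def test_sphere_indentation_depth_and_decay(self):
        slab, dummy = _slab_and_dummy()
        ball = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        # final position: centre 1 mm above the surface -> lowest point
        # dips 4 mm into the slab top (z = 6)
        ball.apply_translation([15.0, 15.0, 6.0 + 1.0 - 0.0])
        plan = fem.InsertionPlan(ball, [0, 0, -1.0], travel_mm=5.0, n_steps=5)
        disp, info = fem.solve_insertion(slab, dummy, plan, MATS)
        u = disp["duodenum"]
        top = np.isclose(slab.nodes[:, 2], 6.0)
        dz = -u[:, 2]
        assert 3.0 <= dz[top].max() <= 4.2  # ~4 mm indentation
        # decays with lateral distance from the indenter axis
        r = np.linalg.norm(slab.nodes[:, :2] - [15.0, 15.0], axis=1)
        near = top & (r < 4)
        far = top & (r > 12)
        assert dz[near].mean() > 5 * max(dz[far].mean(), 1e-9)
        # fixed base never moves
        assert np.abs(u[slab.node_sets["base_fixed"]]).max() == 0.0
        # strain energy grows monotonically over increments
        en = info["energy"]["duodenum"]
        assert all(b >= a - 1e-9 for a, b in zip(en, en[1:]))

    def test_cap_violation_aborts(self):
        slab, dummy = _slab_and_dummy()
        # wide flat punch whose final face sits 10 mm below the slab top:
        # nearest-point projection then demands ~10 mm of displacement
        punch = trimesh.creation.box(extents=(20.0, 20.0, 8.0))
        punch.apply_translation([15.0, 15.0, 0.0])  # bottom face at z = -4
        plan = fem.InsertionPlan(punch, [0, 0, -1.0], travel_mm=12.0, n_steps=4)
        with pytest.raises(fem.FEMError, match="cap"):
            fem.solve_insertion(slab, dummy, plan, MATS, displacement_cap_mm=5.0)


class TestDVF:
    GRID = VoxelGrid((30, 30, 30), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

    def test_zero_displacements_zero_field(self):
        model = structured_box_tet_model((8.0, 8.0, 8.0), h=2.0, origin=(10, 10, 10))
        dvf = fem.displacements_to_dvf([(model, np.zeros((model.n_nodes, 3)))], self.GRID)
        assert np.abs(dvf.displacement).max() == 0.0

    def test_field_matches_node_displacement_at_node(self):
        model = structured_box_tet_model((8.0, 8.0, 8.0), h=2.0, origin=(10, 10, 10))
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1.0, (model.n_nodes, 3))
        dvf = fem.displacements_to_dvf([(model, u)], self.GRID)
        # node (12, 12, 12) sits exactly on a voxel centre
        k = int(np.flatnonzero(np.all(model.nodes == [12.0, 12.0, 12.0], axis=1))[0])
        np.testing.assert_allclose(dvf.displacement[12, 12, 12], u[k], atol=1e-5)

    def test_zero_on_border_and_beyond_cutoff(self):
        model = structured_box_tet_model((4.0, 4.0, 4.0), h=2.0, origin=(13, 13, 13))
        u = np.ones((model.n_nodes, 3))
        dvf = fem.displacements_to_dvf([(model, u)], self.GRID, cutoff_mm=6.0)
        assert np.abs(dvf.displacement[0]).max() == 0.0
        assert np.abs(dvf.displacement[29]).max() == 0.0
        mag = dvf.magnitude_mm()
        far_voxel = mag[2, 2, 2]  # ~19 mm from the block
        assert far_voxel == 0.0


class TestWarp:
    def test_zero_dvf_is_identity(self, phantom_case):
        s = phantom_case
        dvf = fem.DeformationField(
            grid=s.grid, displacement=np.zeros((*s.grid.shape, 3))
        )
        out = fem.warp_structures(s, dvf)
        for name in s.names():
            np.testing.assert_array_equal(out[name], s[name])

    def test_translation_moves_structures(self):
        s = phantom.generate_phantom(2)
        disp = np.zeros((*s.grid.shape, 3), dtype=np.float32)
        inner = np.zeros(s.grid.shape, bool)
        inner[6:-6, 6:-6, 6:-6] = True
        disp[inner, 0] = 4.0  # +4 mm = +2 voxels along x
        dvf = fem.DeformationField(grid=s.grid, displacement=disp)
        out = fem.warp_structures(s, dvf)
        expected = np.zeros_like(s["GTV"])
        expected[2:, :, :] = s["GTV"][:-2, :, :]
        overlap = (out["GTV"] & expected).sum() / max(expected.sum(), 1)
        assert overlap > 0.9
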