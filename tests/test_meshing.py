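"""Surface extraction, smoothing, tetrahedralization, boundary tagging."""

import numpy as np
import pytest

from spacersim import meshing, phantom
from spacersim.grid import VoxelGrid

GRID = VoxelGrid((40, 40, 40), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


def cube_mask(half=10):
    m = np.zeros(GRID.shape, bool)
    m[10:30, 10:30, 10:30] = True
    return m


def sphere_mask(r=10.0, r_in=None):
    xx, yy, zz = np.meshgrid(*[np.arange(40) - 19.5] * 3, indexing="ij")
    rr = np.sqrt(xx**2 + yy**2 + zz**2)
    m = rr <= r
    if r_in is not None:
        m &= rr >= r_in
    return m


class TestMaskToSurface:
    def test_cube_volume_within_five_percent(self):
        mesh = meshing.mask_to_surface(cube_mask(), GRID)
        assert mesh.is_watertight
        assert mesh.volume == pytest.approx(8000.0, rel=0.05)

    def test_sphere_area_within_five_percent(self):
        mesh = meshing.mask_to_surface(sphere_mask(), GRID)
        assert mesh.area == pytest.approx(4 * np.pi * 100, rel=0.05)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            meshing.mask_to_surface(np.zeros(GRID.shape, bool), GRID)

    def test_multi_component_keeps_largest_with_warning(self):
        m = cube_mask()
        m[2:4, 2:4, 2:4] = True
        with pytest.warns(UserWarning, match="connected components"):
            mesh = meshing.mask_to_surface(m, GRID)
        assert mesh.volume == pytest.approx(8000.0, rel=0.05)


class TestSmoothing:
    def test_volume_preserved_within_one_percent(self):
        mesh = meshing.mask_to_surface(sphere_mask(), GRID)
        sm = meshing.smooth_surface(mesh, iterations=20)
        assert abs(sm.volume - mesh.volume) / mesh.volume <= 0.01

    def test_zero_iterations_is_identity(self):
        mesh = meshing.mask_to_surface(sphere_mask(), GRID)
        sm = meshing.smooth_surface(mesh, iterations=0)
        np.testing.assert_array_equal(sm.vertices, mesh.vertices)

    def test_jittered_sphere_gets_rounder(self):
        mesh = meshing.mask_to_surface(sphere_mask(), GRID)
        rng = np.random.default_rng(0)
        noisy = mesh.copy()
        noisy.vertices = noisy.vertices + rng.normal(0, 0.5, noisy.vertices.shape)
        center = noisy.vertices.mean(axis=0)

        def radial_rms(m):
            r = np.linalg.norm(m.vertices - center, axis=1)
            return np.std(r)

        sm = meshing.smooth_surface(noisy, iterations=20)
        assert radial_rms(sm) < radial_rms(noisy)


class TestTetrahedralize:
    def test_cube_volume_and_orientation(self):
        mesh = meshing.mask_to_surface(cube_mask(), GRID)
        model = meshing.tetrahedralize(mesh, max_edge_mm=3.0)
        assert model.volume_mm3 == pytest.approx(mesh.volume, rel=0.05)
        assert np.all(model.tet_volumes() > 0)

    def test_refinement_does_not_worsen_volume(self):
        mesh = meshing.mask_to_surface(sphere_mask(), GRID)
        coarse = meshing.tetrahedralize(mesh, max_edge_mm=5.0)
        fine = meshing.tetrahedralize(mesh, max_edge_mm=2.5)
        err = lambda m: abs(m.volume_mm3 - mesh.volume) / mesh.volume
        assert err(fine) <= err(coarse) + 0.01


class TestHollow:
    def test_concentric_spheres_wall_volume(self):
        outer = meshing.mask_to_surface(sphere_mask(12.5), GRID)
        inner = meshing.mask_to_surface(sphere_mask(10.0), GRID)
        model = meshing.hollow_tetrahedralize(outer, inner, max_edge_mm=3.0)
        analytic = 4 / 3 * np.pi * (12.5**3 - 10**3)
        assert model.volume_mm3 == pytest.approx(analytic, rel=0.08)

    def test_no_node_strictly_inside_inner_surface(self):
        outer = meshing.mask_to_surface(sphere_mask(12.5), GRID)
        inner = meshing.mask_to_surface(sphere_mask(10.0), GRID)
        model = meshing.hollow_tetrahedralize(outer, inner, max_edge_mm=3.0)
        center = np.array([19.5, 19.5, 19.5])
        radii = np.linalg.norm(model.nodes - center, axis=1)
        assert radii.min() >= 10.0 - 1.0  # nodes on/outside the inner surface

    def test_intersecting_surfaces_rejected(self):
        a = meshing.mask_to_surface(sphere_mask(10.0), GRID)
        b = a.copy()
        b.vertices = b.vertices + np.array([8.0, 0.0, 0.0])
        b.metadata["field_origin"] = b.metadata["field_origin"] + np.array([8.0, 0.0, 0.0])
        with pytest.raises(meshing.MeshingError):
            meshing.hollow_tetrahedralize(a, b)

    def test_duodenal_wall_gap_in_band(self, phantom_case):
        s = phantom_case
        outer = meshing.mask_to_surface(s["duodenum"], s.grid, step_size=2)
        inner = meshing.mask_to_surface(s["duodenum_lumen"], s.grid, step_size=2)
        model = meshing.hollow_tetrahedralize(outer, inner, max_edge_mm=5.0)
        # wall built to 2.4-2.9 mm; surface discretisation adds ~half a voxel
        assert 1.8 <= model.wall_thickness_mm <= 3.6


class TestRoundTrip:
    def test_mesh_mask_mesh_dsc(self):
        from spacersim.geometry import dsc

        mask = sphere_mask(11.0)
        mesh = meshing.mask_to_surface(mask, GRID)
        pts = GRID.dense_coordinates().reshape(-1, 3)
        back = meshing.points_inside(mesh, pts).reshape(GRID.shape)
        assert dsc(mask, back) >= 0.95


class TestBoundarySets:
    def test_phantom_tagging(self, phantom_case):
        from scipy import ndimage

        s = phantom_case
        outer = meshing.mask_to_surface(s["duodenum"], s.grid, step_size=2)
        inner = meshing.mask_to_surface(s["duodenum_lumen"], s.grid, step_size=2)
        duo = meshing.hollow_tetrahedralize(outer, inner, max_edge_mm=5.0)
        hop = meshing.tetrahedralize(
            meshing.mask_to_surface(s["HOP"], s.grid, step_size=2), 5.0
        )
        duo, hop = meshing.tag_boundary_sets(
            duo, hop, s["stomach"], s.grid,
            {k: s[k] for k in ("D1", "D2", "D3", "D4")},
            lumen_mask=s["duodenum_lumen"],
        )
        for name in ("D3_inferior_fixed", "near_stomach_fixed"):
            assert duo.node_sets[name].size > 0
        for name in ("HOP_superior_margin", "HOP_inferior_margin"):
            assert hop.node_sets[name].size > 0
        # tagged near-stomach nodes really are within 2 mm of the stomach
        edt = ndimage.distance_transform_edt(~s["stomach"], sampling=s.grid.spacing)
        ijk = s.grid.world_to_index(duo.nodes[duo.node_sets["near_stomach_fixed"]])
        dist = ndimage.map_coordinates(edt, ijk.T, order=1)
        # surface distance = centre distance minus the half-voxel offset
        assert np.all(dist - 0.5 * np.mean(s.grid.spacing) <= 2.0 + 1e-6)
        # section disjointness: no fixed D3 node belongs to D1
        assert not np.any(duo.node_sections[duo.node_sets["D3_inferior_fixed"]] == "D1")

    def test_distant_stomach_raises_named_error(self, phantom_case):
        s = phantom_case
        outer = meshing.mask_to_surface(s["duodenum"], s.grid, step_size=2)
        inner = meshing.mask_to_surface(s["duodenum_lumen"], s.grid, step_size=2)
        duo = meshing.hollow_tetrahedralize(outer, inner, max_edge_mm=5.0)
        hop = meshing.tetrahedralize(
            meshing.mask_to_surface(s["HOP"], s.grid, step_size=2), 5.0
        )
        far_stomach = np.zeros(s.grid.shape, bool)
        far_stomach[0:3, 0:3, 0:3] = True
        with pytest.raises(meshing.ConfigurationError, match="near_stomach_fixed"):
            meshing.tag_boundary_sets(
                duo, hop, far_stomach, s.grid,
                {k: s[k] for k in ("D1", "D2", "D3", "D4")},
            )


def test_structured_box_model_volume():
    model = meshing.structured_box_tet_model((10.0, 6.0, 4.0), h=2.0)
    assert model.volume_mm3 == pytest.approx(240.0, rel=1e-9)
    assert np.all(model.tet_volumes() > 0)
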