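"""Lofting, voxelization, pruning, sectioning, Hausdorff, registration."""

import numpy as np
import pytest
import trimesh

from coroflow.geomkit import (PruneAction, PruneSpec, extract_subtree,
                              hausdorff, landmark_cartesian_distance,
                              loft_mesh, prune, register_npoint,
                              section_centerline, surface_distance, voxelize)
from coroflow.vasctree import polyline_arclength
from tests.conftest import straight_tube_tree


@pytest.fixture(scope="module")
def tube_surface():
    return loft_mesh(straight_tube_tree(), pitch=0.1)


@pytest.fixture(scope="module")
def left_surface(left_tree):
    return loft_mesh(left_tree)


class TestLoft:
    def test_cylinder_lateral_area(self, tube_surface):
        """Lateral surface area within 2% of 2*pi*R*L."""
        lateral = tube_surface.area() - sum(np.pi * c.radius ** 2
                                            for c in tube_surface.caps)
        assert lateral == pytest.approx(2 * np.pi * 1.5 * 20.0, rel=0.02)

    def test_watertight(self, tube_surface, left_surface):
        assert tube_surface.is_watertight()
        assert left_surface.is_watertight()

    def test_opening_count(self, left_tree, left_surface):
        # one inlet plus one outlet per open distal end
        assert left_surface.n_openings() == 1 + left_tree.n_outlets()

    def test_single_branch_three_openings(self):
        tree = straight_tube_tree()
        from coroflow.vasctree import VesselSegment
        n = 11
        pts = np.column_stack([np.linspace(0, 8, n), np.zeros(n),
                               np.linspace(10, 16, n)])
        tree.segments.append(VesselSegment(1, "branch", pts, np.full(n, 0.8),
                                           parent_id=0,
                                           parent_arclength_fraction=0.5))
        sm = loft_mesh(tree)
        assert sm.n_openings() == 3
        assert sm.is_watertight()

    def test_face_labels_cover_segments(self, left_tree, left_surface):
        assert set(left_surface.face_labels) == {s.name for s in left_tree.segments}

    def test_self_intersection_detected(self):
        from coroflow.vasctree import VesselSegment, VesselTree
        n = 9
        a = np.column_stack([np.linspace(0, 20, n), np.zeros(n), np.zeros(n)])
        # a second, unrelated segment passing right through the first
        b = np.column_stack([np.full(n, 10.0), np.linspace(-5, 5, n),
                             np.linspace(14.9, 15.1, n) * 0 + np.linspace(-1, 1, n)])
        t = VesselTree([
            VesselSegment(0, "A", a, np.full(n, 1.5)),
            VesselSegment(1, "B", b, np.full(n, 1.0), parent_id=0,
                          parent_arclength_fraction=0.01),
        ], 0)
        with pytest.raises(ValueError, match="intersect"):
            loft_mesh(t)


class TestVoxelize:
    def test_cylinder_fluid_count(self, tube_surface):
        """Fluid voxel count within 5% of pi R^2 L / h^3."""
        h = 0.15
        grid = voxelize(tube_surface, h)
        expected = np.pi * 1.5 ** 2 * 20.0 / h ** 3
        assert grid.n_fluid() == pytest.approx(expected, rel=0.05)

    def test_insufficient_resolution_rejected(self, tube_surface):
        with pytest.raises(ValueError, match="resolution"):
            voxelize(tube_surface, 2.0)

    def test_single_connected_component(self, left_surface):
        from scipy import ndimage
        grid = voxelize(left_surface, 0.25)
        _, n = ndimage.label(grid.fluid, structure=np.ones((3, 3, 3), int))
        assert n == 1

    def test_volume_convergence(self, tube_surface):
        """Voxelized volume error decreases as h decreases (first order)."""
        vol_mesh = tube_surface.volume()
        errs = []
        for h in [0.4, 0.25, 0.15]:
            grid = voxelize(tube_surface, h)
            errs.append(abs(grid.n_fluid() * h ** 3 - vol_mesh) / vol_mesh)
        assert errs[2] < errs[0]

    def test_outlets_labeled(self, left_tree, left_surface):
        grid = voxelize(left_surface, 0.25)
        assert set(grid.outlet_labels.values()) == \
            {s.name for s in left_tree.terminal_segments()}
        assert grid.inlet_mask.sum() > 0

    def test_save_load_roundtrip(self, left_surface, tmp_path):
        grid = voxelize(left_surface, 0.3)
        p = tmp_path / "grid.npz"
        grid.save(p)
        from coroflow.geomkit import VoxelGrid
        back = VoxelGrid.load(p)
        np.testing.assert_array_equal(back.fluid, grid.fluid)
        assert back.outlet_labels == grid.outlet_labels
        assert back.cap_axis == grid.cap_axis


class TestPrune:
    def test_empty_spec_identity(self, left_tree):
        out = prune(left_tree, PruneSpec())
        for a, b in zip(left_tree.segments, out.segments):
            np.testing.assert_array_equal(a.points, b.points)
            np.testing.assert_array_equal(a.radii, b.radii)

    def test_remove_all_side_branches(self, left_tree):
        """Removing every LAD side branch gives the single-conduit model;
        the outlet count drops by the number removed."""
        diags = [s.name for s in left_tree.segments if s.name.startswith("Diag")]
        out = prune(left_tree, PruneSpec.remove(*diags))
        assert out.n_outlets() == left_tree.n_outlets() - len(diags)
        np.testing.assert_array_equal(out.segment("LAD").points,
                                      left_tree.segment("LAD").points)

    def test_root_not_removable(self, left_tree):
        with pytest.raises(ValueError, match="root"):
            prune(left_tree, PruneSpec.remove("LM"))

    def test_idempotent(self, left_tree):
        spec = PruneSpec.remove("Diag1")
        once = prune(left_tree, spec)
        twice = prune(once, PruneSpec())
        assert [s.name for s in once.segments] == [s.name for s in twice.segments]

    def test_commutes_on_disjoint_branches(self, left_tree):
        a = prune(prune(left_tree, PruneSpec.remove("Diag1")),
                  PruneSpec.remove("OM1"))
        b = prune(prune(left_tree, PruneSpec.remove("OM1")),
                  PruneSpec.remove("Diag1"))
        assert [s.name for s in a.segments] == [s.name for s in b.segments]
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_truncate(self, left_tree):
        lad_len = left_tree.segment("LAD").length
        out = prune(left_tree, PruneSpec([PruneAction("LAD", "truncate",
                                                      at_mm=lad_len / 2)]))
        assert out.segment("LAD").length == pytest.approx(lad_len / 2, rel=1e-6)

    def test_pruned_volume_matches_frustum_oracle(self, left_tree):
        """Lumen volume drop from pruning equals the sum of the pruned
        branches' conical-frustum volumes within 2%."""
        surface_full = loft_mesh(left_tree)
        out = prune(left_tree, PruneSpec.remove("Diag1", "OM1"))
        surface_pruned = loft_mesh(out)

        def frustum_volume(seg):
            arc = polyline_arclength(seg.points)
            r = seg.radii
            # independent oracle: sum of conical frusta between samples
            return float(np.sum(np.pi / 3 * np.diff(arc)
                                * (r[:-1] ** 2 + r[:-1] * r[1:] + r[1:] ** 2)))

        pruned_vol = sum(frustum_volume(left_tree.segment(n))
                         for n in ("Diag1", "OM1"))
        got = surface_full.volume() - surface_pruned.volume()
        # junction blending means the removed volume is slightly less than
        # the full frusta; allow 2% of total plus the ostial overlap
        overlap = sum(np.pi * left_tree.segment(n).radii[0] ** 3 * 2
                      for n in ("Diag1", "OM1"))
        assert abs(got - pruned_vol) <= 0.02 * surface_full.volume() + overlap

    def test_extract_subtree(self, left_tree):
        sub = extract_subtree(left_tree, "LAD")
        assert sub.root.name == "LAD"
        assert all(s.name.startswith(("LAD", "Diag")) for s in sub.segments)
        sub.validate(check_taper=False)


class TestSections:
    def test_count_single_segment(self):
        tree = straight_tube_tree(length=30.0, n=31)
        s = section_centerline(tree, 0.3)
        assert len(s) == 101  # floor(30/0.3)+1

    def test_spacing_uniform_smooth_curve(self):
        """Consecutive centerpoint distances within 1% of 0.3 mm on a
        finely sampled smooth helix."""
        from coroflow.vasctree import VesselSegment, VesselTree
        t = np.linspace(0, 4 * np.pi, 800)
        pts = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 2 * t])
        tree = VesselTree([VesselSegment(0, "helix", pts,
                                         np.full(len(t), 1.5))], 0)
        s = section_centerline(tree, 0.3)
        d = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        assert np.all(np.abs(d - 0.3) < 0.3 * 0.01)

    def test_spacing_on_generated_tree(self, left_tree):
        # generated centerlines are polylines: points sit at exact arclength
        # multiples, so chords can only come up short where the curve kinks,
        # never long; the shortfall stays small relative to the spacing
        s = section_centerline(left_tree, 0.3)
        for name in {x for x in s.labels}:
            ids = s.for_segment(name)
            d = np.linalg.norm(np.diff(s.points[ids], axis=0), axis=1)
            assert np.all(d <= 0.3 + 1e-9)
            assert np.all(d > 0.3 * 0.9)

    def test_about_2000_sections_at_600mm(self):
        """~0.3 mm sectioning yields about 2000 sections per 600 mm tree."""
        tree = straight_tube_tree(length=600.0, n=601, radius=2.0)
        s = section_centerline(tree, 0.3)
        assert abs(len(s) - 2000) <= 10


class TestHausdorff:
    def test_identity_zero(self):
        s = trimesh.creation.icosphere(subdivisions=3)
        assert hausdorff(s, s, n_samples=2000) < 1e-9

    def test_two_unit_spheres(self):
        """Unit spheres 3 apart: symmetric HD = 3.0 (analytic surface
        oracle: farthest point of A is 4 from B's center, minus radius 1)."""
        a = trimesh.creation.icosphere(subdivisions=4)
        b = trimesh.creation.icosphere(subdivisions=4)
        b.apply_translation([3.0, 0.0, 0.0])
        d = hausdorff(a, b, n_samples=8000, seed=0)
        assert d == pytest.approx(3.0, abs=0.02)

    def test_symmetry(self, left_surface, tube_surface):
        d1 = hausdorff(left_surface, tube_surface, n_samples=2000, seed=1)
        d2 = hausdorff(tube_surface, left_surface, n_samples=2000, seed=1)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_surface_distance_exact_on_sphere(self):
        s = trimesh.creation.icosphere(subdivisions=4)
        pts = np.array([[2.0, 0, 0], [0, 0, 0], [0, 3.0, 0]])
        d = surface_distance(pts, s)
        np.testing.assert_allclose(d, [1.0, 1.0, 2.0], atol=5e-3)


class TestRegistration:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        tf = register_npoint(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)
        assert tf.rmsd < 1e-12

    def test_recovers_applied_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 3))
        ang = np.deg2rad(30)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        t = np.array([1.0, 2.0, 3.0])
        b = a @ rot.T + t
        tf = register_npoint(a, b)
        np.testing.assert_allclose(tf.rotation, rot, atol=1e-6)
        np.testing.assert_allclose(tf.translation, t, atol=1e-6)
        np.testing.assert_allclose(tf.apply(a), b, atol=1e-9)

    def test_noisy_rmsd_matches_residual_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(12, 3))
        b = a + rng.normal(0, 0.1, size=a.shape)
        tf = register_npoint(a, b)
        resid = np.sqrt(((tf.apply(a) - b) ** 2).sum(axis=1).mean())
        assert tf.rmsd == pytest.approx(resid, rel=1e-12)

    def test_collinear_rejected(self):
        a = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            register_npoint(a, a)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            register_npoint(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLandmarks:
    def test_identical_zero(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        rep = landmark_cartesian_distance(pts, pts)
        assert rep["mean_mm"] == 0.0

    def test_pythagoras(self):
        rep = landmark_cartesian_distance(np.zeros((1, 3)),
                                          np.array([[3.0, 4.0, 0.0]]))
        assert rep["distances_mm"][0] == pytest.approx(5.0)

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            landmark_cartesian_distance(np.zeros((3, 3)), np.zeros((4, 3)))
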