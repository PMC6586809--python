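"""Generator, stenosis and projection behavior."""

import numpy as np
import pytest

from coroflow.vasctree import (GantryGeometry, GantryView, StenosisSpec,
                               TreeParams, degrade_projection, generate_tree,
                               apply_stenosis, project_tree,
                               stenosis_diameter_profile)


class TestGenerator:
    def test_left_template_topology(self):
        params = TreeParams(n_diagonals=3, n_marginals=2)
        tree = generate_tree("left", params, seed=7)
        assert len(tree.segments) == 8
        assert tree.n_outlets() == 7
        names = {s.name for s in tree.segments}
        assert {"LM", "LAD", "LCx"} <= names
        assert tree.root.name == "LM"

    def test_right_template(self):
        tree = generate_tree("right", TreeParams(n_rca_branches=2), seed=3)
        assert tree.root.name == "RCA"
        assert tree.n_outlets() == 3

    def test_seed_determinism(self):
        params = TreeParams(n_diagonals=3, n_marginals=2)
        a = generate_tree("left", params, seed=7)
        b = generate_tree("left", params, seed=7)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.radii, sb.radii)

    def test_different_seeds_differ(self):
        a = generate_tree("left", TreeParams(), seed=1)
        b = generate_tree("left", TreeParams(), seed=2)
        assert not np.allclose(a.segment("LAD").points, b.segment("LAD").points)

    @pytest.mark.parametrize("seed", range(25))
    def test_invariants_across_seeds(self, seed):
        tree = generate_tree("left", TreeParams(scale=0.6), seed=seed)
        tree.validate()  # raises on any violated invariant
        for seg in tree.segments:
            if seg.parent_id is not None:
                assert 2 * seg.radii[0] > 1.0  # side-branch inclusion rule

    def test_json_roundtrip(self, left_tree, tmp_path):
        p = tmp_path / "tree.json"
        left_tree.to_json(p)
        back = type(left_tree).from_json(p)
        for sa, sb in zip(left_tree.segments, back.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.radii, sb.radii)

    def test_invalid_severity_rejected(self):
        params = TreeParams(stenoses=[StenosisSpec("LAD", 0.5, 8.0, 1.2)])
        with pytest.raises(ValueError):
            generate_tree("left", params, seed=0)


class TestStenosis:
    def test_zero_severity_identity(self, left_tree):
        out = apply_stenosis(left_tree, StenosisSpec("LAD", 0.4, 8.0, 0.0))
        np.testing.assert_array_equal(out.segment("LAD").radii,
                                      left_tree.segment("LAD").radii)

    def test_center_diameter_halved(self):
        """severity 0.5 -> exactly half the local reference diameter at the
        lesion center, and 75% area reduction (1 - 0.5^2)."""
        from tests.conftest import straight_tube_tree
        tree = straight_tube_tree(radius=1.5, length=20.0, n=21)
        spec = StenosisSpec("tube", 0.5, 8.0, 0.5)  # center falls on a sample
        out = apply_stenosis(tree, spec)
        seg0, seg1 = tree.segment("tube"), out.segment("tube")
        i = 10  # arclength 10.0 mm = lesion center
        assert seg1.radii[i] == pytest.approx(0.5 * seg0.radii[i], rel=1e-12)
        area_reduction = 1.0 - (seg1.radii[i] / seg0.radii[i]) ** 2
        assert area_reduction == pytest.approx(0.75, rel=1e-9)

    def test_profile_matches_taper_law(self, left_tree):
        """The applied profile equals the closed-form cosine-bell law
        evaluated on the unstenosed taper."""
        spec = StenosisSpec("LAD", 0.4, 8.0, 0.5)
        out = apply_stenosis(left_tree, spec)
        seg0, seg1 = left_tree.segment("LAD"), out.segment("LAD")
        arc = seg0.arclength()
        expected = stenosis_diameter_profile(2 * seg0.radii, arc, spec, arc[-1])
        np.testing.assert_allclose(2 * seg1.radii, expected, rtol=1e-12)

    def test_outside_region_unchanged(self, left_tree):
        spec = StenosisSpec("LAD", 0.4, 6.0, 0.5)
        out = apply_stenosis(left_tree, spec)
        seg0, seg1 = left_tree.segment("LAD"), out.segment("LAD")
        arc = seg0.arclength()
        c = 0.4 * arc[-1]
        outside = np.abs(arc - c) > 3.5
        np.testing.assert_array_equal(seg1.radii[outside], seg0.radii[outside])

    def test_overlap_rejected(self, left_tree):
        once = apply_stenosis(left_tree, StenosisSpec("LAD", 0.4, 8.0, 0.5))
        with pytest.raises(ValueError, match="overlap"):
            apply_stenosis(once, StenosisSpec("LAD", 0.42, 8.0, 0.3))


class TestProjection:
    def test_isocenter_projects_to_principal_point(self, gantry):
        for view in gantry.views():
            px, mag = view.project_points(np.zeros((1, 3)))
            w, h = view.detector_px
            np.testing.assert_allclose(px[0], [w / 2, h / 2], atol=1e-9)
            assert mag[0] == pytest.approx(view.sid_mm / view.sod_mm)

    def test_offset_point_magnification(self):
        """10 mm offset perpendicular to the beam axis, SOD 750 / SID 1000,
        0.2 mm pixels -> 66.7 px displacement (pinhole projection oracle)."""
        view = GantryView(0.0, 0.0, sod_mm=750.0, sid_mm=1000.0, pixel_mm=0.2)
        # beam axis is +y at zero angles; offset along x
        px, _ = view.project_points(np.array([[10.0, 0.0, 0.0]]))
        w, h = view.detector_px
        disp = (px[0, 0] - w / 2)
        assert disp * view.pixel_mm == pytest.approx(10.0 * 1000.0 / 750.0, rel=1e-9)
        # independent homogeneous projection-matrix oracle
        s = view.source
        axis, (e_u, e_v) = view.axis, view.detector_basis()
        center = s + view.sid_mm * axis
        rows = [np.concatenate([e_u, [-e_u @ center]]),
                np.concatenate([e_v, [-e_v @ center]]),
                np.concatenate([axis, [-axis @ s]])]
        P = np.array(rows) @ np.array([[1, 0, 0, 0], [0, 1, 0, 0],
                                       [0, 0, 1, 0], [0, 0, 0, 1.0]])
        xh = np.array([10.0, 0.0, 0.0, 1.0])
        uvw = P @ xh
        # perspective divide happens at depth SID from the source
        u_mm = uvw[0] / uvw[2] * view.sid_mm
        assert disp * view.pixel_mm == pytest.approx(u_mm, rel=1e-9)

    def test_separation_constraint(self):
        g = GantryGeometry(GantryView(0.0, 0.0), GantryView(30.0, 0.0))
        with pytest.raises(ValueError, match="45"):
            g.validate()

    def test_width_scales_with_pixel_size(self, left_tree):
        g1 = GantryGeometry(GantryView(-30, 20, pixel_mm=0.2),
                            GantryView(40, -15, pixel_mm=0.2))
        g2 = GantryGeometry(GantryView(-30, 20, pixel_mm=0.4),
                            GantryView(40, -15, pixel_mm=0.4))
        a1, _ = project_tree(left_tree, g1)
        a2, _ = project_tree(left_tree, g2)
        s1, s2 = a1.segment("LAD"), a2.segment("LAD")
        np.testing.assert_allclose(s1.widths_px, 2 * s2.widths_px, rtol=1e-12)
        w1, h1 = a1.detector_px
        c1 = s1.points_px - np.array([w1 / 2, h1 / 2])
        c2 = s2.points_px - np.array([w1 / 2, h1 / 2])
        np.testing.assert_allclose(c1, 2 * c2, rtol=1e-9, atol=1e-9)

    def test_magnification_at_least_one(self, left_tree, gantry):
        for view in gantry.views():
            for seg in left_tree.segments:
                _, mag = view.project_points(seg.points)
                assert np.all(mag >= 1.0)

    def test_labels_carried(self, left_tree, gantry):
        pa, pb = project_tree(left_tree, gantry)
        assert pa.labels() == [s.name for s in left_tree.segments]
        assert pb.labels() == pa.labels()


class TestDegrade:
    def test_zero_noise_identity(self, left_tree, gantry):
        pa, _ = project_tree(left_tree, gantry)
        out = degrade_projection(pa, 0.0, 0.0, seed=5)
        for s0, s1 in zip(pa.segments, out.segments):
            np.testing.assert_array_equal(s0.points_px, s1.points_px)

    def test_seed_determinism(self, left_tree, gantry):
        pa, _ = project_tree(left_tree, gantry)
        o1 = degrade_projection(pa, 1.0, 0.5, seed=9)
        o2 = degrade_projection(pa, 1.0, 0.5, seed=9)
        for s1, s2 in zip(o1.segments, o2.segments):
            np.testing.assert_array_equal(s1.points_px, s2.points_px)
            np.testing.assert_array_equal(s1.widths_px, s2.widths_px)

    def test_jitter_sd_calibrated(self, left_tree, gantry):
        """Empirical displacement sd within 10% of nominal on >= 1000 points."""
        pa, _ = project_tree(left_tree, gantry)
        disp = []
        for seed in range(10):
            out = degrade_projection(pa, 1.0, 0.0, seed=seed)
            for s0, s1 in zip(pa.segments, out.segments):
                disp.append((s1.points_px - s0.points_px).ravel())
        disp = np.concatenate(disp)
        assert len(disp) >= 2000
        assert np.std(disp) == pytest.approx(1.0, rel=0.1)

    def test_negative_sd_rejected(self, left_tree, gantry):
        pa, _ = project_tree(left_tree, gantry)
        with pytest.raises(ValueError):
            degrade_projection(pa, -1.0, 0.0)
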