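"""Geometric kernel: plane fits, projections, angles, reference planes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ceph3d.errors import (DegenerateAngleError, NoIntersectionError,
                           SingularFitError)
from ceph3d.geometry import (Plane, angle_at_vertex_projected,
                             angle_between_lines_projected,
                             build_reference_planes, distance,
                             distance_projected, fit_plane_ols, midpoint,
                             plane_intersection_line, project_point,
                             rigid_motion, signed_distance)

coord = st.floats(-200, 200, allow_nan=False, allow_infinity=False)
point_st = st.tuples(coord, coord, coord).map(np.array)


class TestPlaneFit:
    def test_coplanar_points_recovered_exactly(self):
        pts = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0)]
        plane = fit_plane_ols(pts)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert abs(signed_distance(plane, np.zeros(3))) < 1e-12

    def test_matches_normal_equation_oracle(self, rng):
        """OLS coefficients agree with an explicitly solved normal system."""
        for _ in range(20):
            pts = rng.uniform(-50, 50, size=(6, 3))
            pts[:, 2] = 0.1 * pts[:, 0] - 0.2 * pts[:, 1] + rng.normal(scale=0.5, size=6)
            A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(6)])
            coef = np.linalg.solve(A.T @ A, A.T @ pts[:, 2])  # independent route
            plane = fit_plane_ols(pts)
            # recover (a, b, c) from the plane's normal/origin
            a = -plane.normal[0] / plane.normal[2]
            b = -plane.normal[1] / plane.normal[2]
            c = plane.origin[2] - a * plane.origin[0] - b * plane.origin[1]
            np.testing.assert_allclose([a, b, c], coef, atol=1e-10)

    def test_residual_not_beaten_by_grid_search(self, rng):
        pts = rng.uniform(-10, 10, size=(8, 3))
        plane = fit_plane_ols(pts)
        a = -plane.normal[0] / plane.normal[2]
        b = -plane.normal[1] / plane.normal[2]
        c = plane.origin[2] - a * plane.origin[0] - b * plane.origin[1]

        def rss(aa, bb, cc):
            return np.sum((pts[:, 2] - aa * pts[:, 0] - bb * pts[:, 1] - cc) ** 2)

        best = rss(a, b, c)
        for da in np.linspace(-0.05, 0.05, 7):
            for db in np.linspace(-0.05, 0.05, 7):
                for dc in np.linspace(-0.5, 0.5, 7):
                    assert rss(a + da, b + db, c + dc) >= best - 1e-9

    def test_collinear_footprint_rejected(self):
        with pytest.raises(SingularFitError):
            fit_plane_ols([(0, 0, 0), (1, 0, 0), (2, 0, 0)])

    def test_normal_oriented_superior(self, rng):
        pts = rng.uniform(-50, 50, size=(5, 3))
        assert fit_plane_ols(pts).normal[2] > 0


class TestProjectionAndDistance:
    def test_projection_idempotent_and_orthogonal(self, rng):
        plane = Plane(rng.normal(size=3), rng.normal(size=3))
        for _ in range(10):
            x = rng.uniform(-100, 100, size=3)
            proj = project_point(plane, x)
            assert abs(signed_distance(plane, proj)) < 1e-10
            # x - proj parallel to the normal: zero dot with in-plane vectors
            other = project_point(plane, rng.uniform(-100, 100, size=3))
            assert abs(np.dot(x - proj, other - proj)) < 1e-8
            np.testing.assert_allclose(project_point(plane, proj), proj, atol=1e-10)

    def test_signed_distance_along_normal(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        assert signed_distance(plane, [5, -2, 3]) == pytest.approx(3)
        assert signed_distance(plane, plane.origin + 3 * plane.normal) == pytest.approx(3)

    def test_signed_distance_rigid_invariant(self, rng):
        base = rng.uniform(-50, 50, size=(4, 3))
        plane = Plane(base[0], base[1] - base[0])
        x = base[2]
        d0 = signed_distance(plane, x)
        for _ in range(5):
            R, t = rigid_motion(rng)
            plane_t = Plane(R @ plane.origin + t, R @ plane.normal)
            assert signed_distance(plane_t, R @ x + t) == pytest.approx(d0, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x=point_st, y=point_st)
    def test_projected_distance_never_exceeds_distance(self, x, y):
        plane = Plane([0, 1, 2], [1, 2, 3])
        assert distance_projected(x, y, plane) <= distance(x, y) + 1e-9

    def test_projected_distance_collapses_along_normal(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        assert distance_projected([1, 2, 5], [1, 2, -7], plane) == pytest.approx(0, abs=1e-12)

    def test_midpoint_centroid_and_permutation(self, rng):
        pts = rng.normal(size=(4, 3))
        np.testing.assert_allclose(midpoint(*pts), pts.mean(axis=0))
        np.testing.assert_allclose(midpoint(*pts[::-1]), midpoint(*pts))
        np.testing.assert_allclose(midpoint([0, 0, 0], [2, 0, 0]), [1, 0, 0])
        with pytest.raises(ValueError):
            midpoint()


class TestAngles:
    def test_right_angle_in_plane(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        assert angle_at_vertex_projected([1, 0, 0], [0, 0, 0], [0, 1, 0],
                                         plane) == pytest.approx(90)

    def test_collinear_through_vertex_is_straight(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        assert angle_at_vertex_projected([-1, 0, 3], [0, 0, -2], [1, 0, 7],
                                         plane) == pytest.approx(180)

    def test_matches_law_of_cosines_oracle(self, rng):
        plane = Plane(rng.normal(size=3), rng.normal(size=3))
        for _ in range(20):
            a, b, c = rng.uniform(-50, 50, size=(3, 3))
            pa, pb, pc = (project_point(plane, x) for x in (a, b, c))
            la, lc = np.linalg.norm(pa - pb), np.linalg.norm(pc - pb)
            lb = np.linalg.norm(pa - pc)
            expected = np.degrees(np.arccos(
                np.clip((la**2 + lc**2 - lb**2) / (2 * la * lc), -1, 1)))
            got = angle_at_vertex_projected(a, b, c, plane)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_coincident_projection_degenerate(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        with pytest.raises(DegenerateAngleError):
            angle_at_vertex_projected([0, 0, 5], [0, 0, -5], [1, 0, 0], plane)

    def test_line_angles_identical_and_perpendicular(self):
        plane = Plane([0, 0, 0], [0, 0, 1])
        pair = (np.array([0, 0, 0]), np.array([1, 1, 0]))
        assert angle_between_lines_projected(pair, pair, plane) == pytest.approx(0)
        perp = (np.array([0, 0, 0]), np.array([1, -1, 0]))
        assert angle_between_lines_projected(pair, perp, plane) == pytest.approx(90)

    def test_plane_argument_uses_intersection_line(self, rng):
        proj = Plane([0, 0, 0], rng.normal(size=3))
        other = Plane(rng.normal(size=3), rng.normal(size=3))
        pair = (rng.uniform(-10, 10, size=3), rng.uniform(-10, 10, size=3))
        via_plane = angle_between_lines_projected(pair, other, proj)
        line = plane_intersection_line(other, proj)  # explicit oracle
        via_line = angle_between_lines_projected(pair, line, proj)
        assert via_plane == pytest.approx(via_line, abs=1e-9)

    def test_parallel_plane_argument_rejected(self):
        proj = Plane([0, 0, 0], [0, 0, 1])
        with pytest.raises(NoIntersectionError):
            angle_between_lines_projected(((0, 0, 0), (1, 0, 0)),
                                          Plane([0, 0, 5], [0, 0, 1]), proj)


class TestReferencePlanes:
    def test_nasion_on_sp_hp_cp(self, template, template_planes):
        n = template["n"]
        for label in ("sp", "hp", "cp"):
            assert abs(signed_distance(template_planes[label], n)) < 1e-9

    def test_sp_contains_basion(self, template, template_planes):
        assert abs(signed_distance(template_planes.sp, template["ba"])) < 1e-9

    def test_orthogonality_invariants(self, varied_template):
        planes = build_reference_planes(varied_template)
        assert abs(np.dot(planes.hp.normal, planes.fh.normal)) == pytest.approx(1, abs=1e-12)
        for a, b in [("cp", "fh"), ("cp", "sp"), ("tvl", "fh"), ("tvl", "sp"),
                     ("sp", "fh")]:
            assert abs(np.dot(planes[a].normal, planes[b].normal)) < 1e-9

    def test_symmetric_head_equidistant_bilateral_pairs(self, varied_template,
                                                        registry):
        planes = build_reference_planes(varied_template)
        for d in registry:
            if d.name.endswith("_L"):
                dl = signed_distance(planes.sp, varied_template[d.name])
                dr = signed_distance(planes.sp, varied_template[d.name[:-2] + "_R"])
                assert abs(dl) == pytest.approx(abs(dr), abs=1e-6)

    def test_missing_landmark_reported_by_name(self, template):
        from ceph3d.errors import MissingLandmarkError
        from ceph3d.landmarks import LandmarkSet
        pts = dict(template.points)
        pts.pop("ba")
        with pytest.raises(MissingLandmarkError, match="ba"):
            build_reference_planes(LandmarkSet(pts))

    def test_op_modes_agree_on_coplanar_teeth(self, template):
        m3 = build_reference_planes(template, op_mode="midpoint3")
        o6 = build_reference_planes(template, op_mode="ols6")
        # same head: the two readings give similar, superiorly oriented planes
        assert m3.op.normal[2] > 0 and o6.op.normal[2] > 0
        assert np.dot(m3.op.normal, o6.op.normal) > 0.99
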