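import dataclasses

import numpy as np
import pytest

from neckssm import (
    CenterLumenLine,
    NeckGenParams,
    NeckLandmarks,
    ParametrizationConfig,
    analytic_ring,
    cast_ring,
    detect_neck_end,
    generate_neck,
    measure_diameter,
    parametrize,
    place_stations,
    project_lra,
)
from neckssm.errors import (
    LandmarkDistanceError,
    NeckEndNotFoundError,
    NeckTooShortError,
    RayMissError,
)
from neckssm.geometry import LumenMesh
from neckssm.parametrize import ray_cast, station_frame

from conftest import SMALL
from oracles import brute_force_ray_hit

CFG = ParametrizationConfig()


def straight_cll(length=30.0, n=31):
    z = np.linspace(0, length, n)
    return CenterLumenLine(np.column_stack([np.zeros(n), np.zeros(n), z]))


class TestProjectLra:
    def test_perpendicular_foot(self):
        cll = straight_cll()
        arc = project_lra(cll, NeckLandmarks(lra=[5, 0, 10]))
        assert arc == pytest.approx(10.0, abs=1e-12)

    def test_landmark_on_vertex(self):
        cll = straight_cll()
        arc = project_lra(cll, NeckLandmarks(lra=[0, 0, 7.0]))
        assert arc == pytest.approx(7.0, abs=1e-12)

    def test_tie_breaks_to_proximal_foot(self):
        # right-angle polyline; the landmark is equidistant from both legs
        cll = CenterLumenLine([[0, 0, 0], [2, 0, 0], [2, 2, 0]])
        from neckssm.parametrize import project_point_to_polyline

        point = [1.0, 1.0, 0.0]
        arc, dist = project_point_to_polyline(cll, point)
        # brute force over both segments confirms the tie
        feet = [(1.0, np.array([1, 0, 0])), (3.0, np.array([2, 1, 0]))]
        dists = [np.linalg.norm(np.asarray(point) - f) for _, f in feet]
        assert dists[0] == pytest.approx(dists[1])
        assert arc == pytest.approx(feet[0][0])  # proximal foot wins

    def test_distant_landmark_rejected(self):
        cll = straight_cll()
        with pytest.raises(LandmarkDistanceError):
            project_lra(cll, NeckLandmarks(lra=[100, 0, 10]))


class TestMeasureDiameter:
    def test_cylinder(self, cylinder):
        mesh, cll, _ = cylinder
        frame = station_frame(cll, 15.0)
        assert measure_diameter(mesh, frame) == pytest.approx(24.0, abs=1e-9)

    def test_cone_distal(self, cone):
        mesh, cll, _ = cone
        frame = station_frame(cll, 30.0)
        assert measure_diameter(mesh, frame) == pytest.approx(26.4, abs=1e-9)

    def test_elliptical_section_matches_polar_mean(self):
        # straight tube with elliptical cross-section, vertices placed exactly
        # along the ray azimuths so the measurement is faceting-free
        a, b = 10.0, 14.0  # semi-axes along anterior (ray 0) and left (ray 90)
        psi = np.deg2rad(np.arange(0, 360, 5.0))
        r = a * b / np.sqrt((b * np.cos(psi)) ** 2 + (a * np.sin(psi)) ** 2)
        ring = np.column_stack([r * np.sin(psi), -r * np.cos(psi), np.zeros_like(psi)])
        zs = np.linspace(-5, 35, 9)
        verts = np.vstack([ring + [0, 0, z] for z in zs])
        C = len(psi)
        faces = []
        for i in range(len(zs) - 1):
            for j in range(C):
                jn = (j + 1) % C
                faces.append((i * C + j, i * C + jn, (i + 1) * C + jn))
                faces.append((i * C + j, (i + 1) * C + jn, (i + 1) * C + j))
        mesh = LumenMesh(verts, faces)
        frame = station_frame(straight_cll(), 15.0)
        phi = np.deg2rad(CFG.angles_deg)
        oracle = 2.0 * np.mean(a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2))
        assert measure_diameter(mesh, frame) == pytest.approx(oracle, abs=1e-9)


class TestDetectNeckEnd:
    def test_cone_10pct_taper_detected_at_distal_end(self, cone):
        mesh, cll, _ = cone
        arc = detect_neck_end(mesh, cll, baseline_arc=0.0)
        assert arc == pytest.approx(30.0, abs=0.2)

    def test_cone_20pct_taper_detected_at_midpoint(self):
        params = NeckGenParams(taper=0.20, **SMALL)
        mesh, cll, _ = generate_neck(params, seed=0)
        arc = detect_neck_end(mesh, cll, baseline_arc=0.0)
        assert arc == pytest.approx(15.0, abs=0.2)

    def test_cylinder_never_reaches_threshold(self, cylinder):
        mesh, cll, _ = cylinder
        with pytest.raises(NeckEndNotFoundError) as exc_info:
            detect_neck_end(mesh, cll, baseline_arc=0.0)
        assert exc_info.value.max_ratio == pytest.approx(1.0, abs=1e-6)


class TestPlaceStations:
    def test_arithmetic_spacing(self):
        cll = straight_cll(length=40.0)
        frames = place_stations(cll, 0.0, 27.0)
        arcs = [f.origin[2] for f in frames]
        np.testing.assert_allclose(arcs, np.arange(0, 28, 3.0), atol=1e-9)

    def test_straight_cll_constant_frames(self):
        frames = place_stations(straight_cll(), 0.0, 30.0)
        for f in frames:
            np.testing.assert_allclose(f.tangent, [0, 0, 1], atol=1e-12)
            np.testing.assert_allclose(f.ray0, frames[0].ray0, atol=1e-12)

    def test_quarter_circle_tangents_match_analytic(self):
        theta = np.linspace(0, np.pi / 2, 100)
        pts = np.column_stack(
            [10 * np.sin(theta), np.zeros_like(theta), 10 * (1 - np.cos(theta))]
        )
        cll = CenterLumenLine(pts)
        frames = place_stations(cll, 0.0, cll.total_length)
        arcs = np.linspace(0.0, cll.total_length, 10)
        for i, (f, s) in enumerate(zip(frames, arcs)):
            ang = s / 10.0  # arc/radius
            exact = np.array([np.cos(ang), 0.0, np.sin(ang)])
            mis = np.degrees(np.arccos(np.clip(np.dot(f.tangent, exact), -1, 1)))
            # end stations use a one-sided difference whose chord bias on a
            # 10 mm-radius arc is h/2R ~ 1.4 degrees
            assert mis < (2.0 if i in (0, 9) else 1.0)

    def test_too_short_neck_rejected(self):
        with pytest.raises(NeckTooShortError):
            place_stations(straight_cll(), 0.0, 3.0)


class TestCastRing:
    def test_cylinder_ring_radii_and_angles(self, cylinder):
        mesh, cll, _ = cylinder
        frame = station_frame(cll, 12.0)
        pts = cast_ring(mesh, frame)
        rel = pts - frame.origin
        np.testing.assert_allclose(np.linalg.norm(rel, axis=1), 12.0, atol=1e-9)
        e2 = np.cross(frame.tangent, frame.ray0)
        ang = np.degrees(np.arctan2(rel @ e2, rel @ frame.ray0)) % 360
        np.testing.assert_allclose(ang, CFG.angles_deg, atol=1e-9)

    def test_matches_brute_force_oracle_exactly(self, noisy_params):
        mesh, cll, _ = generate_neck(noisy_params, seed=13)
        frame = station_frame(cll, 17.3)
        dirs = frame.ray_directions(CFG.angles_deg)
        dist, tri = ray_cast(frame.origin, dirs, mesh)
        for k in range(len(dirs)):
            t_o, tri_o = brute_force_ray_hit(frame.origin, dirs[k], mesh.vertices, mesh.faces)
            assert tri[k] == tri_o
            assert dist[k] == t_o

    def test_bowed_tube_matches_analytic_ring(self, bowed_params):
        mesh, cll, _ = generate_neck(bowed_params, seed=0)
        t = 0.4
        arc = float(np.interp(t, np.linspace(0, 1, len(cll.points)), cll.arc))
        frame = station_frame(cll, arc)
        pts = cast_ring(mesh, frame)
        exact = analytic_ring(bowed_params, t, CFG.angles_deg)
        err = np.linalg.norm(pts - exact, axis=1).max()
        facet = 12.0 * (1 - np.cos(np.pi / bowed_params.circumferential_samples))
        assert err < 3 * facet + 0.05

    def test_ray_miss_raises(self, cylinder):
        mesh, cll, _ = cylinder
        # station beyond the distal cap overhang: rays miss the tube wall
        far = CenterLumenLine([[0, 0, 40.0], [0, 0, 50.0]])
        frame = station_frame(far, 5.0)
        with pytest.raises(RayMissError):
            cast_ring(mesh, frame)


class TestParametrize:
    def test_full_grid_360_finite_points(self, bowed_params):
        mesh, cll, lm = generate_neck(bowed_params, seed=2)
        grid = parametrize(mesh, cll, lm)
        assert grid.points.shape == (10, 36, 3)
        assert np.isfinite(grid.points).all()

    def test_noise_free_cylinder_all_at_radius_12(self, cylinder):
        mesh, cll, lm = cylinder
        grid = parametrize(mesh, cll, lm)
        r = np.linalg.norm(grid.points[:, :, :2], axis=2)
        np.testing.assert_allclose(r, 12.0, atol=1e-9)
        np.testing.assert_allclose(grid.baseline_point, [0, 0, 0], atol=1e-12)

    def test_mesh_resolution_convergence(self):
        """Contour error vs the analytic surface shrinks with faceting."""
        errs = []
        for c in (36, 72, 144):
            params = NeckGenParams(bow_lr=4.0, bow_ant=2.0, axial_samples=40,
                                   circumferential_samples=c)
            mesh, cll, lm = generate_neck(params, seed=0)
            grid = parametrize(mesh, cll, lm)
            ts = np.interp(grid.arc_positions, cll.arc, np.linspace(0, 1, len(cll.points)))
            exact = np.stack([analytic_ring(params, float(t), grid.angles_deg) for t in ts])
            errs.append(np.linalg.norm(grid.points - exact, axis=2).max())
        assert errs[0] > errs[1] > errs[2]

    def test_grid_invariant_under_vertex_permutation(self, noisy_params):
        mesh, cll, lm = generate_neck(noisy_params, seed=21)
        grid = parametrize(mesh, cll, lm)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mesh.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(mesh.n_vertices)
        shuffled = LumenMesh(mesh.vertices[perm], inv[mesh.faces])
        grid2 = parametrize(shuffled, cll, lm)
        np.testing.assert_allclose(grid2.points, grid.points, atol=1e-9)

    def test_detection_mode_matches_landmark_mode_on_cone(self, cone):
        mesh, cll, lm = cone
        by_landmark = parametrize(mesh, cll, lm)
        by_rule = parametrize(mesh, cll, dataclasses.replace(lm, distal_end=None))
        np.testing.assert_allclose(
            by_rule.points, by_landmark.points, atol=0.3
        )
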