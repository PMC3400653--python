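"""Camera model, back-projection, and midpoint triangulation."""

import numpy as np
import pytest

from fluotrack.geometry3d import (
    CameraAtInfinityError,
    CameraModel,
    DegenerateGeometryError,
    MalformedMatrixFileError,
    Ray3,
    backproject_pixel,
    fit_projection_matrix,
    load_projection_matrix,
    project_point,
    triangulate_midpoint,
)
from fluotrack.synthetic_scene import look_at_rotation, make_camera


def canonical_camera():
    return CameraModel.from_matrix(np.hstack([np.eye(3), np.zeros((3, 1))]))


class TestCameraModel:
    def test_canonical_camera_center_at_origin(self):
        cam = canonical_camera()
        np.testing.assert_allclose(cam.optical_center, np.zeros(3), atol=1e-12)

    def test_center_is_null_space_point(self, rng):
        # defining property P [C; 1] = 0 for random valid cameras
        for seed in range(20):
            r = np.random.default_rng(seed)
            P = r.normal(size=(3, 4))
            if np.linalg.matrix_rank(P[:, :3]) < 3:
                continue
            cam = CameraModel.from_matrix(P)
            Pn = P / np.linalg.norm(P)
            residual = Pn @ np.append(cam.optical_center, 1.0)
            assert np.abs(residual).max() < 1e-9

    def test_rank_deficient_left_block_rejected(self):
        P = np.zeros((3, 4))
        P[0, 0] = P[1, 1] = 1.0
        P[2, 3] = 1.0
        with pytest.raises(Exception):
            CameraModel.from_matrix(P)

    def test_camera_without_finite_center_rejected(self):
        # affine-like camera: singular left block, null vector with w = 0 —
        # no finite optical center exists, construction must fail
        from fluotrack.geometry3d import CameraError

        P = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0], [0, 0, 0, 1.0]])
        with pytest.raises(CameraError):
            CameraModel.from_matrix(P)


class TestMatrixFile:
    def test_round_trip_with_comments(self, tmp_path):
        center = np.array([3.0, -2.0, 5.0])
        R = look_at_rotation(center, np.zeros(3))
        cam = make_camera(400.0, (160.0, 120.0), R, center)
        path = tmp_path / "cam.txt"
        rows = "\n".join(" ".join(f"{x:.15g}" for x in row) for row in cam.projection)
        path.write_text("# pixel convention: u=col, v=row\n" + rows + "\n")
        loaded = load_projection_matrix(path, view_id=1)
        np.testing.assert_allclose(loaded.optical_center, center, atol=1e-9)
        assert loaded.view_id == 1

    def test_identity_matrix_file(self, tmp_path):
        path = tmp_path / "cam.txt"
        path.write_text("1 0 0 0\n0 1 0 0\n0 0 1 0\n")
        cam = load_projection_matrix(path)
        np.testing.assert_allclose(cam.optical_center, np.zeros(3), atol=1e-12)

    @pytest.mark.parametrize(
        "content",
        ["1 0 0\n0 1 0\n0 0 1\n", "1 0 0 0\n0 1 0 0\n", "a b c d\ne f g h\ni j k l\n"],
    )
    def test_malformed_files_rejected(self, tmp_path, content):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(MalformedMatrixFileError):
            load_projection_matrix(path)


class TestProjection:
    def test_canonical_projection(self):
        cam = canonical_camera()
        np.testing.assert_allclose(project_point(cam, [0, 0, 1]), [0, 0], atol=1e-12)

    def test_scale_invariance(self, rng):
        P = rng.normal(size=(3, 4))
        X = rng.normal(size=3) + [0, 0, 5]
        x1 = project_point(CameraModel.from_matrix(P), X)
        x2 = project_point(CameraModel.from_matrix(-3.7 * P), X)
        np.testing.assert_allclose(x1, x2, atol=1e-9)

    def test_matches_two_stage_transform_oracle(self, rng):
        # oracle: extrinsic transform to camera coords, then intrinsic scale/offset
        f, pp = 350.0, (80.0, 60.0)
        center = np.array([10.0, 4.0, -3.0])
        R = look_at_rotation(center, np.zeros(3))
        cam = make_camera(f, pp, R, center)
        for _ in range(50):
            X = rng.normal(scale=3.0, size=3)
            Xc = R @ (X - center)  # camera coordinates
            expected = np.array(
                [f * Xc[0] / Xc[2] + pp[0], f * Xc[1] / Xc[2] + pp[1]]
            )
            np.testing.assert_allclose(project_point(cam, X), expected, atol=1e-9)

    def test_principal_plane_point_errors(self):
        cam = canonical_camera()
        with pytest.raises(DegenerateGeometryError):
            project_point(cam, [1.0, 1.0, 0.0])


class TestBackprojection:
    def test_ray_reprojects_to_pixel(self, random_camera_pair):
        cam1, cam2 = random_camera_pair(3)
        for cam in (cam1, cam2):
            for x in ([100.0, 90.0], [10.0, 200.0], [155.5, 120.25]):
                ray = backproject_pixel(cam, x)
                np.testing.assert_allclose(ray.origin, cam.optical_center, atol=1e-12)
                for t in (0.5, 1.0, 10.0):
                    np.testing.assert_allclose(
                        project_point(cam, ray.point_at(t)), x, atol=1e-9
                    )

    def test_direction_matches_two_point_line_oracle(self, random_camera_pair):
        # oracle: solve P [X;1] = s [x;1] at two scales, direction joins solutions
        cam, _ = random_camera_pair(11)
        x = np.array([120.0, 101.0])
        P = cam.projection
        A = P[:, :3]
        pts = []
        for s in (1.0, 2.0):
            b = s * np.append(x, 1.0) - P[:, 3]
            pts.append(np.linalg.solve(A, b))
        expected = pts[1] - pts[0]
        expected /= np.linalg.norm(expected)
        ray = backproject_pixel(cam, x)
        assert min(
            np.abs(ray.direction - expected).max(),
            np.abs(ray.direction + expected).max(),
        ) < 1e-9


class TestTriangulation:
    def test_intersecting_rays_recover_the_point(self):
        X = np.array([1.0, 2.0, 3.0])
        r1 = Ray3(origin=[0, 0, 0], direction=X)
        r2 = Ray3(origin=[10, 0, 0], direction=X - [10, 0, 0])
        point, gap = triangulate_midpoint(r1, r2)
        np.testing.assert_allclose(point, X, atol=1e-12)
        assert gap < 1e-12

    def test_hand_constructed_skew_pair(self):
        # common perpendicular is the z-axis segment from (0,0,0) to (0,0,2)
        r1 = Ray3(origin=[0, 0, 0], direction=[1, 0, 0])
        r2 = Ray3(origin=[0, 0, 2], direction=[0, 1, 0])
        point, gap = triangulate_midpoint(r1, r2)
        np.testing.assert_allclose(point, [0, 0, 1], atol=1e-12)
        assert gap == pytest.approx(2.0, abs=1e-12)

    def test_parallel_rays_error(self):
        r1 = Ray3(origin=[0, 0, 0], direction=[1, 0, 0])
        r2 = Ray3(origin=[0, 1, 0], direction=[1, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            triangulate_midpoint(r1, r2)

    def test_round_trip_project_backproject_triangulate(self, random_camera_pair):
        for seed in range(10):
            cam1, cam2 = random_camera_pair(seed)
            r = np.random.default_rng(seed + 100)
            for _ in range(10):
                X = r.uniform(-5, 5, size=3)
                x1 = project_point(cam1, X)
                x2 = project_point(cam2, X)
                point, gap = triangulate_midpoint(
                    backproject_pixel(cam1, x1), backproject_pixel(cam2, x2)
                )
                np.testing.assert_allclose(point, X, atol=1e-8)
                assert gap < 1e-8

    def test_pixel_noise_robustness(self):
        # half-pixel jitter must not move the point more than 1% of the
        # chamber diameter (20 world units) on the default two-camera rig
        import fluotrack as ft

        cam1, cam2 = ft.default_cameras(ft.SceneConfig())
        r = np.random.default_rng(0)
        X = np.array([2.0, -1.0, 15.0])  # inside the chamber
        x1, x2 = project_point(cam1, X), project_point(cam2, X)
        for _ in range(25):
            d1 = r.uniform(-0.5, 0.5, 2)
            d2 = r.uniform(-0.5, 0.5, 2)
            point, _ = triangulate_midpoint(
                backproject_pixel(cam1, x1 + d1), backproject_pixel(cam2, x2 + d2)
            )
            assert np.linalg.norm(point - X) < 0.01 * 20


class TestDLTFit:
    def test_recovers_camera_from_correspondences(self, rng):
        center = np.array([12.0, -7.0, 4.0])
        R = look_at_rotation(center, np.zeros(3))
        cam = make_camera(420.0, (150.0, 110.0), R, center)
        world = rng.uniform(-4, 4, size=(10, 3))
        image = np.array([project_point(cam, X) for X in world])
        fitted = fit_projection_matrix(world, image)
        for X in rng.uniform(-4, 4, size=(5, 3)):
            np.testing.assert_allclose(
                project_point(fitted, X), project_point(cam, X), atol=1e-6
            )
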