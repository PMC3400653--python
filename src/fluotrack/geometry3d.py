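"""Pinhole camera model and two-ray triangulation.

A camera is a 3x4 projection matrix ``P`` (defined up to scale) mapping
homogeneous world points to homogeneous pixel points, ``s [u, v, 1]^T =
P [X, Y, Z, 1]^T``.  The optical center ``C`` is the unique world point
annihilated by ``P``.  A 2D observation back-projects to the viewing ray
through ``C``; the 3D position seen by two cameras is estimated as the
midpoint of the shortest segment joining the two rays, with the segment
length reported as a reconstruction-quality diagnostic (with imperfect
calibration or centroid noise the rays are skew, not intersecting).

Pixel convention: ``u`` = column, ``v`` = row, origin at the top-left
corner, 0-based.  Projection-matrix text files must follow it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CameraModel",
    "Ray3",
    "CameraError",
    "MalformedMatrixFileError",
    "RankDeficientCameraError",
    "CameraAtInfinityError",
    "DegenerateGeometryError",
    "load_projection_matrix",
    "project_point",
    "backproject_pixel",
    "triangulate_midpoint",
    "fit_projection_matrix",
]


class CameraError(ValueError):
    """Base class for camera-model construction failures."""


class MalformedMatrixFileError(CameraError):
    """Matrix file does not hold 3 rows x 4 columns of reals."""


class RankDeficientCameraError(CameraError):
    """Left 3x3 block of the projection matrix is singular."""


class CameraAtInfinityError(CameraError):
    """Null vector of P has zero last coordinate: no finite optical center."""


class DegenerateGeometryError(ValueError):
    """Triangulation geometry is degenerate (near-parallel rays)."""


def _optical_center(P: np.ndarray) -> np.ndarray:
    """Right null vector of P, dehomogenized to the finite optical center."""
    _, s, vt = np.linalg.svd(P)
    null = vt[-1]
    # rank check on the left 3x3 block: a proper finite camera has an
    # invertible intrinsic-rotation part
    if np.linalg.matrix_rank(P[:, :3], tol=1e-10 * max(s[0], 1.0)) < 3:
        raise RankDeficientCameraError("left 3x3 block of P is rank-deficient")
    if abs(null[3]) < 1e-12 * np.linalg.norm(null):
        raise CameraAtInfinityError("optical center at infinity (null vector has w = 0)")
    return null[:3] / null[3]


@dataclass(frozen=True)
class CameraModel:
    """A 3x4 projection matrix with its derived optical center."""

    projection: np.ndarray
    optical_center: np.ndarray = field(default=None)  # type: ignore[assignment]
    view_id: int | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.projection, dtype=float)
        if P.shape != (3, 4):
            raise CameraError(f"projection matrix must be 3x4, got {P.shape}")
        object.__setattr__(self, "projection", P)
        if self.optical_center is None:
            object.__setattr__(self, "optical_center", _optical_center(P))
        else:
            object.__setattr__(
                self, "optical_center", np.asarray(self.optical_center, dtype=float)
            )

    @classmethod
    def from_matrix(cls, P: np.ndarray, view_id: int | None = None) -> "CameraModel":
        return cls(projection=np.asarray(P, dtype=float), view_id=view_id)


@dataclass(frozen=True)
class Ray3:
    """A 3D ray: origin (the optical center) plus a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("ray direction must be non-zero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


def load_projection_matrix(path: str | Path, view_id: int | None = None) -> CameraModel:
    """Read a 3x4 projection matrix from a plain-text file.

    The file holds 3 lines of 4 whitespace-separated reals; lines starting
    with ``#`` are comments and are ignored.
    """
    path = Path(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            values = [float(tok) for tok in stripped.split()]
        except ValueError as exc:
            raise MalformedMatrixFileError(f"{path}:{lineno}: non-numeric token") from exc
        rows.append(values)
    if len(rows) != 3 or any(len(r) != 4 for r in rows):
        raise MalformedMatrixFileError(
            f"{path}: expected 3 rows x 4 columns, got {[len(r) for r in rows]}"
        )
    return CameraModel.from_matrix(np.array(rows, dtype=float), view_id=view_id)


def project_point(camera: CameraModel, X: np.ndarray) -> np.ndarray:
    """Project a 3D world point to (u, v) pixels via homogeneous coordinates."""
    X = np.asarray(X, dtype=float)
    h = camera.projection @ np.append(X, 1.0)
    scale = abs(h[2])
    if scale < 1e-12 * max(np.linalg.norm(h), 1.0):
        raise DegenerateGeometryError("point lies on the principal plane (zero scale)")
    return h[:2] / h[2]


def backproject_pixel(camera: CameraModel, x: np.ndarray) -> Ray3:
    """Back-project a pixel to the 3D viewing ray through the optical center.

    The direction is oriented so that points along the ray lie in front of
    the camera (positive homogeneous scale under ``P``).
    """
    u, v = np.asarray(x, dtype=float)
    # pseudo-inverse pre-image of the pixel: one point on the viewing ray
    pre = np.linalg.pinv(camera.projection) @ np.array([u, v, 1.0])
    C = camera.optical_center
    if abs(pre[3]) > 1e-12 * np.linalg.norm(pre):
        direction = pre[:3] / pre[3] - C
    else:  # pre-image at infinity: its first three coords already give the direction
        direction = pre[:3]
    ray = Ray3(origin=C, direction=direction)
    w = camera.projection[2] @ np.append(ray.point_at(1.0), 1.0)
    if w < 0:
        ray = Ray3(origin=C, direction=-ray.direction)
    return ray


def triangulate_midpoint(ray1: Ray3, ray2: Ray3) -> tuple[np.ndarray, float]:
    """Midpoint of the shortest segment between two viewing rays.

    Returns ``(point, gap)`` where ``gap`` is the closest-approach distance
    between the rays — 0 for exactly intersecting rays, growing with
    calibration/measurement error.  Raises :class:`DegenerateGeometryError`
    for near-parallel rays.
    """
    d1, d2 = ray1.direction, ray2.direction
    if np.linalg.norm(np.cross(d1, d2)) <= 1e-9:
        raise DegenerateGeometryError("rays are near-parallel; no unique closest point")
    r = ray2.origin - ray1.origin
    # perpendicularity conditions: (p1 - p2) . d1 = 0 and (p1 - p2) . d2 = 0
    a = np.array([[d1 @ d1, -(d1 @ d2)], [d1 @ d2, -(d2 @ d2)]])
    b = np.array([d1 @ r, d2 @ r])
    t1, t2 = np.linalg.solve(a, b)
    p1 = ray1.point_at(t1)
    p2 = ray2.point_at(t2)
    return (p1 + p2) / 2.0, float(np.linalg.norm(p1 - p2))


def fit_projection_matrix(
    world_points: np.ndarray, image_points: np.ndarray, view_id: int | None = None
) -> CameraModel:
    """Direct linear transform fit of P from >= 6 known 3D<->2D correspondences.

    Fixture-building aid (e.g. writing matrix files for synthetic rigs);
    plain homogeneous least squares, no normalization refinements.
    """
    W = np.asarray(world_points, dtype=float)
    x = np.asarray(image_points, dtype=float)
    if W.shape[0] < 6 or W.shape[0] != x.shape[0]:
        raise ValueError("need >= 6 matching 3D and 2D points")
    rows = []
    for (X, Y, Z), (u, v) in zip(W, x):
        Xh = [X, Y, Z, 1.0]
        rows.append([*Xh, 0, 0, 0, 0, *(-u * np.array(Xh))])
        rows.append([0, 0, 0, 0, *Xh, *(-v * np.array(Xh))])
    _, _, vt = np.linalg.svd(np.array(rows))
    P = vt[-1].reshape(3, 4)
    return CameraModel.from_matrix(P, view_id=view_id)
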