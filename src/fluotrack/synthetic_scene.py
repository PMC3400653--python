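"""Synthetic two-view test scenes with exported ground truth.

Renders one or more bright, Gaussian-profile fluorescent blobs moving
along known 3D paths inside a cylindrical chamber (proportioned like a
culture vial, height about three times the radius), viewed by two known
pinhole cameras against a dark noisy background.  Every downstream stage
— background subtraction, silhouette extraction, intensity binning,
pairing and triangulation — is testable against the exported truth
without any recorded video.

The blob is photometrically an isotropic 2D Gaussian spot: the pipeline
consumes only silhouette area, centroid and intensity, none of which is
shape-specific.  Blobs whose projected center leaves a view are rendered
blob-free in that view and flagged, mirroring real single-camera
occlusion.  Rendering is deterministic: one config (seed included) gives
a bit-identical frame stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry3d import CameraModel, project_point
from .io import FrameSequence

__all__ = [
    "SceneConfig",
    "make_camera",
    "look_at_rotation",
    "default_cameras",
    "make_trajectory",
    "render_sequence",
    "write_fixture",
]

GROUND_TRUTH_COLUMNS = [
    "frame", "blob_id", "x", "y", "z",
    "u1", "v1", "u2", "v2", "in_view1", "in_view2",
    "green_sum1", "green_sum2",
]


@dataclass
class SceneConfig:
    """Geometry, photometry and noise of a rendered two-view scene.

    The chamber is the cylinder of given radius and height, axis along
    +z from z = 0.  World units are arbitrary; defaults proportion the
    chamber like a glass culture vial.
    """

    image_height: int = 240
    image_width: int = 320
    frame_rate: float = 30.0
    n_frames: int = 600
    chamber_radius: float = 10.0
    chamber_height: float = 30.0
    blob_radius_world: float = 1.0
    blob_peak_intensity: int = 200
    background_level: int = 10
    noise_sd: float = 2.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in (
            "image_height", "image_width", "frame_rate",
            "chamber_radius", "chamber_height", "blob_radius_world",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.background_level <= 255 or not 0 <= self.blob_peak_intensity <= 255:
            raise ValueError("intensity levels must lie in 0-255")
        if self.blob_peak_intensity <= self.background_level + 3 * self.noise_sd:
            raise ValueError(
                "blob_peak_intensity must exceed background_level + 3*noise_sd "
                "(blobs must be detectable by construction)"
            )

    @property
    def chamber_center(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.chamber_height / 2.0])

    @property
    def chamber_diameter(self) -> float:
        return 2.0 * self.chamber_radius


def make_camera(
    focal_length: float,
    principal_point: tuple[float, float],
    rotation: np.ndarray,
    center: np.ndarray,
    view_id: int | None = None,
) -> CameraModel:
    """Compose a pinhole camera: P = K [R | -R C].

    ``rotation`` maps world to camera coordinates (rows are the camera
    axes); it must be orthonormal to 1e-9.  The derived optical center of
    the returned camera equals ``center``.
    """
    R = np.asarray(rotation, dtype=float)
    C = np.asarray(center, dtype=float)
    if focal_length <= 0:
        raise ValueError("focal_length must be positive")
    if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
        raise ValueError("rotation must be a 3x3 orthonormal matrix (tol 1e-9)")
    cx, cy = principal_point
    K = np.array([[focal_length, 0.0, cx], [0.0, focal_length, cy], [0.0, 0.0, 1.0]])
    P = K @ np.hstack([R, -R @ C[:, None]])
    return CameraModel(projection=P, optical_center=C, view_id=view_id)


def look_at_rotation(camera_center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World-to-camera rotation looking from ``camera_center`` at ``target``.

    Camera z points at the target, x is horizontal (world z is up), and y
    completes the frame pointing toward decreasing world z so that image
    rows grow downward.
    """
    forward = np.asarray(target, float) - np.asarray(camera_center, float)
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    nr = np.linalg.norm(right)
    if nr < 1e-12:
        raise ValueError("viewing direction parallel to world up; pick another center")
    right /= nr
    down = np.cross(forward, right)
    return np.stack([right, down, forward])


def default_cameras(config: SceneConfig) -> tuple[CameraModel, CameraModel]:
    """Two orthogonal cameras framing the whole chamber.

    Both sit at twice the chamber height from the axis, at chamber
    mid-height, 90 degrees apart, with focal length chosen so the
    cylinder fills ~85% of the image height.
    """
    target = config.chamber_center
    d = 2.0 * config.chamber_height
    focal = 0.85 * (config.image_height / 2.0) * (d - config.chamber_radius) / (
        config.chamber_height / 2.0
    )
    pp = (config.image_width / 2.0, config.image_height / 2.0)
    cams = []
    for view_id, center in enumerate(
        ([d, 0.0, target[2]], [0.0, d, target[2]]), start=1
    ):
        R = look_at_rotation(center, target)
        cams.append(make_camera(focal, pp, R, np.asarray(center), view_id=view_id))
    return cams[0], cams[1]


def make_trajectory(
    kind: str, config: SceneConfig, radius: float | None = None
) -> np.ndarray:
    """A blob path of ``n_frames`` 3D points inside the chamber cylinder.

    kinds: ``helix`` (rising spiral of given radius, default 0.7 x chamber
    radius — echoes wall-following exploration), ``bounded-random-walk``
    (reflected Gaussian steps, reproducible from ``random_seed``), and
    ``stationary``.
    """
    n = config.n_frames
    R, H = config.chamber_radius, config.chamber_height
    if kind == "stationary":
        return np.tile([0.5 * R, 0.0, 0.4 * H], (n, 1))
    if kind == "helix":
        r = 0.7 * R if radius is None else radius
        if not 0 <= r <= R:
            raise ValueError("helix radius must fit inside the chamber")
        theta = np.linspace(0.0, 4.0 * np.pi, n)
        z = np.linspace(0.2 * H, 0.8 * H, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    if kind == "bounded-random-walk":
        rng = np.random.default_rng(config.random_seed)
        step_sd = R / 20.0
        pts = np.empty((n, 3))
        p = np.array([0.0, 0.0, H / 2.0])
        r_max, z_lo, z_hi = 0.95 * R, 0.05 * H, 0.95 * H
        for i in range(n):
            p = p + rng.normal(0.0, step_sd, 3)
            rad = math.hypot(p[0], p[1])
            if rad > r_max:  # reflect off the wall back inside
                p[:2] *= (2 * r_max - rad) / rad
            if p[2] < z_lo:
                p[2] = 2 * z_lo - p[2]
            elif p[2] > z_hi:
                p[2] = 2 * z_hi - p[2]
            pts[i] = p
        return pts
    raise ValueError(f"unknown trajectory kind: {kind!r}")


def _projected_sigma(
    camera: CameraModel, X: np.ndarray, uv: np.ndarray, config: SceneConfig
) -> float:
    """Spot width in pixels: half the projected blob radius, floored so the
    above-threshold footprint spans at least ~9 pixels."""
    ray = X - camera.optical_center
    ray /= np.linalg.norm(ray)
    # offset the blob center perpendicular to the viewing ray by one radius
    perp = np.cross(ray, [0.0, 0.0, 1.0])
    n = np.linalg.norm(perp)
    if n < 1e-9:
        perp = np.cross(ray, [0.0, 1.0, 0.0])
        n = np.linalg.norm(perp)
    offset = project_point(camera, X + config.blob_radius_world * perp / n)
    radius_px = float(np.linalg.norm(offset - uv))
    return max(radius_px / 2.0, 1.5)


def render_sequence(
    trajectories: list[np.ndarray],
    cameras: tuple[CameraModel, CameraModel],
    config: SceneConfig,
    peak_per_frame: np.ndarray | None = None,
) -> tuple[FrameSequence, FrameSequence, pd.DataFrame]:
    """Render both views plus the ground-truth table.

    Each frame is ``background_level`` plus clipped Gaussian noise in all
    channels, plus one Gaussian-profile spot per in-view blob in the
    green channel (the reporter emission channel).  Ground truth holds,
    per (frame, blob): the true 3D position, each view's projected pixel
    position and in-view flag, and the rendered green intensity sum.

    ``peak_per_frame`` optionally schedules the spot's peak intensity
    frame by frame (overriding ``config.blob_peak_intensity``), emulating
    a reporter whose expression is induced during the recording; every
    scheduled peak must still clear ``background_level + 3 * noise_sd``.
    """
    if len(cameras) != 2:
        raise ValueError("exactly two cameras are required")
    for t in trajectories:
        if np.asarray(t).shape != (config.n_frames, 3):
            raise ValueError("each trajectory must have n_frames 3D points")
    if peak_per_frame is not None:
        peak_per_frame = np.asarray(peak_per_frame, dtype=float)
        if peak_per_frame.shape != (config.n_frames,):
            raise ValueError("peak_per_frame must hold one level per frame")
        if peak_per_frame.min() <= config.background_level + 3 * config.noise_sd:
            raise ValueError("scheduled peaks must stay detectable above background")
        if peak_per_frame.max() > 255:
            raise ValueError("scheduled peaks must stay within levels 0-255")
    H, W = config.image_height, config.image_width
    rng = np.random.default_rng(config.random_seed)
    stacks = [np.empty((config.n_frames, H, W, 3), dtype=np.uint8) for _ in cameras]
    records: list[dict] = []
    # precompute projections and spot widths per blob/view/frame
    proj: list[list[list]] = []  # [view][blob][frame] -> (uv, sigma, in_view)
    for cam in cameras:
        per_blob = []
        for traj in trajectories:
            per_frame = []
            for X in np.asarray(traj, dtype=float):
                uv = project_point(cam, X)
                in_view = bool(0 <= uv[0] < W and 0 <= uv[1] < H)
                sigma = _projected_sigma(cam, X, uv, config) if in_view else np.nan
                per_frame.append((uv, sigma, in_view))
            per_blob.append(per_frame)
        proj.append(per_blob)

    for f in range(config.n_frames):
        buffers = []
        for v in range(2):
            buf = np.full((H, W, 3), float(config.background_level))
            if config.noise_sd > 0:
                buf += rng.normal(0.0, config.noise_sd, (H, W, 3))
            buffers.append(buf)
        frame_records = [
            {
                "frame": f,
                "blob_id": b,
                "x": trajectories[b][f][0],
                "y": trajectories[b][f][1],
                "z": trajectories[b][f][2],
            }
            for b in range(len(trajectories))
        ]
        for v in range(2):
            for b in range(len(trajectories)):
                (u, vv), sigma, in_view = proj[v][b][f]
                rec = frame_records[b]
                rec[f"u{v + 1}"], rec[f"v{v + 1}"] = u, vv
                rec[f"in_view{v + 1}"] = in_view
                spot_sum = 0.0
                if in_view:
                    peak = (
                        config.blob_peak_intensity
                        if peak_per_frame is None
                        else peak_per_frame[f]
                    )
                    half = int(math.ceil(4 * sigma))
                    r0, r1 = max(int(vv) - half, 0), min(int(vv) + half + 1, H)
                    c0, c1 = max(int(u) - half, 0), min(int(u) + half + 1, W)
                    rr, cc = np.mgrid[r0:r1, c0:c1]
                    spot = peak * np.exp(
                        -((cc - u) ** 2 + (rr - vv) ** 2) / (2.0 * sigma**2)
                    )
                    buffers[v][r0:r1, c0:c1, 1] += spot
                    spot_sum = float(spot[spot >= 0.5].sum())
                rec[f"green_sum{v + 1}"] = spot_sum
        records.extend(frame_records)
        for v in range(2):
            stacks[v][f] = np.clip(np.round(buffers[v]), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS)
    seq1 = FrameSequence(stacks[0], frame_rate=config.frame_rate)
    seq2 = FrameSequence(stacks[1], frame_rate=config.frame_rate)
    return seq1, seq2, truth


def write_fixture(
    outdir: str | Path,
    config: SceneConfig,
    cameras: tuple[CameraModel, CameraModel],
    sequences: tuple[FrameSequence, FrameSequence],
    ground_truth: pd.DataFrame,
) -> Path:
    """Write the on-disk fixture layout.

    ``view1/``, ``view2/`` hold numbered 8-bit RGB PNG frames; ``cam1.txt``
    and ``cam2.txt`` hold the 3x4 projection matrices (whitespace-separated
    rows, ``#`` comments); ``ground_truth.csv`` holds the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for v, seq in enumerate(sequences, start=1):
        vdir = outdir / f"view{v}"
        vdir.mkdir(exist_ok=True)
        for i in range(len(seq)):
            iio.imwrite(vdir / f"frame_{i:06d}.png", seq[i])
    for v, cam in enumerate(cameras, start=1):
        rows = "\n".join(" ".join(f"{x:.12g}" for x in row) for row in cam.projection)
        (outdir / f"cam{v}.txt").write_text(
            "# 3x4 projection matrix; pixel convention u=column, v=row, origin top-left\n"
            + rows + "\n"
        )
    ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    return outdir
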