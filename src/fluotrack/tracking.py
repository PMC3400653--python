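"""Cross-view pairing, 3D trajectory reconstruction, and motion statistics.

The two cameras are frame-synchronized, so pairing is by frame index: a
frame contributes a 3D point only when exactly one retained silhouette is
seen in each view (body orientation sometimes hides the animal from one
camera; several identical animals have no defined cross-view
correspondence, so multi-component frames are skipped for 3D while
remaining in the fluorescence output).  Each pair is triangulated by the
ray-midpoint method, carrying the closest-approach gap as a per-point
quality diagnostic.

Motion statistics: speed from consecutive positions (long frame gaps
break the series instead of producing spurious speeds), heading-change
events when the angle between incoming and outgoing displacements
exceeds a threshold (default 90 degrees), path length, and per-axis
position ranges.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .geometry3d import (
    CameraModel,
    DegenerateGeometryError,
    backproject_pixel,
    triangulate_midpoint,
)

__all__ = [
    "Observation2D",
    "TrackPoint3D",
    "MotionSummary",
    "components_to_observations",
    "pair_observations",
    "reconstruct_trajectory",
    "compute_velocity",
    "heading_change_frequency",
    "summarize_motion",
]


@dataclass(frozen=True)
class Observation2D:
    """One retained silhouette in one view of one frame."""

    frame_index: int
    view_id: int
    centroid: tuple[float, float]  # (row, col) pixels
    size: int
    intensity_sum: float  # selected-bin summed intensity


@dataclass(frozen=True)
class TrackPoint3D:
    """A triangulated position with its closest-approach gap."""

    frame_index: int
    position: np.ndarray  # (3,)
    gap: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.gap < 0:
            raise ValueError("gap must be >= 0")


@dataclass
class MotionSummary:
    """Velocity, turning, and spatial-extent statistics of one track."""

    speeds: np.ndarray  # world units / second, one per retained pair
    heading_change_count: int
    heading_change_frequency: float  # events / second
    path_length: float
    axis_ranges: tuple[tuple[float, float], ...]  # ((xmin,xmax),(ymin,ymax),(zmin,zmax))


def components_to_observations(result, channel: str, report_bins: tuple[int, ...]):
    """Flatten a processed view (see :mod:`fluotrack.pipeline`) to observations."""
    obs: list[Observation2D] = []
    for frame_idx, comps in sorted(result.components_per_frame.items()):
        hists = result.histograms_per_frame[frame_idx]
        for comp, hist_set in zip(comps, hists):
            obs.append(
                Observation2D(
                    frame_index=frame_idx,
                    view_id=comp.view_id,
                    centroid=comp.centroid,
                    size=comp.size,
                    intensity_sum=float(hist_set[channel].sum_over_bins(report_bins)),
                )
            )
    return obs


def pair_observations(
    view1_obs: list[Observation2D], view2_obs: list[Observation2D]
) -> tuple[list[tuple[Observation2D, Observation2D]], Counter]:
    """Match single detections across views frame by frame.

    Emits a pair for every frame holding exactly one observation in each
    view; other frames are skipped and tallied by reason ("missing view k"
    for an absent detection, "multiple view k" for ambiguous ones).
    """
    by_frame: dict[int, tuple[list, list]] = defaultdict(lambda: ([], []))
    for o in view1_obs:
        by_frame[o.frame_index][0].append(o)
    for o in view2_obs:
        by_frame[o.frame_index][1].append(o)
    pairs: list[tuple[Observation2D, Observation2D]] = []
    skips: Counter = Counter()
    for frame in sorted(by_frame):
        v1, v2 = by_frame[frame]
        ok = True
        for view, obs_list in ((1, v1), (2, v2)):
            if len(obs_list) == 0:
                skips[f"missing view {view}"] += 1
                ok = False
            elif len(obs_list) > 1:
                skips[f"multiple view {view}"] += 1
                ok = False
        if ok:
            pairs.append((v1[0], v2[0]))
    return pairs, skips


def reconstruct_trajectory(
    pairs: list[tuple[Observation2D, Observation2D]],
    cam1: CameraModel,
    cam2: CameraModel,
) -> tuple[list[TrackPoint3D], int]:
    """Triangulate each matched pair; returns (track, dropped-degenerate count)."""
    track: list[TrackPoint3D] = []
    n_degenerate = 0
    for o1, o2 in pairs:
        # centroid is (row, col); pixels are (u, v) = (col, row)
        x1 = np.array([o1.centroid[1], o1.centroid[0]])
        x2 = np.array([o2.centroid[1], o2.centroid[0]])
        try:
            point, gap = triangulate_midpoint(
                backproject_pixel(cam1, x1), backproject_pixel(cam2, x2)
            )
        except DegenerateGeometryError:
            n_degenerate += 1
            continue
        track.append(TrackPoint3D(frame_index=o1.frame_index, position=point, gap=gap))
    return track, n_degenerate


def compute_velocity(
    track: list[TrackPoint3D], frame_rate: float, max_frame_gap: int = 30
) -> np.ndarray:
    """Speeds over consecutive track points, world units per second.

    A pair of points separated by more than ``max_frame_gap`` frames
    breaks the series (no speed emitted) rather than diluting a long
    invisible interval into a spurious slow segment.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if len(track) < 2:
        return np.array([])
    speeds = []
    for a, b in zip(track, track[1:]):
        g = b.frame_index - a.frame_index
        if g <= 0:
            raise ValueError("track must be strictly increasing in frame index")
        if g > max_frame_gap:
            continue
        dist = float(np.linalg.norm(b.position - a.position))
        speeds.append(dist / (g / frame_rate))
    return np.asarray(speeds)


def heading_change_frequency(
    track: list[TrackPoint3D],
    frame_rate: float,
    angle_threshold: float = 90.0,
    max_frame_gap: int = 30,
) -> tuple[int, float]:
    """Count direction reversals sharper than ``angle_threshold`` degrees.

    At each interior point of a contiguous segment (consecutive gaps
    within ``max_frame_gap``), the angle between the incoming and
    outgoing displacement is measured; zero-length displacements are
    skipped.  Returns (event count, events per tracked second).
    """
    if len(track) < 3:
        return 0, 0.0
    events = 0
    tracked_seconds = 0.0
    cos_thresh = math.cos(math.radians(angle_threshold))
    for prev, here, nxt in zip(track, track[1:], track[2:]):
        g_in = here.frame_index - prev.frame_index
        g_out = nxt.frame_index - here.frame_index
        if g_in > max_frame_gap or g_out > max_frame_gap:
            continue
        tracked_seconds += (g_in + g_out) / (2.0 * frame_rate)
        v_in = here.position - prev.position
        v_out = nxt.position - here.position
        n_in, n_out = np.linalg.norm(v_in), np.linalg.norm(v_out)
        if n_in == 0 or n_out == 0:
            continue
        # angle > threshold  <=>  cos(angle) < cos(threshold)
        if float(v_in @ v_out) / (n_in * n_out) < cos_thresh:
            events += 1
    freq = events / tracked_seconds if tracked_seconds > 0 else 0.0
    return events, freq


def summarize_motion(
    track: list[TrackPoint3D],
    frame_rate: float,
    angle_threshold: float = 90.0,
    max_frame_gap: int = 30,
) -> MotionSummary:
    """All motion statistics of one reconstructed track."""
    speeds = compute_velocity(track, frame_rate, max_frame_gap=max_frame_gap)
    count, freq = heading_change_frequency(
        track, frame_rate, angle_threshold=angle_threshold, max_frame_gap=max_frame_gap
    )
    positions = np.array([p.position for p in track])
    path_length = 0.0
    for a, b in zip(track, track[1:]):
        if b.frame_index - a.frame_index <= max_frame_gap:
            path_length += float(np.linalg.norm(b.position - a.position))
    ranges = tuple(
        (float(positions[:, i].min()), float(positions[:, i].max())) for i in range(3)
    ) if len(track) else ((np.nan, np.nan),) * 3
    return MotionSummary(
        speeds=speeds,
        heading_change_count=count,
        heading_change_frequency=freq,
        path_length=path_length,
        axis_ranges=ranges,
    )
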