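"""Frame-sequence input, run configuration, and the batch driver.

Video enters either as a directory of lexicographically ordered image
frames (the synthetic fixture layout) or as a multi-frame image file
(e.g. a TIFF stack).  Frames are 8-bit RGB; intensity levels are the
integers 0-255.

The batch driver streams each source in chunks of ``chunk_frames`` with a
single persistent background model per view, so results are independent
of the chunk size.  The default chunk, 108,000 frames, is one hour of
video at 30 frames/s — the historical per-file recording limit of the
original rig, kept as a useful memory-bounded streaming unit.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry3d import load_projection_matrix

__all__ = [
    "FrameSequence",
    "RunConfig",
    "read_frames",
    "run_batch",
    "CHANNELS",
]

CHANNELS = {"red": 0, "green": 1, "blue": 2}

_FRAME_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

logger = logging.getLogger("fluotrack")


@dataclass
class FrameSequence:
    """An ordered stack of H x W x 3 8-bit frames at a fixed frame rate."""

    frames: np.ndarray  # (n, H, W, 3) uint8
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        a = np.asarray(self.frames)
        if a.ndim != 4 or a.shape[-1] != 3:
            raise ValueError(f"frames must be (n, H, W, 3), got {a.shape}")
        if a.dtype != np.uint8:
            raise ValueError(f"frames must be uint8 levels 0-255, got {a.dtype}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.frames = a

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_seconds(self) -> float:
        return len(self) / self.frame_rate


def _to_rgb8(a: np.ndarray, name: str) -> np.ndarray:
    """Coerce a single decoded image to H x W x 3 uint8."""
    if a.ndim == 2:
        a = np.stack([a] * 3, axis=-1)
    if a.ndim != 3 or a.shape[-1] not in (3, 4):
        raise ValueError(f"{name}: not an RGB image (shape {a.shape})")
    if a.shape[-1] == 4:
        a = a[..., :3]
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.max(initial=0) <= 255:
            a = a.astype(np.uint8)
        else:
            raise ValueError(f"{name}: frames must be 8-bit (dtype {a.dtype})")
    return a


def list_frame_files(source: str | Path) -> list[Path]:
    """Lexicographically sorted image files inside a frame directory."""
    source = Path(source)
    files = sorted(
        p for p in source.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
    )
    if not files:
        raise ValueError(f"{source}: no image frames found")
    return files


def read_frame_files(
    files: list[Path], frame_rate: float = 30.0, indices: list[int] | None = None
) -> FrameSequence:
    """Read selected files from an ordered frame list into a sequence."""
    chosen = files if indices is None else [files[i] for i in indices]
    frames = []
    shape = None
    for f in chosen:
        try:
            a = _to_rgb8(iio.imread(f), str(f))
        except (OSError, ValueError) as exc:
            raise ValueError(f"unreadable frame {f}: {exc}") from exc
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError(
                f"inconsistent frame size: {f} is {a.shape[:2]}, expected {shape[:2]}"
            )
        frames.append(a)
    return FrameSequence(np.stack(frames), frame_rate=frame_rate)


def read_frames(source: str | Path, frame_rate: float = 30.0) -> FrameSequence:
    """Read a video source: a frame directory or a multi-frame image file."""
    source = Path(source)
    if source.is_dir():
        return read_frame_files(list_frame_files(source), frame_rate=frame_rate)
    if not source.exists():
        raise ValueError(f"video source {source} does not exist")
    try:
        stack = np.asarray(iio.imread(source))
    except OSError as exc:
        raise ValueError(f"unreadable video source {source}: {exc}") from exc
    if stack.ndim == 4 or (stack.ndim == 3 and stack.shape[-1] not in (3, 4)):
        frames = [_to_rgb8(fr, f"{source}[{i}]") for i, fr in enumerate(stack)]
        return FrameSequence(np.stack(frames), frame_rate=frame_rate)
    raise ValueError(f"{source}: single image, not a frame sequence")


class _FrameSource:
    """Uniform chunked access to a directory of frames or an in-memory sequence."""

    def __init__(self, source: str | Path | FrameSequence, frame_rate: float):
        if isinstance(source, FrameSequence):
            self._seq: FrameSequence | None = source
            self._files: list[Path] | None = None
            self.n_frames = len(source)
        else:
            src = Path(source)
            if src.is_dir():
                self._seq = None
                self._files = list_frame_files(src)
                self.n_frames = len(self._files)
            else:
                self._seq = read_frames(src, frame_rate)
                self._files = None
                self.n_frames = len(self._seq)
        self.frame_rate = frame_rate

    def read(self, indices: list[int]) -> FrameSequence:
        if self._seq is not None:
            return FrameSequence(self._seq.frames[indices], frame_rate=self.frame_rate)
        return read_frame_files(self._files, self.frame_rate, indices)  # type: ignore[arg-type]

    def read_range(self, start: int, stop: int) -> FrameSequence:
        return self.read(list(range(start, min(stop, self.n_frames))))


@dataclass
class RunConfig:
    """All parameters of a two-view batch run.

    Defaults follow the recommended operating point: detection on the green
    channel (GFP), |I - mu| > threshold with a slowly adapting background,
    3x3 opening, and per-minute G3+G4 reporting smoothed by LOESS.
    """

    video1: str = ""
    video2: str = ""
    matrix1: str = ""
    matrix2: str = ""
    outdir: str = "fluotrack_out"

    threshold: float = 50.0
    alpha: float = 0.05
    sample_fraction: float = 0.01
    channel: str = "green"
    min_component_size: int = 5
    connectivity: int = 8
    bin_edges: tuple[int, ...] = (0, 64, 128, 192, 256)
    report_bins: tuple[int, ...] = (3, 4)  # G3+G4: reporter carries the high bins
    loess_span: float = 0.1
    loess_degree: int = 2
    onset_baseline_minutes: int = 30
    angle_threshold: float = 90.0
    frame_rate: float = 30.0
    max_frame_gap: int = 30
    missing_frame_policy: str = "zero"  # or "skip"
    chunk_frames: int = 108_000  # one hour at 30 fps per processing unit

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {sorted(CHANNELS)}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.missing_frame_policy not in ("zero", "skip"):
            raise ValueError("missing_frame_policy must be 'zero' or 'skip'")
        if self.chunk_frames < 1:
            raise ValueError("chunk_frames must be >= 1")
        self.bin_edges = tuple(int(e) for e in self.bin_edges)
        self.report_bins = tuple(int(b) for b in self.report_bins)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def content_hash(self) -> str:
        """Short hash of the analysis parameters (paths and chunking excluded,
        so the same analysis carries the same provenance tag however it is
        chunked or relocated)."""
        skip = {"video1", "video2", "matrix1", "matrix2", "outdir", "chunk_frames"}
        payload = ";".join(
            f"{k}={v}" for k, v in sorted(asdict(self).items()) if k not in skip
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def frames_per_hour(frame_rate: float) -> int:
    """Frame count of a one-hour recording chunk at the given frame rate."""
    return int(round(3600 * frame_rate))


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """CSV with a provenance header comment (version + config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# fluotrack {__version__} config_hash={config.content_hash()}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_batch(
    config: RunConfig,
    sources: tuple[FrameSequence, FrameSequence] | None = None,
) -> Path:
    """Run the full two-view pipeline and write the output CSV set.

    Each view is processed in chunks of ``config.chunk_frames`` with one
    persistent background model (initialized from ``sample_fraction`` of
    the total frames before streaming starts).  Outputs in ``outdir``:

    - ``detections.csv``   — frame, view, component id, size, centroid, bbox
    - ``fluorescence.csv`` — per-component 4-bin histograms, all 3 channels
    - ``per_minute.csv``   — minute, raw mean, LOESS-smoothed mean
    - ``trajectory.csv``   — frame, x, y, z, gap (single-animal 3D track)
    - ``summary.csv``      — motion statistics and pairing skip counts
    - ``run.log``          — per-chunk, per-stage progress lines

    ``sources`` may supply in-memory sequences (testing); otherwise the
    configured paths are read.
    """
    from .background import initialize_background
    from .fluorescence import aggregate_per_minute, loess_smooth
    from .pipeline import process_sequence
    from .tracking import (
        components_to_observations,
        pair_observations,
        reconstruct_trajectory,
        summarize_motion,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        if sources is not None:
            view_sources = [_FrameSource(s, config.frame_rate) for s in sources]
        else:
            view_sources = [
                _FrameSource(config.video1, config.frame_rate),
                _FrameSource(config.video2, config.frame_rate),
            ]
        cams = None
        if config.matrix1 and config.matrix2:
            cams = (
                load_projection_matrix(config.matrix1, view_id=1),
                load_projection_matrix(config.matrix2, view_id=2),
            )

        det_rows: list[dict] = []
        fluor_rows: list[dict] = []
        obs_per_view: list[list] = []
        n_frames_per_view: list[int] = []

        for view_id, src in enumerate(view_sources, start=1):
            n_total = src.n_frames
            n_frames_per_view.append(n_total)
            n_init = max(math.ceil(config.sample_fraction * n_total), 2)
            init_idx = np.unique(
                np.round(np.linspace(0, n_total - 1, n_init)).astype(int)
            ).tolist()
            model = initialize_background(
                src.read(init_idx),
                sample_fraction=1.0,  # the index selection above already sampled
                threshold=config.threshold,
                alpha=config.alpha,
                channel=config.channel,
            )
            logger.info(
                "view=%d stage=init frames_sampled=%d of=%d", view_id, len(init_idx), n_total
            )

            view_obs = []
            for start in range(0, n_total, config.chunk_frames):
                chunk = src.read_range(start, start + config.chunk_frames)
                result = process_sequence(
                    chunk,
                    model,
                    min_size=config.min_component_size,
                    connectivity=config.connectivity,
                    view_id=view_id,
                    frame_offset=start,
                    bin_edges=config.bin_edges,
                )
                for frame_idx, comps in result.components_per_frame.items():
                    for cid, comp in enumerate(comps):
                        det_rows.append(
                            {
                                "frame": frame_idx,
                                "view": view_id,
                                "component_id": cid,
                                "size_px": comp.size,
                                "centroid_row": comp.centroid[0],
                                "centroid_col": comp.centroid[1],
                                "bbox_min_row": comp.bounding_box[0],
                                "bbox_min_col": comp.bounding_box[1],
                                "bbox_max_row": comp.bounding_box[2],
                                "bbox_max_col": comp.bounding_box[3],
                            }
                        )
                for frame_idx, hist_sets in result.histograms_per_frame.items():
                    for cid, hists in enumerate(hist_sets):
                        row = {
                            "frame": frame_idx,
                            "view": view_id,
                            "component_id": cid,
                            "size_px": result.components_per_frame[frame_idx][cid].size,
                        }
                        for ch_name, letter in (("red", "R"), ("green", "G"), ("blue", "B")):
                            h = hists[ch_name]
                            for b in range(4):
                                row[f"{letter}{b + 1}"] = h.intensity_sums[b]
                                row[f"{letter}{b + 1}_count"] = h.counts[b]
                        fluor_rows.append(row)
                view_obs.extend(
                    components_to_observations(
                        result, config.channel, config.report_bins
                    )
                )
                logger.info(
                    "view=%d stage=detect chunk=%d frames=%d-%d components=%d",
                    view_id,
                    start // config.chunk_frames,
                    start,
                    start + len(chunk) - 1,
                    sum(len(c) for c in result.components_per_frame.values()),
                )
            obs_per_view.append(view_obs)

        det_df = pd.DataFrame(
            det_rows,
            columns=[
                "frame", "view", "component_id", "size_px", "centroid_row",
                "centroid_col", "bbox_min_row", "bbox_min_col", "bbox_max_row",
                "bbox_max_col",
            ],
        )
        _write_csv(det_df, outdir / "detections.csv", config)
        fluor_cols = ["frame", "view", "component_id", "size_px"]
        for letter in "RGB":
            fluor_cols += [f"{letter}{b}" for b in range(1, 5)]
        for letter in "RGB":
            fluor_cols += [f"{letter}{b}_count" for b in range(1, 5)]
        _write_csv(pd.DataFrame(fluor_rows, columns=fluor_cols), outdir / "fluorescence.csv", config)

        # --- per-minute reporter time course, pooled over views and components
        n_frames = max(n_frames_per_view)
        per_frame = np.zeros(n_frames)
        seen = np.zeros(n_frames, dtype=bool)
        for view_obs in obs_per_view:
            for obs in view_obs:
                per_frame[obs.frame_index] += obs.intensity_sum
                seen[obs.frame_index] = True
        if config.missing_frame_policy == "skip":
            per_frame = np.where(seen, per_frame, np.nan)
        logger.info(
            "stage=fluor frames=%d frames_without_detections=%d policy=%s",
            n_frames, int((~seen).sum()), config.missing_frame_policy,
        )
        per_minute = aggregate_per_minute(
            per_frame, config.frame_rate, skip_missing=config.missing_frame_policy == "skip"
        )
        minutes = np.arange(len(per_minute))
        valid = np.isfinite(per_minute)
        smooth = np.full(len(per_minute), np.nan)
        min_pts = config.loess_degree + 2
        if valid.sum() >= min_pts:
            smooth[valid] = loess_smooth(
                per_minute[valid],
                span=config.loess_span,
                degree=config.loess_degree,
                x=minutes[valid].astype(float),
            )
        _write_csv(
            pd.DataFrame(
                {"minute": minutes, "raw_mean": per_minute, "loess_mean": smooth}
            ),
            outdir / "per_minute.csv",
            config,
        )

        # --- 3D trajectory (single-animal frames only) and motion summary
        traj_df = pd.DataFrame(columns=["frame", "x", "y", "z", "gap"])
        summary = {
            "n_frames": n_frames,
            "n_pairs": 0,
            "n_points": 0,
            "mean_speed": np.nan,
            "heading_change_freq": np.nan,
            "path_length": np.nan,
        }
        skips: dict[str, int] = {}
        if cams is not None:
            pairs, skips = pair_observations(obs_per_view[0], obs_per_view[1])
            track, n_degenerate = reconstruct_trajectory(pairs, cams[0], cams[1])
            logger.info(
                "stage=track pairs=%d skipped=%s degenerate=%d",
                len(pairs), dict(skips), n_degenerate,
            )
            summary["n_pairs"] = len(pairs)
            summary["n_points"] = len(track)
            if track:
                traj_df = pd.DataFrame(
                    {
                        "frame": [p.frame_index for p in track],
                        "x": [p.position[0] for p in track],
                        "y": [p.position[1] for p in track],
                        "z": [p.position[2] for p in track],
                        "gap": [p.gap for p in track],
                    }
                )
                motion = summarize_motion(
                    track,
                    config.frame_rate,
                    angle_threshold=config.angle_threshold,
                    max_frame_gap=config.max_frame_gap,
                )
                summary["mean_speed"] = (
                    float(np.mean(motion.speeds)) if len(motion.speeds) else np.nan
                )
                summary["heading_change_freq"] = motion.heading_change_frequency
                summary["path_length"] = motion.path_length
                for axis, (lo, hi) in zip("xyz", motion.axis_ranges):
                    summary[f"{axis}_min"], summary[f"{axis}_max"] = lo, hi
        for reason, count in sorted(skips.items()):
            summary[f"skipped_{reason.replace(' ', '_')}"] = count
        _write_csv(traj_df, outdir / "trajectory.csv", config)
        _write_csv(pd.DataFrame([summary]), outdir / "summary.csv", config)
        logger.info("stage=done outdir=%s", outdir)
        return outdir
    finally:
        logger.removeHandler(handler)
        handler.close()
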