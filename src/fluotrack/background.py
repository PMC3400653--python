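"""Running-Gaussian background model with selective update.

The background is modeled independently at each pixel by an exponentially
weighted running mean ``mu`` of the detection-channel intensity.  A pixel
of the current frame is classified foreground when ``|I - mu| > T`` for a
fixed, empirically chosen threshold ``T``.  After classification the model
is updated *selectively*: only pixels classified background are blended,

    mu <- (1 - alpha) * mu + alpha * I,

so a resting animal never bleeds into the model.  The adaptation rate
``alpha`` in [0, 1] trades stability (small alpha) against speed of
update (large alpha); the default 0.05 suits slow background drift over
multi-hour dark-chamber recordings.

To give the very first frame a usable background, a small fraction of the
whole recording (default 1%) is sampled at even intervals and averaged.

An optional per-pixel running variance is tracked with the same selective
exponential rule, purely as instrumentation — it never enters the
classification test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CHANNELS, FrameSequence

__all__ = [
    "BackgroundModel",
    "ChangeMask",
    "initialize_background",
    "classify_frame",
    "update_background",
]


@dataclass
class ChangeMask:
    """Binary foreground mask for one frame (1 = foreground)."""

    mask: np.ndarray  # (H, W) bool
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.mask.shape}")

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())

    def background_mask(self) -> np.ndarray:
        """The complementary polarity (1 = background)."""
        return ~self.mask


@dataclass
class BackgroundModel:
    """Per-pixel running mean (and optional variance) with threshold."""

    mean_image: np.ndarray  # (H, W) float, levels
    threshold: float
    alpha: float
    channel: str = "green"
    variance_image: np.ndarray | None = None  # levels^2
    frames_seen: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {sorted(CHANNELS)}")
        self.mean_image = np.asarray(self.mean_image, dtype=float)
        if self.mean_image.ndim != 2:
            raise ValueError("mean_image must be 2-D")
        if self.mean_image.min() < 0 or self.mean_image.max() > 255:
            raise ValueError("mean_image values must lie in [0, 255]")


def _detection_channel(frame: np.ndarray, channel: str) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return frame[..., CHANNELS[channel]].astype(float)
    if frame.ndim == 2:
        return frame.astype(float)
    raise ValueError(f"frame must be H x W or H x W x 3, got shape {frame.shape}")


def sample_indices(n_frames: int, sample_fraction: float) -> np.ndarray:
    """Evenly spaced frame indices covering first through last frame.

    Selects ``max(ceil(sample_fraction * n_frames), 2)`` indices, so 1% of
    a 10,000-frame video is exactly 100 frames; short sequences always
    contribute at least two.
    """
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    if n_frames < 1:
        raise ValueError("cannot sample an empty sequence")
    k = min(max(math.ceil(sample_fraction * n_frames), 2), n_frames)
    return np.unique(np.round(np.linspace(0, n_frames - 1, k)).astype(int))


def initialize_background(
    frames: FrameSequence,
    sample_fraction: float = 0.01,
    *,
    threshold: float = 50.0,
    alpha: float = 0.05,
    channel: str = "green",
    track_variance: bool = False,
) -> BackgroundModel:
    """Build the initial background from evenly sampled frames.

    ``mean_image`` is the per-pixel arithmetic mean of the detection
    channel over the sampled frames.
    """
    if len(frames) == 0:
        raise ValueError("cannot initialize background from an empty sequence")
    idx = sample_indices(len(frames), sample_fraction)
    stack = np.stack([_detection_channel(frames[i], channel) for i in idx])
    mean = stack.mean(axis=0)
    var = stack.var(axis=0) if track_variance else None
    return BackgroundModel(
        mean_image=mean,
        threshold=threshold,
        alpha=alpha,
        channel=channel,
        variance_image=var,
        frames_seen=len(idx),
    )


def classify_frame(
    frame: np.ndarray, model: BackgroundModel, frame_index: int = 0
) -> ChangeMask:
    """Threshold the frame against the background: foreground iff |I - mu| > T.

    Pure function — the model is not touched.
    """
    intensity = _detection_channel(frame, model.channel)
    if intensity.shape != model.mean_image.shape:
        raise ValueError(
            f"frame shape {intensity.shape} does not match model {model.mean_image.shape}"
        )
    fg = np.abs(intensity - model.mean_image) > model.threshold
    return ChangeMask(mask=fg, frame_index=frame_index)


def update_background(
    model: BackgroundModel, frame: np.ndarray, mask: ChangeMask
) -> BackgroundModel:
    """Selective exponential update of the model from one classified frame.

    Background pixels blend toward the frame with weight ``alpha``;
    foreground pixels are left untouched.  The model is updated in place
    and returned.
    """
    intensity = _detection_channel(frame, model.channel)
    if intensity.shape != model.mean_image.shape or mask.mask.shape != intensity.shape:
        raise ValueError("frame/mask dimensions do not match the model")
    bg = mask.background_mask()
    a = model.alpha
    model.mean_image[bg] = (1.0 - a) * model.mean_image[bg] + a * intensity[bg]
    if model.variance_image is not None:
        dev = intensity[bg] - model.mean_image[bg]
        model.variance_image[bg] = (1.0 - a) * model.variance_image[bg] + a * dev**2
    model.frames_seen += 1
    return model
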