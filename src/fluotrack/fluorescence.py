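"""Per-component fluorescence quantification and reporter time courses.

For each detected silhouette and each color channel, the member pixels
are split into four intensity bins of increasing brightness (G1-G4 for
the green channel), recording both pixel counts and summed intensities
per bin.  Binning instead of a plain mean preserves signal when the
fluorescing region occupies a different fraction of each animal:
background and tissue autofluorescence fall almost entirely into the
lowest bin, while reporter signal populates the upper bins.

To compare samples, the highest bin populated in *every* sample is used;
when a sample is empty there, the next lower bin is merged in (G4, then
G4+G3, ...) until all samples are represented.

Time courses average the pooled selected-bin intensity per minute and
are smoothed by LOESS (tricube-weighted local polynomial regression;
default span 0.1, degree 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CHANNELS
from .silhouette import Component

__all__ = [
    "DEFAULT_BIN_EDGES",
    "ChannelHistogram",
    "FluorescenceSeries",
    "bin_component_intensities",
    "select_reporting_bin",
    "aggregate_per_minute",
    "loess_smooth",
    "detect_onset",
    "build_fluorescence_series",
]

# equal-width quartiles of the 0-255 level range
DEFAULT_BIN_EDGES: tuple[int, ...] = (0, 64, 128, 192, 256)


@dataclass
class ChannelHistogram:
    """4-bin intensity histogram of one component in one channel.

    ``counts[k]`` and ``intensity_sums[k]`` cover levels in
    ``[bin_edges[k], bin_edges[k+1])``; bin 1 is dimmest, bin 4 brightest.
    """

    channel: str
    counts: np.ndarray  # (4,) int
    intensity_sums: np.ndarray  # (4,) int (sums of integer levels)
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {sorted(CHANNELS)}")
        edges = tuple(self.bin_edges)
        if len(edges) != 5 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges must be 5 ascending levels")
        self.bin_edges = edges
        self.counts = np.asarray(self.counts, dtype=int)
        self.intensity_sums = np.asarray(self.intensity_sums, dtype=int)
        if self.counts.shape != (4,) or self.intensity_sums.shape != (4,):
            raise ValueError("counts and intensity_sums must each have 4 entries")
        if (self.counts < 0).any() or (self.intensity_sums < 0).any():
            raise ValueError("counts and intensity_sums must be non-negative")

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())

    def sum_over_bins(self, bins: tuple[int, ...]) -> int:
        """Summed intensity over a set of 1-based bin numbers."""
        return int(sum(self.intensity_sums[b - 1] for b in bins))


def bin_component_intensities(
    frame: np.ndarray,
    component: Component,
    channel: str = "green",
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
) -> ChannelHistogram:
    """Assign each member pixel to its intensity bin; accumulate counts and sums."""
    frame = np.asarray(frame)
    rows = component.pixel_coords[:, 0]
    cols = component.pixel_coords[:, 1]
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= frame.shape[0]
        or cols.max() >= frame.shape[1]
    ):
        raise ValueError("component pixels fall outside the frame bounds")
    if frame.ndim == 3:
        values = frame[rows, cols, CHANNELS[channel]].astype(int)
    else:
        values = frame[rows, cols].astype(int)
    edges = np.asarray(bin_edges)
    idx = np.searchsorted(edges, values, side="right") - 1
    if idx.min() < 0 or idx.max() > 3:
        raise ValueError("pixel intensity outside the binned range")
    counts = np.bincount(idx, minlength=4)
    sums = np.bincount(idx, weights=values, minlength=4).astype(int)
    return ChannelHistogram(
        channel=channel, counts=counts, intensity_sums=sums, bin_edges=tuple(bin_edges)
    )


def select_reporting_bin(histograms: list[ChannelHistogram]) -> tuple[int, ...]:
    """Top-anchored contiguous bin set populated in every sample.

    Returns ``(4,)`` when every sample has bin-4 pixels; otherwise extends
    downward — ``(4, 3)``, ``(4, 3, 2)``, ``(4, 3, 2, 1)`` — until each
    sample has at least one pixel in the union.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    channels = {h.channel for h in histograms}
    if len(channels) > 1:
        raise ValueError(f"histograms mix channels: {sorted(channels)}")
    if any(h.total_pixels == 0 for h in histograms):
        raise ValueError("a sample has zero pixels: no valid reporting bin set")
    for lowest in (4, 3, 2, 1):
        bins = tuple(range(4, lowest - 1, -1))
        if all(sum(h.counts[b - 1] for b in bins) > 0 for h in histograms):
            return bins
    raise AssertionError("unreachable: non-empty samples must populate some bin")


def aggregate_per_minute(
    per_frame_values: np.ndarray, frame_rate: float, skip_missing: bool = False
) -> np.ndarray:
    """Mean over consecutive one-minute blocks of frames.

    A block is ``round(60 * frame_rate)`` frames; a trailing partial
    minute averages whatever frames it has.  With ``skip_missing``,
    NaN entries (frames without detections) are excluded from each
    block mean instead of counting as zero.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    values = np.asarray(per_frame_values, dtype=float)
    if values.size == 0:
        return np.array([])
    block = max(int(round(60 * frame_rate)), 1)
    n_blocks = math.ceil(values.size / block)
    out = np.empty(n_blocks)
    for i in range(n_blocks):
        chunk = values[i * block : (i + 1) * block]
        if skip_missing:
            out[i] = np.nanmean(chunk) if np.isfinite(chunk).any() else np.nan
        else:
            out[i] = chunk.mean()
    return out


def loess_smooth(
    series: np.ndarray,
    span: float = 0.1,
    degree: int = 2,
    x: np.ndarray | None = None,
) -> np.ndarray:
    """LOESS: tricube-weighted local polynomial regression.

    At each point the ``k = max(ceil(span * n), degree + 2)`` nearest
    neighbors (in ``x``) are fit with a degree-``degree`` polynomial by
    weighted least squares, weights tricube in scaled distance, and the
    fit is evaluated at the point.  Exact on polynomials up to the fitted
    degree.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    min_len = degree + 2
    if n < min_len:
        raise ValueError(f"series too short for LOESS: need >= {min_len} points, got {n}")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if x is None:
        x = np.arange(n, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and series must have equal length")
    k = min(max(math.ceil(span * n), min_len), n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        local = np.argpartition(d, k - 1)[:k]
        dmax = d[local].max()
        if dmax == 0:
            out[i] = y[local].mean()
            continue
        w = (1.0 - (d[local] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # guard: the farthest neighbor gets weight 0; keep the fit solvable
        if np.count_nonzero(w) <= degree:
            w = w + 1e-9
        coeffs = np.polynomial.polynomial.polyfit(
            x[local] - x[i], y[local], deg=degree, w=np.sqrt(w)
        )
        out[i] = coeffs[0]
    return out


def detect_onset(
    smoothed: np.ndarray,
    baseline_minutes: int = 30,
    k: float = 3.0,
    min_hold: int = 10,
) -> int | None:
    """First minute the smoothed series rises and stays above baseline.

    The threshold is baseline mean + ``k`` x baseline SD over the first
    ``baseline_minutes`` points; a candidate onset must remain above it
    for at least ``min_hold`` consecutive minutes.  Returns None when the
    series never sustains an excursion.  This is a convenience readout —
    onset is conventionally judged from the smoothed plot by eye.
    """
    y = np.asarray(smoothed, dtype=float)
    if baseline_minutes >= y.size:
        raise ValueError("baseline window must be shorter than the series")
    base = y[:baseline_minutes]
    thresh = base.mean() + k * base.std()
    above = y > thresh
    run = 0
    for i in range(baseline_minutes, y.size):
        run = run + 1 if above[i] else 0
        if run >= min_hold:
            return i - run + 1
    return None


@dataclass
class FluorescenceSeries:
    """Bundled reporter time course: per-frame, per-minute, and smoothed."""

    per_frame: np.ndarray
    per_minute: np.ndarray
    smoothed: np.ndarray
    frame_rate: float
    report_bins: tuple[int, ...] = (3, 4)

    @property
    def minutes(self) -> np.ndarray:
        return np.arange(self.per_minute.size)


def build_fluorescence_series(
    per_frame_values: np.ndarray,
    frame_rate: float,
    span: float = 0.1,
    degree: int = 2,
    report_bins: tuple[int, ...] = (3, 4),
) -> FluorescenceSeries:
    """Aggregate a per-frame pooled intensity series to its smoothed per-minute curve."""
    per_minute = aggregate_per_minute(per_frame_values, frame_rate)
    smoothed = loess_smooth(per_minute, span=span, degree=degree)
    return FluorescenceSeries(
        per_frame=np.asarray(per_frame_values, dtype=float),
        per_minute=per_minute,
        smoothed=smoothed,
        frame_rate=frame_rate,
        report_bins=tuple(report_bins),
    )
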