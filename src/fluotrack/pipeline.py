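"""Per-view detection pipeline: classify, open, label, filter, bin, update.

Ties the background model, silhouette extraction and fluorescence binning
together for one frame sequence, carrying the background model across
calls so a long recording can be streamed chunk by chunk with identical
results to a single pass.

The selective background update uses the raw classified mask: the
animal's pixels must be flagged foreground when the model is updated, or
a resting animal would be absorbed into the background.  Morphological
opening is applied only on the component-extraction path, where isolated
noise pixels would otherwise masquerade as tiny silhouettes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .background import BackgroundModel, classify_frame, update_background
from .fluorescence import DEFAULT_BIN_EDGES, ChannelHistogram, bin_component_intensities
from .io import CHANNELS, FrameSequence
from .silhouette import Component, filter_components, label_components, morphological_open

__all__ = ["ProcessedView", "process_sequence"]


@dataclass
class ProcessedView:
    """Detections and per-component histograms for one view's frames."""

    view_id: int
    components_per_frame: dict[int, list[Component]] = field(default_factory=dict)
    # one {channel: ChannelHistogram} per component, aligned with components_per_frame
    histograms_per_frame: dict[int, list[dict[str, ChannelHistogram]]] = field(
        default_factory=dict
    )

    @property
    def n_frames(self) -> int:
        return len(self.components_per_frame)

    def frames_with_exactly_one(self) -> list[int]:
        return [f for f, c in self.components_per_frame.items() if len(c) == 1]


def process_sequence(
    frames: FrameSequence,
    model: BackgroundModel,
    *,
    min_size: int = 5,
    connectivity: int = 8,
    view_id: int = 0,
    frame_offset: int = 0,
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
    channels: tuple[str, ...] = ("red", "green", "blue"),
) -> ProcessedView:
    """Run detection over a (chunk of a) sequence, updating ``model`` in place.

    Frame indices in the result are offset by ``frame_offset`` so chunked
    processing yields globally consistent indices.
    """
    result = ProcessedView(view_id=view_id)
    for i in range(len(frames)):
        frame = frames[i]
        global_idx = frame_offset + i
        raw_mask = classify_frame(frame, model, frame_index=global_idx)
        opened = morphological_open(raw_mask)
        comps = filter_components(
            label_components(opened, connectivity=connectivity, view_id=view_id),
            min_size,
        )
        result.components_per_frame[global_idx] = comps
        result.histograms_per_frame[global_idx] = [
            {
                ch: bin_component_intensities(frame, comp, channel=ch, bin_edges=bin_edges)
                for ch in channels
            }
            for comp in comps
        ]
        update_background(model, frame, raw_mask)
    return result
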