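"""Silhouette extraction from binary change masks.

Stray single pixels are removed by morphological opening (erosion then
dilation with a 3x3 square structural element) which leaves animal-sized
components essentially unchanged; the survivors are partitioned into
connected components, filtered by size, and summarized by their geometric
centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .background import ChangeMask

__all__ = [
    "Component",
    "morphological_open",
    "label_components",
    "filter_components",
    "component_centroid",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class Component:
    """One detected silhouette: its pixels plus derived geometry."""

    pixel_coords: np.ndarray  # (n, 2) int (row, col)
    frame_index: int = 0
    view_id: int = 0

    def __post_init__(self) -> None:
        coords = np.asarray(self.pixel_coords, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("pixel_coords must be a non-empty (n, 2) array")
        self.pixel_coords = coords

    @property
    def size(self) -> int:
        return self.pixel_coords.shape[0]

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        mins = self.pixel_coords.min(axis=0)
        maxs = self.pixel_coords.max(axis=0)
        return int(mins[0]), int(mins[1]), int(maxs[0]), int(maxs[1])

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.pixel_coords.mean(axis=0)
        return float(r), float(c)


def _mask_array(mask: ChangeMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, ChangeMask):
        return mask.mask
    return np.asarray(mask).astype(bool)


def morphological_open(mask: ChangeMask) -> ChangeMask:
    """Opening by the 3x3 square element (erosion then dilation).

    Out-of-image neighborhoods count as background, so a silhouette
    touching the image edge loses its one-pixel rim, as erosion demands.
    """
    m = _mask_array(mask)
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(m, structure=_SQUARE3, border_value=0),
        structure=_SQUARE3,
        border_value=0,
    )
    idx = mask.frame_index if isinstance(mask, ChangeMask) else 0
    return ChangeMask(mask=opened, frame_index=idx)


def label_components(
    mask: ChangeMask, connectivity: int = 8, view_id: int = 0
) -> list[Component]:
    """Partition foreground pixels into maximal connected components.

    8-connectivity by default, so thin diagonal silhouette fragments stay
    one component.  Components are ordered by (min_row, min_col).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    m = _mask_array(mask)
    frame_index = mask.frame_index if isinstance(mask, ChangeMask) else 0
    labels = measure.label(m, connectivity=1 if connectivity == 4 else 2)
    comps = [
        Component(
            pixel_coords=np.argwhere(labels == lab),
            frame_index=frame_index,
            view_id=view_id,
        )
        for lab in range(1, labels.max() + 1)
    ]
    comps.sort(key=lambda c: c.bounding_box[:2])
    return comps


def filter_components(components: list[Component], min_size: int) -> list[Component]:
    """Drop components strictly smaller than ``min_size`` pixels.

    A component of exactly ``min_size`` pixels is kept; order is preserved.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    return [c for c in components if c.size >= min_size]


def component_centroid(component: Component) -> tuple[float, float]:
    """Unweighted mean of member pixel coordinates, (row, col)."""
    return component.centroid
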