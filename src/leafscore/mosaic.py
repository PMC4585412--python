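"""Frame mosaicking and whole-leaf object extraction.

Frames acquired one after another down the scan direction are stitched by
row concatenation; labelling connected components globally on the stitched
canvas is equivalent to cutting a leaf at a frame boundary and reconnecting
it to its remaining portion in the next frame, and is much simpler to
verify.  Because per-frame channel correction background-fills the last
``max(channel offsets)`` rows of every frame, a leaf crossing a boundary
arrives with a thin off-band gap there; :func:`bridge_frame_boundaries`
reconnects it by filling the vacated rows in every column that has leaf
foreground immediately above and below the gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

from .channels import ScanFrame
from .errors import InputError

__all__ = ["LeafObject", "stitch", "bridge_frame_boundaries", "extract_leaves"]


@dataclass
class LeafObject:
    """One connected leaf component on the task canvas."""

    mask: np.ndarray  # boolean crop over the bounding box
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1) half-open
    pixel_count: int
    class_pixel_counts: dict[str, int] = field(default_factory=dict)

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Expand the crop back to a full-canvas mask."""
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


def stitch(frames: list[ScanFrame]) -> np.ndarray:
    """Concatenate ordered frames of one task into the full canvas."""
    if not frames:
        raise InputError("no frames to stitch")
    widths = {f.width for f in frames}
    if len(widths) != 1:
        raise InputError(f"frames disagree on width: {sorted(widths)}")
    tasks = {f.task_id for f in frames}
    if len(tasks) != 1:
        raise InputError(f"frames belong to different tasks: {sorted(tasks)}")
    indices = [f.frame_index for f in frames]
    if indices != list(range(min(indices), min(indices) + len(frames))):
        raise InputError(f"frame indices not contiguous/ordered: {indices}")
    return np.concatenate([f.pixels for f in frames], axis=0)


def bridge_frame_boundaries(
    mask: np.ndarray, frame_height: int, max_offset: int
) -> np.ndarray:
    """Reconnect leaves split by the per-frame correction edge fill.

    At every frame boundary ``b`` the rows ``[b - max_offset, b)`` were
    background-filled during channel correction.  For each column that has
    foreground both directly above the vacated band and at the boundary
    row, the vacated rows are re-marked as foreground.  A no-op when
    ``max_offset`` is 0.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    if max_offset <= 0:
        return mask
    rows = mask.shape[0]
    for b in range(frame_height, rows, frame_height):
        above = b - max_offset - 1
        if above < 0:
            continue
        cols = mask[above] & mask[b]
        if cols.any():
            mask[b - max_offset : b, cols] = True
    return mask


def extract_leaves(
    total_mask: np.ndarray,
    class_masks: dict[str, np.ndarray] | None = None,
    min_leaf_px: int = 200,
) -> list[LeafObject]:
    """Extract one :class:`LeafObject` per 8-connected component.

    Components below ``min_leaf_px`` pixels are dropped (surviving
    impurities and broken slivers).  Objects are ordered by bounding-box
    top row, then left column.  ``class_masks`` (full-canvas boolean masks
    per colour class) supply the per-leaf class pixel counts.
    """
    total_mask = np.asarray(total_mask, dtype=bool)
    labels = skmeasure.label(total_mask, connectivity=2)
    objects: list[LeafObject] = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_leaf_px:
            continue
        r0, c0, r1, c1 = region.bbox
        crop = labels[r0:r1, c0:c1] == region.label
        counts: dict[str, int] = {}
        for name, cmask in (class_masks or {}).items():
            counts[name] = int(np.count_nonzero(cmask[r0:r1, c0:c1] & crop))
        objects.append(
            LeafObject(
                mask=crop,
                bbox=(r0, c0, r1, c1),
                pixel_count=int(region.area),
                class_pixel_counts=counts,
            )
        )
    objects.sort(key=lambda o: (o.bbox[0], o.bbox[1]))
    return objects
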