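"""Tri-linear sensor channel registration.

The camera's red, green and blue sensor lines are physically offset along
the scan direction, so a raw frame has its green and blue planes displaced
*down* the scan axis relative to red.  Correction shifts the green and blue
planes back up by whole line counts (red is the reference and is never
touched) and refills the vacated bottom rows with the background value.
The refilled rows are the only place where correction is lossy; the mosaic
stage reconnects leaves that were split across a frame boundary by this
edge fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanFrame", "correct_channels", "shift_plane"]


@dataclass
class ScanFrame:
    """One RGB raster strip of the scan sequence."""

    pixels: np.ndarray  # (rows, cols, 3) uint8
    frame_index: int = 0
    task_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise ValueError("frame pixels must have shape (rows, cols, 3)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("frame must have positive height and width")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.pixels.dtype != np.uint8:
            if np.issubdtype(self.pixels.dtype, np.integer) and (
                self.pixels.min() >= 0 and self.pixels.max() <= 255
            ):
                self.pixels = self.pixels.astype(np.uint8)
            else:
                raise ValueError("frame pixels must be 8-bit (0-255)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def shift_plane(plane: np.ndarray, shift_up: int, fill: int) -> np.ndarray:
    """Translate a 2-D plane up by ``shift_up`` rows, filling vacated rows."""
    if shift_up == 0:
        return plane.copy()
    out = np.full_like(plane, fill)
    out[:-shift_up] = plane[shift_up:]
    return out


def correct_channels(
    frame: ScanFrame | np.ndarray,
    offsets: tuple[int, int],
    fill: tuple[int, int, int] = (0, 0, 0),
) -> ScanFrame | np.ndarray:
    """Shift the green and blue planes up into registration with red.

    Parameters
    ----------
    frame:
        A :class:`ScanFrame` or a bare ``(rows, cols, 3)`` uint8 array.
        Returns the same type as given; the input is never modified.
    offsets:
        ``(green, blue)`` row shifts; each must satisfy ``0 <= off < rows``.
    fill:
        Per-channel background value for the vacated bottom rows.
    """
    is_frame = isinstance(frame, ScanFrame)
    pixels = frame.pixels if is_frame else np.asarray(frame)
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError("expected an RGB raster of shape (rows, cols, 3)")
    g_off, b_off = (int(o) for o in offsets)
    rows = pixels.shape[0]
    for name, off in (("green", g_off), ("blue", b_off)):
        if not 0 <= off < rows:
            raise ValueError(f"{name} offset {off} out of range [0, {rows})")

    out = pixels.copy()
    out[..., 1] = shift_plane(pixels[..., 1], g_off, fill[1])
    out[..., 2] = shift_plane(pixels[..., 2], b_off, fill[2])
    if is_frame:
        return ScanFrame(out, frame_index=frame.frame_index, task_id=frame.task_id)
    return out
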