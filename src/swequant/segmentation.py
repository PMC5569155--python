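"""Locating the elastogram inside a saved ultrasound screen capture.

On the device display the elasticity colour box is surrounded by a thin
white frame; detecting that frame is what makes fully automatic offline
evaluation possible.  Detection binarizes the capture at a whiteness
threshold, finds white components that enclose a large rectangular hole,
and returns the hole (the elastogram interior, frame pixels excluded).
When the capture shows the dual display (colour box above the plain B-mode
panel, each framed), the uppermost qualifying box wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["ScreenCapture", "FrameBox", "FrameNotFoundError", "detect_frame", "crop"]


class FrameNotFoundError(RuntimeError):
    """No white frame enclosing a large-enough rectangle was found."""


@dataclass
class ScreenCapture:
    """An 8-bit RGB screen capture plus whatever metadata came with it."""

    pixels: np.ndarray
    source_format: str = "PNG"
    pixel_spacing_mm: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError("capture must be at least 16x16")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if self.pixel_spacing_mm is not None and not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")


@dataclass
class FrameBox:
    """0-based, half-open bounds of the elastogram interior (frame excluded)."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom and 0 <= self.left < self.right):
            raise ValueError("FrameBox bounds must satisfy top<bottom, left<right")
        if (self.bottom - self.top) * (self.right - self.left) < 64:
            raise ValueError("FrameBox interior must cover at least 64 pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bottom - self.top, self.right - self.left)

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.top, self.bottom), slice(self.left, self.right))

    def to_dict(self) -> dict:
        return {"top": self.top, "left": self.left, "bottom": self.bottom, "right": self.right}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameBox":
        return cls(int(d["top"]), int(d["left"]), int(d["bottom"]), int(d["right"]))


def detect_frame(
    capture: ScreenCapture,
    whiteness_threshold: float = 0.85,
    min_area_fraction: float = 0.05,
    rectangularity: float = 0.95,
) -> FrameBox:
    """Find the interior of the white frame around the elastogram.

    A pixel is "white" when its darkest channel is at least
    ``whiteness_threshold`` (unit scale; the default 217/255 keeps thin
    frames intact under JPEG ringing while staying above B-mode speckle).  Each connected white component is tested for an enclosed
    hole of at least ``min_area_fraction`` of the image whose shape is
    rectangular (hole area >= ``rectangularity`` of its bounding box).
    Among qualifying components the one whose interior starts uppermost is
    returned.  Raises :class:`FrameNotFoundError` when nothing qualifies —
    the caller may then fall back to a manually supplied :class:`FrameBox`.
    """
    px = capture.pixels
    h, w = px.shape[:2]
    white = px.min(axis=2) >= whiteness_threshold * 255.0
    if not white.any():
        raise FrameNotFoundError("no white pixels at the given threshold")

    candidates = _frame_candidates(white, h, w, min_area_fraction, rectangularity)
    if not candidates:
        # lossy compression can nick single pixels out of a thin frame;
        # a 3x3 closing bridges hairline breaks without moving the interior
        closed = ndimage.binary_closing(white, structure=np.ones((3, 3), dtype=bool))
        candidates = _frame_candidates(closed, h, w, min_area_fraction, rectangularity)

    if not candidates:
        raise FrameNotFoundError(
            "no closed rectangular white frame of sufficient area found"
        )
    candidates.sort(key=lambda b: (b.top, b.left))
    return candidates[0]


def _frame_candidates(
    white: np.ndarray,
    h: int,
    w: int,
    min_area_fraction: float,
    rectangularity: float,
) -> list[FrameBox]:
    labels, n = ndimage.label(white, structure=np.ones((3, 3), dtype=int))
    min_area = min_area_fraction * h * w
    candidates: list[FrameBox] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        filled = ndimage.binary_fill_holes(comp)
        hole = filled & ~comp
        area = int(hole.sum())
        if area < max(min_area, 64):
            continue
        rows = np.flatnonzero(hole.any(axis=1))
        cols = np.flatnonzero(hole.any(axis=0))
        top, bottom = int(rows[0]), int(rows[-1]) + 1
        left, right = int(cols[0]), int(cols[-1]) + 1
        bbox_area = (bottom - top) * (right - left)
        if area < rectangularity * bbox_area:
            continue
        candidates.append(FrameBox(top, left, bottom, right))
    return candidates


def crop(capture: ScreenCapture, box: FrameBox) -> np.ndarray:
    """Return the interior pixels delimited by ``box`` as an (h, w, 3) array."""
    h, w = capture.pixels.shape[:2]
    if box.bottom > h or box.right > w:
        raise ValueError("FrameBox extends outside the capture")
    return capture.pixels[box.slices].copy()
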