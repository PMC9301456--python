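"""Axis-aligned bounding boxes.

Internal convention: 0-based, half-open pixel intervals ``[xmin, xmax) x
[ymin, ymax)``.  Pascal VOC files use 1-based inclusive coordinates; the
conversion happens only at the I/O boundary (:mod:`pestdet.voc`), so area
and IoU arithmetic never carries an off-by-one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["BoundingBox", "iou", "iou_xyxy", "size_aligned_iou"]


@dataclass(frozen=True)
class BoundingBox:
    """Integer pixel box, 0-based half-open."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError(f"degenerate box {self!r}")
        if self.xmin < 0 or self.ymin < 0:
            raise ValueError(f"negative coordinates in {self!r}")

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def clipped(self, width: int, height: int) -> "BoundingBox":
        """Clip to an image extent; raises if nothing remains."""
        return BoundingBox(
            max(self.xmin, 0),
            max(self.ymin, 0),
            min(self.xmax, width),
            min(self.ymax, height),
        )

    def inside(self, width: int, height: int) -> bool:
        return 0 <= self.xmin < self.xmax <= width and 0 <= self.ymin < self.ymax <= height

    def shifted(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.xmin + dx, self.ymin + dy, self.xmax + dx, self.ymax + dy)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)


def iou_xyxy(a: Sequence[float], b: Sequence[float]) -> float:
    """IoU of two ``(xmin, ymin, xmax, ymax)`` boxes (half-open/continuous)."""
    ix = min(a[2], b[2]) - max(a[0], b[0])
    iy = min(a[3], b[3]) - max(a[1], b[1])
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    return iou_xyxy(a.as_tuple(), b.as_tuple())


def size_aligned_iou(wh_a: Sequence[float], wh_b: Sequence[float]) -> float:
    """IoU of two boxes compared by size only (corners aligned at the origin).

    This is the distance kernel of YOLO-style anchor clustering: position is
    ignored, only the ``(w, h)`` pair matters.
    """
    inter = min(wh_a[0], wh_b[0]) * min(wh_a[1], wh_b[1])
    union = wh_a[0] * wh_a[1] + wh_b[0] * wh_b[1] - inter
    return inter / union
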