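"""Axis-aligned bounding boxes in pixel coordinates.

A box is anchored at its upper-left corner (image origin top-left, x
rightward, y downward) and occupies the half-open region
``[x, x+w) x [y, y+h)``.  All spatial annotation in the pipeline — citizen
rectangles, consensus regions, detector output, tracker output — uses this
one representation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError


@dataclass(frozen=True)
class BBox:
    """Axis-aligned rectangle: upper-left corner ``(x, y)``, size ``(w, h)``.

    Width and height must be strictly positive; degenerate rectangles are
    rejected because every downstream overlap computation divides by area.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(
                f"box width and height must be positive, got w={self.w}, h={self.h}"
            )

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    def intersection_area(self, other: "BBox") -> float:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes, in [0, 1].

    Symmetric; 1.0 for identical boxes, 0.0 for disjoint ones.  This is the
    overlap measure used pipeline-wide: detection-to-period linking, truth
    matching in the evaluation metrics, and tests of the tracker.
    """
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union
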