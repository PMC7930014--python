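"""Detector-side file formats: darknet label files, dataset splits, and
the raw-detection / observation-period tables.

Label lines follow the darknet convention — ``<class> <cx> <cy> <w> <h>``
with box center and size normalised to [0, 1] by the image dimensions —
written at a fixed six decimal places so outputs are byte-stable.

The observation-period CSV schema (FilenameInThisStudy, frame_no_start,
frame_no_end, max_conf, x, y, w, h) is the survey's published model-output
format and is honoured verbatim.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TypeVar, Union

import pandas as pd

from .boxes import BBox
from .errors import FormatError, ValidationError

PERIODS_HEADER = [
    "FilenameInThisStudy",
    "frame_no_start",
    "frame_no_end",
    "max_conf",
    "x",
    "y",
    "w",
    "h",
]

RAW_DETECTION_COLUMNS = [
    "movie_id",
    "frame_no",
    "x",
    "y",
    "w",
    "h",
    "confidence",
    "class_index",
]

T = TypeVar("T")


@dataclass(frozen=True)
class LabelLine:
    """One normalised darknet label: class index plus center/size in [0,1]."""

    class_index: int
    cx: float
    cy: float
    w: float
    h: float


@dataclass(frozen=True)
class RawDetection:
    """One raw detector output: a box with a confidence on one movie frame."""

    movie_id: str
    frame_no: int
    bbox: BBox
    confidence: float
    class_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence must be in [0,1], got {self.confidence}"
            )


@dataclass(frozen=True)
class ObservationPeriod:
    """A maximal run of consecutive frames over which one object was tracked.

    ``max_conf`` is the highest member confidence and ``best_bbox`` the box
    of that max-confidence member.
    """

    movie_id: str
    frame_no_start: int
    frame_no_end: int
    max_conf: float
    best_bbox: BBox

    def __post_init__(self) -> None:
        if self.frame_no_start > self.frame_no_end:
            raise ValidationError(
                f"frame_no_start {self.frame_no_start} > frame_no_end "
                f"{self.frame_no_end}"
            )


def write_labels(
    boxes: Iterable[tuple[int, BBox]], image_w: int, image_h: int
) -> str:
    """Render boxes as darknet label text for one image.

    One newline-terminated line per box; empty input yields the empty
    string.  Boxes must lie within the image.
    """
    lines = []
    for class_index, b in boxes:
        if b.x < 0 or b.y < 0 or b.x2 > image_w or b.y2 > image_h:
            raise ValidationError(
                f"box {b} outside {image_w}x{image_h} image"
            )
        cx = (b.x + b.w / 2.0) / image_w
        cy = (b.y + b.h / 2.0) / image_h
        lines.append(
            f"{class_index} {cx:.6f} {cy:.6f} {b.w / image_w:.6f} {b.h / image_h:.6f}\n"
        )
    return "".join(lines)


def read_labels(text: str) -> list[LabelLine]:
    """Parse darknet label text back into :class:`LabelLine` records."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise FormatError(f"label line {lineno}: expected 5 fields, got {len(parts)}")
        out.append(
            LabelLine(int(parts[0]), *(float(p) for p in parts[1:]))
        )
    return out


def denormalize(label: LabelLine, image_w: int, image_h: int) -> BBox:
    """Recover the pixel box a label line encodes."""
    w = label.w * image_w
    h = label.h * image_h
    return BBox(label.cx * image_w - w / 2.0, label.cy * image_h - h / 2.0, w, h)


def split_dataset(
    items: Sequence[T],
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> tuple[list[T], list[T], list[T]]:
    """Deterministic train/validation/test split by seeded shuffle.

    Part sizes follow largest-remainder apportionment of ``ratios`` (which
    must sum to 1), so they depend only on ``len(items)`` and the ratios;
    the assignment of items to parts depends only on the seed.
    """
    if not items:
        raise ValidationError("cannot split an empty item list")
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError(f"ratios must sum to 1, got {ratios}")
    n = len(items)
    floors = [int(math.floor(r * n)) for r in ratios]
    remainders = [r * n - f for r, f in zip(ratios, floors)]
    short = n - sum(floors)
    # ties in fractional remainder broken toward earlier parts (train first)
    order = sorted(range(3), key=lambda i: (-remainders[i], i))
    sizes = list(floors)
    for i in order[:short]:
        sizes[i] += 1
    idx = list(range(n))
    random.Random(seed).shuffle(idx)
    parts: list[list[T]] = []
    at = 0
    for s in sizes:
        parts.append([items[i] for i in idx[at : at + s]])
        at += s
    return parts[0], parts[1], parts[2]


def write_periods(
    periods: Iterable[ObservationPeriod], path: Union[str, Path]
) -> None:
    """Write observation periods in the published model-output CSV schema."""
    rows = [
        {
            "FilenameInThisStudy": p.movie_id,
            "frame_no_start": p.frame_no_start,
            "frame_no_end": p.frame_no_end,
            "max_conf": p.max_conf,
            "x": p.best_bbox.x,
            "y": p.best_bbox.y,
            "w": p.best_bbox.w,
            "h": p.best_bbox.h,
        }
        for p in periods
    ]
    pd.DataFrame(rows, columns=PERIODS_HEADER).to_csv(path, index=False)


def read_periods(path: Union[str, Path]) -> list[ObservationPeriod]:
    """Read an observation-period CSV, validating schema and frame ordering."""
    df = pd.read_csv(path)
    for col in PERIODS_HEADER:
        if col not in df.columns:
            raise FormatError(f"periods CSV missing required column '{col}'")
    out = []
    for i, r in enumerate(df.itertuples(), start=1):
        if r.frame_no_start > r.frame_no_end:
            raise ValidationError(
                f"row {i}: frame_no_start {r.frame_no_start} > "
                f"frame_no_end {r.frame_no_end}"
            )
        out.append(
            ObservationPeriod(
                movie_id=str(r.FilenameInThisStudy),
                frame_no_start=int(r.frame_no_start),
                frame_no_end=int(r.frame_no_end),
                max_conf=float(r.max_conf),
                best_bbox=BBox(float(r.x), float(r.y), float(r.w), float(r.h)),
            )
        )
    return out


def write_detections(
    detections: Iterable[RawDetection], path: Union[str, Path]
) -> None:
    """Write raw detections as CSV (movie_id,frame_no,x,y,w,h,confidence,class_index)."""
    rows = [
        {
            "movie_id": d.movie_id,
            "frame_no": d.frame_no,
            "x": d.bbox.x,
            "y": d.bbox.y,
            "w": d.bbox.w,
            "h": d.bbox.h,
            "confidence": d.confidence,
            "class_index": d.class_index,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=RAW_DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path: Union[str, Path]) -> list[RawDetection]:
    """Read a raw-detection CSV written by :func:`write_detections`."""
    df = pd.read_csv(path)
    for col in RAW_DETECTION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"detections CSV missing required column '{col}'")
    return [
        RawDetection(
            movie_id=str(r.movie_id),
            frame_no=int(r.frame_no),
            bbox=BBox(float(r.x), float(r.y), float(r.w), float(r.h)),
            confidence=float(r.confidence),
            class_index=int(r.class_index),
        )
        for r in df.itertuples()
    ]
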