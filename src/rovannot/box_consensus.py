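"""Multi-annotator consensus over rectangles drawn on still frames.

Several citizen scientists each draw zero or more rectangles around the
individuals they see in a frame.  The consensus is the region of the frame
covered by rectangles from at least ``k`` *distinct* annotators, where
``k = min_support(n_annotators, threshold)`` and annotators who drew
nothing still count in the denominator (a "no individuals" answer is an
annotation).  Each 4-connected component of that region yields one
consensus box: the component's axis-aligned bounding box, with support
equal to the maximum distinct-annotator depth inside it.

This depth-thresholding formalisation reduces to the plain intersection of
rectangles when every annotator draws a single box, and extends naturally
to frames containing several individuals.

Two routes compute it:

* :func:`consensus_regions` — exact coordinate-compressed 2-D sweep; works
  for real-valued coordinates and any canvas size.
* :func:`consensus_oracle` — brute-force per-pixel counting on an explicit
  integer grid, limited to small canvases; exists purely as an independent
  cross-check of the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boxes import BBox
from .clip_consensus import min_support
from .errors import ValidationError

ORACLE_MAX_CANVAS = 512


@dataclass(frozen=True)
class FrameAnnotation:
    """All rectangles one annotator drew on one frame (possibly none)."""

    subject_id: str
    annotator_id: str
    boxes: tuple[BBox, ...] = ()


@dataclass(frozen=True)
class ConsensusBox:
    """Bounding box of one connected component of the consensus region."""

    subject_id: str
    bbox: BBox
    support: int
    n_annotators: int


def _check_single_subject(annotations: list[FrameAnnotation]) -> str:
    if not annotations:
        raise ValidationError("consensus requires at least one frame annotation")
    subjects = {a.subject_id for a in annotations}
    if len(subjects) != 1:
        raise ValidationError(f"annotations mix subjects: {sorted(subjects)}")
    return annotations[0].subject_id


def consensus_regions(
    annotations: list[FrameAnnotation], threshold: float = 0.8
) -> list[ConsensusBox]:
    """Consensus boxes for one frame by exact coordinate-compressed sweep.

    The x- and y-edges of all rectangles partition the plane into a grid of
    cells on which every rectangle is constant; per cell we count distinct
    annotators covering it (an annotator covering a cell with several of
    their own boxes counts once), threshold at ``k``, and label 4-connected
    components.  Exact for integer and real coordinates alike.  Output is
    sorted by (y, x) of the component bounding box.
    """
    subject_id = _check_single_subject(annotations)
    n_annotators = len(annotations)
    k = min_support(n_annotators, threshold)

    all_boxes = [b for a in annotations for b in a.boxes]
    if not all_boxes:
        return []
    xs = np.array(sorted({e for b in all_boxes for e in (b.x, b.x2)}))
    ys = np.array(sorted({e for b in all_boxes for e in (b.y, b.y2)}))
    ncx, ncy = len(xs) - 1, len(ys) - 1
    if ncx == 0 or ncy == 0:  # cannot happen with positive-size boxes
        return []

    depth = np.zeros((ncy, ncx), dtype=np.int32)
    for ann in annotations:
        if not ann.boxes:
            continue
        mask = np.zeros((ncy, ncx), dtype=bool)
        for b in ann.boxes:
            x0 = int(np.searchsorted(xs, b.x))
            x1 = int(np.searchsorted(xs, b.x2))
            y0 = int(np.searchsorted(ys, b.y))
            y1 = int(np.searchsorted(ys, b.y2))
            mask[y0:y1, x0:x1] = True
        depth += mask

    region = depth >= k
    if not region.any():
        return []
    labels, n_comp = ndimage.label(region)  # default structure = 4-connectivity
    out: list[ConsensusBox] = []
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == comp)
        x = float(xs[cols.min()])
        y = float(ys[rows.min()])
        w = float(xs[cols.max() + 1]) - x
        h = float(ys[rows.max() + 1]) - y
        support = int(depth[rows, cols].max())
        out.append(ConsensusBox(subject_id, BBox(x, y, w, h), support, n_annotators))
    out.sort(key=lambda c: (c.bbox.y, c.bbox.x))
    return out


def consensus_oracle(
    annotations: list[FrameAnnotation],
    threshold: float,
    canvas_w: int,
    canvas_h: int,
) -> list[ConsensusBox]:
    """Brute-force consensus by per-pixel counting on an explicit grid.

    Requires integer box coordinates inside a canvas of at most 512x512.
    Semantics match :func:`consensus_regions` by construction; kept as the
    independent reference implementation for testing the sweep.
    """
    if canvas_w > ORACLE_MAX_CANVAS or canvas_h > ORACLE_MAX_CANVAS:
        raise ValidationError(
            f"oracle canvas limited to {ORACLE_MAX_CANVAS}px, got {canvas_w}x{canvas_h}"
        )
    subject_id = _check_single_subject(annotations)
    n_annotators = len(annotations)
    k = min_support(n_annotators, threshold)

    depth = np.zeros((canvas_h, canvas_w), dtype=np.int32)
    for ann in annotations:
        mask = np.zeros((canvas_h, canvas_w), dtype=bool)
        for b in ann.boxes:
            coords = (b.x, b.y, b.w, b.h)
            if any(c != int(c) for c in coords):
                raise ValidationError(f"oracle requires integer coordinates: {b}")
            if b.x < 0 or b.y < 0 or b.x2 > canvas_w or b.y2 > canvas_h:
                raise ValidationError(f"box outside canvas: {b}")
            mask[int(b.y) : int(b.y2), int(b.x) : int(b.x2)] = True
        depth += mask

    region = depth >= k
    if not region.any():
        return []
    labels, n_comp = ndimage.label(region)
    out: list[ConsensusBox] = []
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labels == comp)
        x, y = float(cols.min()), float(rows.min())
        w = float(cols.max() + 1) - x
        h = float(rows.max() + 1) - y
        support = int(depth[rows, cols].max())
        out.append(ConsensusBox(subject_id, BBox(x, y, w, h), support, n_annotators))
    out.sort(key=lambda c: (c.bbox.y, c.bbox.x))
    return out
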