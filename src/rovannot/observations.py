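"""Aggregation of frame-level detections into observation periods, and
presence/absence classification of survey grid squares.

A detector emits an independent box+confidence per frame.  Ecologically we
want *observation periods*: maximal runs of consecutive frames over which
the same object was continuously seen.  Detections below the confidence
threshold are discarded; a surviving detection at frame ``f+1`` extends a
period that ended at frame ``f`` when the IoU of its box with the period's
last box strictly exceeds the link threshold (default 0.5, i.e. ">50%
overlap").  When several detections and several live periods are eligible,
pairs are matched greedily in descending IoU; each detection joins at most
one period and unmatched detections open new periods.

Grid squares are then labelled Coral / NoCoral by whether any observation
period intersects the footage span surveyed in the square (closed frame
intervals, same movie).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .boxes import BBox, iou
from .errors import ValidationError
from .yolo import ObservationPeriod, RawDetection

logger = logging.getLogger(__name__)

CORAL = "Coral"
NO_CORAL = "NoCoral"


@dataclass(frozen=True)
class SquareFootageMap:
    """Footage span (closed frame interval of one movie) surveyed in one grid square."""

    square_id: str
    movie_id: str
    frame_no_start: int
    frame_no_end: int

    def __post_init__(self) -> None:
        if self.frame_no_start > self.frame_no_end:
            raise ValidationError(
                f"square {self.square_id}: start frame after end frame"
            )


class _LivePeriod:
    __slots__ = ("movie_id", "start", "last_frame", "last_box", "best_conf", "best_box")

    def __init__(self, det: RawDetection) -> None:
        self.movie_id = det.movie_id
        self.start = det.frame_no
        self.last_frame = det.frame_no
        self.last_box = det.bbox
        self.best_conf = det.confidence
        self.best_box = det.bbox

    def extend(self, det: RawDetection) -> None:
        self.last_frame = det.frame_no
        self.last_box = det.bbox
        if det.confidence > self.best_conf:
            self.best_conf = det.confidence
            self.best_box = det.bbox

    def close(self) -> ObservationPeriod:
        return ObservationPeriod(
            movie_id=self.movie_id,
            frame_no_start=self.start,
            frame_no_end=self.last_frame,
            max_conf=self.best_conf,
            best_bbox=self.best_box,
        )


def aggregate_detections(
    detections: Iterable[RawDetection],
    conf_threshold: float,
    link_iou: float = 0.5,
    gap: int = 0,
) -> list[ObservationPeriod]:
    """Link thresholded per-frame detections into observation periods.

    ``gap`` is the number of missing frames tolerated between consecutive
    members; the default 0 demands strictly consecutive frames
    ("continuously observed").  Output is ordered by
    (movie_id, frame_no_start, frame_no_end).
    """
    dets = sorted(detections, key=lambda d: (d.movie_id, d.frame_no))
    kept = [d for d in dets if d.confidence >= conf_threshold]
    periods: list[ObservationPeriod] = []

    by_movie: dict[str, list[RawDetection]] = {}
    for d in kept:
        by_movie.setdefault(d.movie_id, []).append(d)

    for movie_id in sorted(by_movie):
        live: list[_LivePeriod] = []
        frames: dict[int, list[RawDetection]] = {}
        for d in by_movie[movie_id]:
            frames.setdefault(d.frame_no, []).append(d)
        for f in sorted(frames):
            frame_dets = frames[f]
            still_live = [p for p in live if f - p.last_frame <= gap + 1]
            for p in live:
                if p not in still_live:
                    periods.append(p.close())
            # greedy descending-IoU matching between live periods and detections
            pairs = []
            for pi, p in enumerate(still_live):
                for di, d in enumerate(frame_dets):
                    v = iou(p.last_box, d.bbox)
                    if v > link_iou:
                        pairs.append((v, pi, di))
            pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
            used_p: set[int] = set()
            used_d: set[int] = set()
            for v, pi, di in pairs:
                if pi in used_p or di in used_d:
                    continue
                still_live[pi].extend(frame_dets[di])
                used_p.add(pi)
                used_d.add(di)
            for di, d in enumerate(frame_dets):
                if di not in used_d:
                    still_live.append(_LivePeriod(d))
            live = still_live
        periods.extend(p.close() for p in live)

    periods.sort(key=lambda p: (p.movie_id, p.frame_no_start, p.frame_no_end))
    return periods


def classify_squares(
    periods: Sequence[ObservationPeriod],
    footage_map: Sequence[SquareFootageMap],
) -> dict[str, str]:
    """Label every grid square Coral / NoCoral by observation-period presence.

    A square is Coral iff at least one period lies in the same movie and its
    closed frame interval intersects the square's footage span.  Periods
    whose movie appears nowhere in the map are ignored with a logged count.
    """
    mapped_movies = {m.movie_id for m in footage_map}
    ignored = sum(1 for p in periods if p.movie_id not in mapped_movies)
    if ignored:
        logger.warning(
            "%d observation period(s) reference movies absent from the "
            "square footage map and were ignored", ignored,
        )
    labels: dict[str, str] = {}
    for sq in footage_map:
        hit = any(
            p.movie_id == sq.movie_id
            and p.frame_no_start <= sq.frame_no_end
            and sq.frame_no_start <= p.frame_no_end
            for p in periods
        )
        labels[sq.square_id] = CORAL if hit else NO_CORAL
    return labels


def segment_oracle(
    detections: Sequence[RawDetection],
    conf_threshold: float,
    link_iou: float = 0.5,
) -> list[ObservationPeriod]:
    """Brute-force reference for :func:`aggregate_detections`.

    Valid only for instances with at most one detection per (movie, frame):
    after thresholding, the detection sequence of each movie is split
    exactly where the frame gap exceeds 1 or the IoU of successive boxes
    fails to exceed ``link_iou``.
    """
    kept = sorted(
        (d for d in detections if d.confidence >= conf_threshold),
        key=lambda d: (d.movie_id, d.frame_no),
    )
    seen = set()
    for d in kept:
        key = (d.movie_id, d.frame_no)
        if key in seen:
            raise ValidationError("oracle requires at most one detection per frame")
        seen.add(key)

    periods: list[ObservationPeriod] = []
    run: list[RawDetection] = []

    def flush() -> None:
        if not run:
            return
        best = max(run, key=lambda d: d.confidence)
        periods.append(
            ObservationPeriod(
                movie_id=run[0].movie_id,
                frame_no_start=run[0].frame_no,
                frame_no_end=run[-1].frame_no,
                max_conf=best.confidence,
                best_bbox=best.bbox,
            )
        )
        run.clear()

    for d in kept:
        if run and (
            d.movie_id != run[-1].movie_id
            or d.frame_no != run[-1].frame_no + 1
            or iou(run[-1].bbox, d.bbox) <= link_iou
        ):
            flush()
        run.append(d)
    flush()
    periods.sort(key=lambda p: (p.movie_id, p.frame_no_start, p.frame_no_end))
    return periods
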