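"""Aggregation of per-clip species choices from multiple annotators.

Each clip is classified independently by several citizen scientists, who
select one or more choices (taxa, or options such as "Nothing here") and,
for taxa, report how many individuals they saw and when one first appears
fully.  A choice is retained for a clip when the fraction of distinct
annotators selecting it reaches the agreement threshold (default 80%): with
8 annotators and a 0.8 threshold that means at least 7 of the 8 must agree.

The agreement denominator is always the number of distinct annotators who
annotated *that clip*, never a global constant, so clips with unusual
annotator counts are handled consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError

DEFAULT_AGREEMENT_THRESHOLD = 0.8


@dataclass(frozen=True)
class ClipAnnotation:
    """One annotator's answer for one clip subject.

    ``individual_count`` and ``first_seen_s`` are present only for taxon
    choices (annotators are not asked them for "Nothing here"-type options).
    """

    subject_id: str
    annotator_id: str
    choice_id: str
    individual_count: Optional[int] = None
    first_seen_s: Optional[float] = None


@dataclass(frozen=True)
class RetainedChoice:
    """A choice that met the agreement threshold on one clip."""

    subject_id: str
    choice_id: str
    n_support: int
    n_annotators: int
    mean_first_seen_s: Optional[float] = None
    consensus_count: Optional[int] = None


def min_support(n_annotators: int, threshold: float) -> int:
    """Smallest number of annotators whose agreement reaches the threshold.

    Returns the smallest integer ``k`` with ``k / n_annotators >= threshold``
    — e.g. 7 for 8 annotators at an 80% threshold.  Computed by ceiling with
    an explicit fix-up so float rounding in ``threshold * n`` can never move
    the answer off the exact definition.
    """
    if n_annotators < 1:
        raise ValidationError(f"n_annotators must be >= 1, got {n_annotators}")
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    k = int(math.ceil(threshold * n_annotators))
    while k > 1 and (k - 1) / n_annotators >= threshold:
        k -= 1
    while k / n_annotators < threshold:
        k += 1
    return k


def _lower_median(values: list[int]) -> int:
    """Median with even-length ties resolved to the lower middle value."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def aggregate_clip(
    annotations: Iterable[ClipAnnotation],
    threshold: float = DEFAULT_AGREEMENT_THRESHOLD,
) -> list[RetainedChoice]:
    """Retain the choices on one clip that meet the agreement threshold.

    For each retained choice the supporters' first-seen times are averaged
    (arithmetic mean) and their individual counts are summarised by the
    lower median.  Output is sorted by descending support, then choice_id,
    so results are deterministic and diff-stable.
    """
    anns = list(annotations)
    if not anns:
        raise ValidationError("aggregate_clip requires at least one annotation")
    subject_ids = {a.subject_id for a in anns}
    if len(subject_ids) != 1:
        raise ValidationError(
            f"annotations mix subjects: {sorted(subject_ids)}"
        )
    subject_id = anns[0].subject_id
    annotators = {a.annotator_id for a in anns}
    n_annotators = len(annotators)
    k = min_support(n_annotators, threshold)

    # One vote per (annotator, choice): duplicates from the same annotator
    # count once, but the first-seen / count answers of the first record win.
    by_choice: dict[str, dict[str, ClipAnnotation]] = {}
    for a in anns:
        by_choice.setdefault(a.choice_id, {}).setdefault(a.annotator_id, a)

    retained: list[RetainedChoice] = []
    for choice_id, votes in by_choice.items():
        support = len(votes)
        if support < k:
            continue
        times = [a.first_seen_s for a in votes.values() if a.first_seen_s is not None]
        counts = [
            a.individual_count for a in votes.values() if a.individual_count is not None
        ]
        retained.append(
            RetainedChoice(
                subject_id=subject_id,
                choice_id=choice_id,
                n_support=support,
                n_annotators=n_annotators,
                mean_first_seen_s=(sum(times) / len(times)) if times else None,
                consensus_count=_lower_median(counts) if counts else None,
            )
        )
    retained.sort(key=lambda r: (-r.n_support, r.choice_id))
    return retained


def aggregate_all(
    annotations: pd.DataFrame,
    threshold: float = DEFAULT_AGREEMENT_THRESHOLD,
) -> pd.DataFrame:
    """Batch driver: aggregate every subject in a raw clip-annotation table.

    ``annotations`` columns: subject_id, annotator_id, choice_id,
    individual_count, first_seen_s (the last two may be NaN).  Returns one
    row per retained choice; subjects on which nothing met the threshold
    appear once with a null choice_id so that no subject silently vanishes.
    """
    cols = [
        "subject_id",
        "choice_id",
        "n_support",
        "n_annotators",
        "mean_first_seen_s",
        "consensus_count",
    ]
    if annotations.empty:
        return pd.DataFrame(columns=cols)
    rows: list[dict] = []
    for subject_id, group in annotations.groupby("subject_id", sort=True):
        anns = [
            ClipAnnotation(
                subject_id=str(r.subject_id),
                annotator_id=str(r.annotator_id),
                choice_id=str(r.choice_id),
                individual_count=(
                    None if pd.isna(r.individual_count) else int(r.individual_count)
                ),
                first_seen_s=(
                    None if pd.isna(r.first_seen_s) else float(r.first_seen_s)
                ),
            )
            for r in group.itertuples()
        ]
        results = aggregate_clip(anns, threshold)
        if not results:
            rows.append(
                {
                    "subject_id": subject_id,
                    "choice_id": None,
                    "n_support": 0,
                    "n_annotators": len({a.annotator_id for a in anns}),
                    "mean_first_seen_s": None,
                    "consensus_count": None,
                }
            )
        for r in results:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "choice_id": r.choice_id,
                    "n_support": r.n_support,
                    "n_annotators": r.n_annotators,
                    "mean_first_seen_s": r.mean_first_seen_s,
                    "consensus_count": r.consensus_count,
                }
            )
    return pd.DataFrame(rows, columns=cols)
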