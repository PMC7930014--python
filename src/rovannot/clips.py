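"""Clip and frame planning for long survey movies.

Hour-plus ROV movies are split into fixed-length clips (default 10 s) for
the species-identification workflow; for clips in which a species was
confirmed, up to three still frames are sampled at one-second spacing
starting from the moment the species first fully appears.

Conventions fixed here and relied on everywhere downstream:

* clips are contiguous from t=0 and a trailing partial clip is dropped;
* frames are indexed 0-based, frame ``k`` covers time ``[k/fps, (k+1)/fps)``,
  so a timestamp maps to a frame index by ``floor(t * fps)``.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .errors import ValidationError

DEFAULT_CLIP_LEN_S = 10.0
DEFAULT_MAX_FRAMES = 3


@dataclass(frozen=True)
class ClipPlan:
    """One planned clip: ``[start_s, end_s)`` within its movie."""

    movie_id: str
    clip_index: int
    start_s: float
    end_s: float

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FramePlan:
    """Frames sampled from one clip, as clip-relative times and movie frame indices."""

    subject_id: str
    frame_times_s: tuple[float, ...]
    frame_nos: tuple[int, ...]


def plan_clips(
    movie_id: str, duration_s: float, clip_len_s: float = DEFAULT_CLIP_LEN_S
) -> list[ClipPlan]:
    """Split a movie of ``duration_s`` seconds into consecutive fixed-length clips.

    Returns ``floor(duration / clip_len)`` clips covering ``[0, n*clip_len)``;
    the trailing remainder shorter than one clip is dropped rather than
    padded, so every annotation subject has identical length.
    """
    if duration_s < 0:
        raise ValidationError(f"duration_s must be non-negative, got {duration_s}")
    if clip_len_s <= 0:
        raise ValidationError(f"clip_len_s must be positive, got {clip_len_s}")
    n = int(math.floor(duration_s / clip_len_s + 1e-9))
    return [
        ClipPlan(movie_id, i, i * clip_len_s, (i + 1) * clip_len_s) for i in range(n)
    ]


def sample_clips(clips: list[ClipPlan], n: int, seed: int) -> list[ClipPlan]:
    """Uniform sample of ``n`` clips without replacement, reproducible by seed.

    The returned list preserves the original (movie_id, clip_index) ordering
    so the selection is a stable sub-list of the input.
    """
    if n < 0 or n > len(clips):
        raise ValidationError(
            f"cannot sample {n} clips from {len(clips)} available"
        )
    rng = random.Random(seed)
    chosen = sorted(rng.sample(range(len(clips)), n))
    return [clips[i] for i in chosen]


def plan_frames(
    clip: ClipPlan,
    first_seen_s: float,
    fps: float,
    max_frames: int = DEFAULT_MAX_FRAMES,
) -> FramePlan:
    """Plan still frames at 1-second spacing from the first full appearance.

    ``first_seen_s`` is clip-relative (the consensus answer to "when does the
    species first appear fully?").  Times run ``first_seen, +1 s, +2 s, ...``
    and stop at whichever comes first of ``max_frames`` frames or the clip
    end.  Movie frame indices follow the floor convention
    ``floor((clip.start_s + t) * fps)``.
    """
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    clip_len = clip.length_s
    if not (0 <= first_seen_s < clip_len):
        raise ValidationError(
            f"first_seen_s={first_seen_s} outside clip of length {clip_len}"
        )
    times: list[float] = []
    t = first_seen_s
    while len(times) < max_frames and t < clip_len:
        times.append(t)
        t += 1.0
    frame_nos = [int(math.floor((clip.start_s + t) * fps + 1e-9)) for t in times]
    subject_id = f"{clip.movie_id}_c{clip.clip_index}"
    return FramePlan(subject_id, tuple(times), tuple(frame_nos))
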