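"""Synthetic data generators emulating every upstream source of the pipeline.

The real pipeline consumes ROV footage, citizen-scientist answers from a
crowdsourcing platform, and raw detector output — none of which are
available at desk scale.  This module builds a *known-truth* miniature
study instead: moving-object tracks in a virtual movie (:class:`TrueScene`),
per-annotator clip choices with stated sensitivity/specificity, rectangle
annotations with corner jitter and misses, detector streams with noisy
confidences and spurious boxes, and rendered textured frames for the
tracker.  Every generator is a pure function of its parameters and seed, so
any downstream result can be compared against the exact ground truth.

In the noiseless limits (sensitivity = specificity = 1, zero jitter, zero
miss and false-positive rates) each generator reproduces the truth exactly,
which gives the pipeline an end-to-end identity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .boxes import BBox
from .box_consensus import FrameAnnotation
from .clip_consensus import ClipAnnotation
from .clips import ClipPlan, plan_clips, plan_frames
from .errors import ValidationError
from .tracker import FrameImage
from .yolo import RawDetection

TAXON_CHOICE = "coral"
NOTHING_CHOICE = "nothing_here"


@dataclass(frozen=True)
class AnnotatorProfile:
    """Behavioural model of one citizen scientist.

    ``sensitivity`` is the probability of selecting the true taxon on a clip
    where it is present; ``specificity`` the probability of *not* selecting
    it where absent.  Rectangle behaviour is Gaussian jitter (sd in pixels)
    independently on each corner, with ``box_miss_prob`` of not drawing a
    rectangle for a visible individual.
    """

    annotator_id: str
    sensitivity: float = 0.9
    specificity: float = 0.9
    first_seen_noise_sd: float = 0.5
    count_noise: int = 1
    box_jitter_sd: float = 2.0
    box_miss_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "box_miss_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.first_seen_noise_sd < 0 or self.box_jitter_sd < 0 or self.count_noise < 0:
            raise ValidationError("noise parameters must be non-negative")


def default_profiles(
    n: int, sensitivity: float = 0.9, specificity: float = 0.9, **kwargs
) -> list[AnnotatorProfile]:
    return [
        AnnotatorProfile(f"ann{i:02d}", sensitivity, specificity, **kwargs)
        for i in range(n)
    ]


@dataclass(frozen=True)
class Track:
    """One object's box per frame over a consecutive frame interval."""

    object_id: str
    boxes: dict[int, BBox]

    @property
    def start_frame(self) -> int:
        return min(self.boxes)

    @property
    def end_frame(self) -> int:
        return max(self.boxes)

    def __post_init__(self) -> None:
        frames = sorted(self.boxes)
        if frames != list(range(frames[0], frames[-1] + 1)):
            raise ValidationError("track frames must be consecutive")


@dataclass(frozen=True)
class TrueScene:
    """Ground truth for one virtual movie: canvas, timing, and object tracks."""

    movie_id: str
    fps: float
    duration_s: float
    canvas_w: int
    canvas_h: int
    tracks: tuple[Track, ...] = ()

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_s * self.fps))

    def boxes_at(self, frame_no: int) -> list[BBox]:
        return [t.boxes[frame_no] for t in self.tracks if frame_no in t.boxes]

    def presence_intervals(self) -> list[tuple[str, int, int]]:
        """(object_id, first_frame, last_frame) per track, sorted by start."""
        out = [(t.object_id, t.start_frame, t.end_frame) for t in self.tracks]
        out.sort(key=lambda x: (x[1], x[2], x[0]))
        return out


@dataclass(frozen=True)
class ClipTruth:
    """Ground-truth answer for one clip subject derived from the tracks."""

    subject_id: str
    clip: ClipPlan
    present: bool
    first_seen_s: Optional[float]  # clip-relative, None when absent
    count: int


def clip_subject_id(clip: ClipPlan) -> str:
    return f"{clip.movie_id}_c{clip.clip_index}"


def frame_subject_id(movie_id: str, frame_no: int) -> str:
    return f"{movie_id}_f{frame_no}"


def clip_truths(scene: TrueScene, clip_len_s: float = 10.0) -> list[ClipTruth]:
    """Derive per-clip presence, first-appearance time and count from tracks."""
    out = []
    for clip in plan_clips(scene.movie_id, scene.duration_s, clip_len_s):
        f0 = int(math.floor(clip.start_s * scene.fps + 1e-9))
        f1 = int(math.floor(clip.end_s * scene.fps + 1e-9))  # exclusive
        present_tracks = [
            t for t in scene.tracks
            if t.start_frame < f1 and t.end_frame >= f0
        ]
        if present_tracks:
            first_frame = min(max(t.start_frame, f0) for t in present_tracks)
            first_seen = first_frame / scene.fps - clip.start_s
            out.append(
                ClipTruth(
                    clip_subject_id(clip), clip, True, first_seen, len(present_tracks)
                )
            )
        else:
            out.append(ClipTruth(clip_subject_id(clip), clip, False, None, 0))
    return out


def make_scene(
    movie_id: str,
    seed: int,
    n_tracks: int = 6,
    fps: float = 25.0,
    duration_s: float = 400.0,
    canvas_w: int = 480,
    canvas_h: int = 270,
    track_len_frames: tuple[int, int] = (50, 250),
    box_size: tuple[int, int] = (40, 80),
    max_speed: float = 1.0,
) -> TrueScene:
    """Generate a random scene of slowly drifting objects.

    Object boxes drift at most ``max_speed`` px/frame per axis (slow enough
    that consecutive-frame IoU stays well above the 0.5 link threshold) and
    reflect off the canvas edges.  Tracks start at least one clip apart in
    time from nothing — their start frames are uniform over the movie.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(math.floor(duration_s * fps))
    tracks = []
    for i in range(n_tracks):
        w = int(rng.integers(box_size[0], box_size[1] + 1))
        h = int(rng.integers(box_size[0], box_size[1] + 1))
        length = int(rng.integers(track_len_frames[0], track_len_frames[1] + 1))
        start = int(rng.integers(0, max(1, n_frames - length)))
        x = float(rng.uniform(0, canvas_w - w))
        y = float(rng.uniform(0, canvas_h - h))
        vx = float(rng.uniform(-max_speed, max_speed))
        vy = float(rng.uniform(-max_speed, max_speed))
        boxes: dict[int, BBox] = {}
        for f in range(start, min(start + length, n_frames)):
            boxes[f] = BBox(round(x, 2), round(y, 2), w, h)
            x += vx
            y += vy
            if x < 0 or x + w > canvas_w:
                vx = -vx
                x = min(max(x, 0.0), canvas_w - w)
            if y < 0 or y + h > canvas_h:
                vy = -vy
                y = min(max(y, 0.0), canvas_h - h)
        tracks.append(Track(f"{movie_id}_obj{i}", boxes))
    return TrueScene(movie_id, fps, duration_s, canvas_w, canvas_h, tuple(tracks))


def simulate_clip_annotations(
    scene: TrueScene,
    profiles: Sequence[AnnotatorProfile],
    seed: int,
    clip_len_s: float = 10.0,
    taxon: str = TAXON_CHOICE,
) -> list[ClipAnnotation]:
    """Simulate the species-identification workflow on every clip of a scene.

    On clips where the taxon is present each annotator selects it with
    probability ``sensitivity`` (reporting a noisy first-seen time and
    count); on absent clips they select it with probability
    ``1 - specificity`` (a false positive with a uniform first-seen time),
    otherwise they answer "nothing here".
    """
    if not profiles:
        raise ValidationError("at least one annotator profile required")
    rng = np.random.default_rng(seed)
    out: list[ClipAnnotation] = []
    for truth in clip_truths(scene, clip_len_s):
        clip_len = truth.clip.length_s
        for prof in profiles:
            u = rng.random()
            says_taxon = (
                u < prof.sensitivity if truth.present else u < 1 - prof.specificity
            )
            if not says_taxon:
                out.append(
                    ClipAnnotation(truth.subject_id, prof.annotator_id, NOTHING_CHOICE)
                )
                continue
            if truth.present:
                t = truth.first_seen_s + rng.normal(0, prof.first_seen_noise_sd)
                t = float(min(max(t, 0.0), clip_len - 1e-6))
                count = int(truth.count + rng.integers(-prof.count_noise,
                                                       prof.count_noise + 1))
                count = max(1, count)
            else:
                t = float(rng.uniform(0, clip_len))
                count = 1
            out.append(
                ClipAnnotation(truth.subject_id, prof.annotator_id, taxon, count, t)
            )
    return out


def planned_frames(
    scene: TrueScene, clip_len_s: float = 10.0, max_frames: int = 3
) -> list[int]:
    """Movie frame numbers the frame workflow would sample, from true first appearances."""
    frames: set[int] = set()
    for truth in clip_truths(scene, clip_len_s):
        if not truth.present:
            continue
        plan = plan_frames(truth.clip, truth.first_seen_s, scene.fps, max_frames)
        frames.update(plan.frame_nos)
    return sorted(frames)


def simulate_frame_annotations(
    scene: TrueScene,
    profiles: Sequence[AnnotatorProfile],
    seed: int,
    frame_nos: Optional[Sequence[int]] = None,
) -> list[FrameAnnotation]:
    """Simulate rectangle drawing on sampled frames.

    Every annotator annotates every frame: for each true box they either
    miss it (``box_miss_prob``) or draw it with independent Gaussian jitter
    on each corner.  Jittered boxes are clamped to keep at least 1 px of
    width and height.
    """
    if not profiles:
        raise ValidationError("at least one annotator profile required")
    rng = np.random.default_rng(seed)
    if frame_nos is None:
        frame_nos = planned_frames(scene)
    out: list[FrameAnnotation] = []
    for frame_no in frame_nos:
        true_boxes = scene.boxes_at(frame_no)
        subject = frame_subject_id(scene.movie_id, frame_no)
        for prof in profiles:
            drawn: list[BBox] = []
            for b in true_boxes:
                if rng.random() < prof.box_miss_prob:
                    continue
                j = rng.normal(0, prof.box_jitter_sd, size=4) if prof.box_jitter_sd else np.zeros(4)
                x1, y1 = b.x + j[0], b.y + j[1]
                x2, y2 = b.x2 + j[2], b.y2 + j[3]
                if x2 <= x1:
                    x2 = x1 + 1.0
                if y2 <= y1:
                    y2 = y1 + 1.0
                drawn.append(BBox(x1, y1, x2 - x1, y2 - y1))
            out.append(FrameAnnotation(subject, prof.annotator_id, tuple(drawn)))
    return out


def simulate_detections(
    scene: TrueScene,
    conf_mean_present: float = 0.8,
    conf_sd: float = 0.1,
    false_pos_rate: float = 0.0,
    seed: int = 0,
) -> list[RawDetection]:
    """Emulate raw detector output along the scene's tracks.

    Each present track-frame yields one detection at the true box with
    confidence drawn from a Gaussian clamped to [0.01, 0.99] (so threshold
    sweeps never degenerate); independently, each movie frame spawns a
    spurious random box with probability ``false_pos_rate`` and uniform
    confidence.
    """
    rng = np.random.default_rng(seed)
    out: list[RawDetection] = []
    for track in scene.tracks:
        for f in range(track.start_frame, track.end_frame + 1):
            conf = (
                conf_mean_present
                if conf_sd == 0
                else float(rng.normal(conf_mean_present, conf_sd))
            )
            conf = float(min(max(conf, 0.01), 0.99))
            out.append(RawDetection(scene.movie_id, f, track.boxes[f], conf))
    if false_pos_rate > 0:
        for f in range(scene.n_frames):
            if rng.random() < false_pos_rate:
                w = float(rng.uniform(20, 60))
                h = float(rng.uniform(20, 60))
                x = float(rng.uniform(0, scene.canvas_w - w))
                y = float(rng.uniform(0, scene.canvas_h - h))
                conf = float(rng.uniform(0.01, 0.99))
                out.append(RawDetection(scene.movie_id, f, BBox(x, y, w, h), conf))
    out.sort(key=lambda d: (d.movie_id, d.frame_no, -d.confidence))
    return out


def false_positive_rates(
    n_clips: int = 500,
    n_annotators: int = 8,
    sensitivity: float = 0.9,
    specificity: float = 0.9,
    threshold: float = 0.8,
    seed: int = 0,
) -> tuple[float, float]:
    """Compare single-annotator vs. aggregated false-positive rates.

    Simulates ``n_clips`` clips on which the taxon is absent; returns
    ``(individual_rate, aggregated_rate)`` where the individual rate is the
    fraction of annotator answers that falsely select the taxon and the
    aggregated rate is the fraction of clips on which the consensus retains
    it at the given agreement threshold.  Demonstrates why aggregation at a
    high threshold suppresses the false positives single annotators make.
    """
    from .clip_consensus import aggregate_clip  # local to avoid cycle at import

    scene = TrueScene("fp_experiment", 25.0, n_clips * 10.0, 480, 270, ())
    profiles = default_profiles(n_annotators, sensitivity, specificity)
    anns = simulate_clip_annotations(scene, profiles, seed)
    individual = sum(a.choice_id == TAXON_CHOICE for a in anns) / len(anns)
    by_subject: dict[str, list[ClipAnnotation]] = {}
    for a in anns:
        by_subject.setdefault(a.subject_id, []).append(a)
    n_fp_clips = sum(
        any(r.choice_id == TAXON_CHOICE for r in aggregate_clip(group, threshold))
        for group in by_subject.values()
    )
    return individual, n_fp_clips / len(by_subject)


def render_frames(
    scene: TrueScene,
    color_cast: tuple[float, float, float] = (1.0, 1.0, 1.0),
    texture_seed: int = 0,
    frame_nos: Optional[Sequence[int]] = None,
) -> list[FrameImage]:
    """Render frames: seeded noise texture plus a bright ellipse per track box.

    The background texture is static across frames (the virtual camera does
    not move); each present box is filled with a high-contrast ellipse.
    All channels are finally multiplied by ``color_cast``, emulating the
    blue-green cast of underwater light.
    """
    if scene.canvas_w < 64 or scene.canvas_h < 64:
        raise ValidationError("render canvas must be at least 64x64")
    rng = np.random.default_rng(texture_seed)
    noise = rng.normal(0, 1, size=(scene.canvas_h, scene.canvas_w))
    texture = ndimage.gaussian_filter(noise, sigma=3)
    texture = 100 + 40 * texture / max(1e-9, np.abs(texture).max())

    if frame_nos is None:
        frame_nos = range(scene.n_frames)
    yy, xx = np.mgrid[0 : scene.canvas_h, 0 : scene.canvas_w]
    frames = []
    for f in frame_nos:
        gray = texture.copy()
        for b in scene.boxes_at(f):
            cx, cy = b.center
            rx, ry = b.w / 2.0, b.h / 2.0
            mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
            gray[mask] = 230.0
        rgb = gray[:, :, None] * np.asarray(color_cast)[None, None, :]
        frames.append(
            FrameImage(
                np.clip(np.rint(rgb), 0, 255).astype(np.uint8), scene.movie_id, int(f)
            )
        )
    return frames
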