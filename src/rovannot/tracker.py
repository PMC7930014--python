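"""Frame-tracker data augmentation and underwater color correction.

Consensus boxes exist only on the handful of frames citizen scientists
annotated.  To multiply the training data, each consensus box is propagated
through the following movie frames with a template tracker: the grayscale
patch under the previous box is searched for in a window around its last
position by normalized cross-correlation (NCC), the best placement is
accepted while its score stays above a stop threshold, and the template is
refreshed after every accepted step.  With the default ``max_steps=10`` one
annotated box yields ten propagated boxes, a ten-fold augmentation.

Color correction compensates the wavelength-dependent attenuation of
underwater light with gray-world white balance followed by a per-channel
linear contrast stretch to the 1st-99th percentile range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
from skimage.feature import match_template

from .boxes import BBox
from .errors import ValidationError

DEFAULT_SEARCH_RADIUS = 20
DEFAULT_MAX_STEPS = 10
DEFAULT_STOP_SCORE = 0.5


@dataclass(frozen=True)
class FrameImage:
    """One decoded movie frame: H x W x 3 uint8 pixels plus provenance."""

    pixels: np.ndarray
    movie_id: str
    frame_no: int

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3 or p.dtype != np.uint8:
            raise ValidationError("pixels must be an HxWx3 uint8 array")
        if p.shape[0] < 16 or p.shape[1] < 16:
            raise ValidationError("frames must be at least 16x16 pixels")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class AugmentedAnnotation:
    """A training box on one frame, either human consensus or tracker-propagated."""

    movie_id: str
    frame_no: int
    bbox: BBox
    source: Literal["consensus", "propagated"]
    match_score: Optional[float] = None


def _gray(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(np.float64).mean(axis=2)


def propagate_boxes(
    frames: Sequence[FrameImage],
    seed_box: BBox,
    max_steps: int = DEFAULT_MAX_STEPS,
    stop_score: float = DEFAULT_STOP_SCORE,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> list[AugmentedAnnotation]:
    """Propagate ``seed_box`` from ``frames[0]`` into subsequent frames.

    For each following frame (at most ``max_steps``), the grayscale patch
    under the previous box is matched by NCC within ``search_radius`` pixels
    of its previous position.  Propagation emits the best placement while
    its score reaches ``stop_score`` and stops at the first failure —
    typically when the object leaves the field of view.  Returns propagated
    annotations only, ordered by frame number.
    """
    if len(frames) < 2:
        return []
    first = frames[0]
    if (
        seed_box.x < 0
        or seed_box.y < 0
        or seed_box.x2 > first.width
        or seed_box.y2 > first.height
    ):
        raise ValidationError(f"seed box {seed_box} outside frame bounds")
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) != 1:
        raise ValidationError("all frames must share dimensions")

    bx, by = int(round(seed_box.x)), int(round(seed_box.y))
    bw, bh = int(round(seed_box.w)), int(round(seed_box.h))
    template = _gray(first.pixels)[by : by + bh, bx : bx + bw]

    out: list[AugmentedAnnotation] = []
    for frame in frames[1 : 1 + max_steps]:
        gray = _gray(frame.pixels)
        x0 = max(0, bx - search_radius)
        y0 = max(0, by - search_radius)
        x1 = min(frame.width, bx + bw + search_radius)
        y1 = min(frame.height, by + bh + search_radius)
        window = gray[y0:y1, x0:x1]
        if window.shape[0] < bh or window.shape[1] < bw:
            break
        scores = match_template(window, template)
        best = np.unravel_index(int(np.argmax(scores)), scores.shape)
        score = float(scores[best])
        if score < stop_score:
            break
        by = y0 + int(best[0])
        bx = x0 + int(best[1])
        out.append(
            AugmentedAnnotation(
                movie_id=frame.movie_id,
                frame_no=frame.frame_no,
                bbox=BBox(float(bx), float(by), float(bw), float(bh)),
                source="propagated",
                match_score=score,
            )
        )
        template = gray[by : by + bh, bx : bx + bw]
    return out


def color_correct(image: FrameImage) -> FrameImage:
    """Gray-world white balance plus a 1st-99th percentile contrast stretch.

    Each channel is first scaled so its mean equals the overall mean (a
    channel with zero mean is passed through), then all channels are
    linearly stretched so the balanced image's 1st and 99th percentiles map
    to 0 and 255.  The stretch uses one lo/hi pair pooled over channels: a
    per-channel pair would re-tilt the channel means that the white balance
    just equalised.  An image with no dynamic range (percentiles coincide)
    passes through the stretch unchanged.  Output is clipped to [0, 255]
    uint8 of the same size.
    """
    px = image.pixels.astype(np.float64)
    means = px.reshape(-1, 3).mean(axis=0)
    overall = means.mean()
    balanced = px.copy()
    for c in range(3):
        if means[c] > 0:
            balanced[:, :, c] *= overall / means[c]
    lo, hi = np.percentile(balanced, [1.0, 99.0])
    if hi > lo:
        stretched = (balanced - lo) * (255.0 / (hi - lo))
    else:
        stretched = balanced
    out = np.clip(np.rint(stretched), 0, 255).astype(np.uint8)
    return FrameImage(out, image.movie_id, image.frame_no)


def frame_filename(movie_id: str, frame_no: int) -> str:
    return f"{movie_id}_{frame_no}.png"


def load_frame(path: Union[str, Path]) -> FrameImage:
    """Load a ``<movie_id>_<frame_no>.png`` frame image from disk."""
    path = Path(path)
    stem = path.stem
    movie_id, _, frame_no = stem.rpartition("_")
    if not movie_id or not frame_no.isdigit():
        raise ValidationError(
            f"frame filename must look like <movie_id>_<frame_no>: {path.name}"
        )
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=2)
    return FrameImage(pixels[:, :, :3].astype(np.uint8), movie_id, int(frame_no))


def save_frame(frame: FrameImage, directory: Union[str, Path]) -> Path:
    path = Path(directory) / frame_filename(frame.movie_id, frame.frame_no)
    iio.imwrite(path, frame.pixels)
    return path
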