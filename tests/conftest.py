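import random

import pytest

from rovannot.boxes import BBox
from rovannot.box_consensus import FrameAnnotation
from rovannot import synthetic as syn


@pytest.fixture
def small_scene():
    """A 100-second scene with three slow-moving objects (deterministic)."""
    return syn.make_scene("mv", seed=5, n_tracks=3, duration_s=100.0)


@pytest.fixture
def perfect_profiles():
    """Eight noiseless annotators: every answer equals ground truth."""
    return syn.default_profiles(
        8, sensitivity=1.0, specificity=1.0,
        first_seen_noise_sd=0.0, count_noise=0, box_jitter_sd=0.0, box_miss_prob=0.0,
    )


def random_frame_annotations(rng: random.Random, canvas: int = 200):
    """One random frame instance: 3-8 annotators, 0-4 integer boxes each."""
    n_ann = rng.randint(3, 8)
    anns = []
    for a in range(n_ann):
        boxes = []
        for _ in range(rng.randint(0, 4)):
            x = rng.randint(0, canvas - 20)
            y = rng.randint(0, canvas - 20)
            w = rng.randint(1, canvas - x)
            h = rng.randint(1, canvas - y)
            boxes.append(BBox(x, y, w, h))
        anns.append(FrameAnnotation("s", f"a{a}", tuple(boxes)))
    return anns
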