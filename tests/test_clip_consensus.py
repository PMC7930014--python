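import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rovannot.clip_consensus import (
    ClipAnnotation,
    aggregate_all,
    aggregate_clip,
    min_support,
)
from rovannot.errors import ValidationError


class TestMinSupport:
    def test_eight_annotators_at_eighty_percent_means_seven(self):
        assert min_support(8, 0.80) == 7

    @pytest.mark.parametrize(
        "n, thr, expected",
        [(8, 1.0, 8), (8, 0.60, 5), (8, 0.40, 4), (5, 0.8, 4), (1, 0.5, 1)],
    )
    def test_threshold_arithmetic(self, n, thr, expected):
        assert min_support(n, thr) == expected

    @pytest.mark.parametrize("thr", [0.0, -0.1, 1.01])
    def test_threshold_domain(self, thr):
        with pytest.raises(ValidationError):
            min_support(8, thr)

    @settings(max_examples=300, derandomize=True)
    @given(n=st.integers(1, 40), thr=st.floats(0.01, 1.0))
    def test_matches_enumeration_oracle(self, n, thr):
        """min_support is the smallest k in 1..n with k/n >= threshold."""
        oracle = next(k for k in range(1, n + 1) if k / n >= thr)
        assert min_support(n, thr) == oracle


def _clip(annotators_choices, subject="c1"):
    """Build annotations from [(annotator, choice, count, first_seen), ...]."""
    return [
        ClipAnnotation(subject, a, ch, cnt, fs)
        for a, ch, cnt, fs in annotators_choices
    ]


class TestAggregateClip:
    def test_seven_of_eight_retained_with_mean_first_seen(self):
        times = [2, 2, 3, 3, 4, 4, 3]
        anns = _clip(
            [(f"a{i}", "coral", 1, t) for i, t in enumerate(times)]
            + [("a7", "nothing_here", None, None)]
        )
        (r,) = aggregate_clip(anns, threshold=0.8)
        assert (r.choice_id, r.n_support, r.n_annotators) == ("coral", 7, 8)
        assert r.mean_first_seen_s == pytest.approx(3.0)

    def test_six_of_eight_not_retained(self):
        anns = _clip(
            [(f"a{i}", "coral", 1, 2.0) for i in range(6)]
            + [(f"a{i}", "nothing_here", None, None) for i in range(6, 8)]
        )
        assert aggregate_clip(anns, threshold=0.8) == []

    def test_unanimous_nothing_here(self):
        anns = _clip([(f"a{i}", "nothing_here", None, None) for i in range(5)])
        (r,) = aggregate_clip(anns, threshold=0.8)
        assert (r.choice_id, r.n_support) == ("nothing_here", 5)
        assert r.mean_first_seen_s is None and r.consensus_count is None

    def test_consensus_count_is_lower_median(self):
        anns = _clip([(f"a{i}", "coral", c, 1.0) for i, c in enumerate([1, 2, 3, 4])])
        (r,) = aggregate_clip(anns, threshold=1.0)
        assert r.consensus_count == 2  # lower of the two middle values

    def test_duplicate_votes_count_once(self):
        anns = _clip(
            [("a0", "coral", 1, 1.0), ("a0", "coral", 9, 5.0), ("a1", "coral", 1, 3.0)]
        )
        (r,) = aggregate_clip(anns, threshold=0.8)
        assert r.n_support == 2 and r.n_annotators == 2
        assert r.mean_first_seen_s == pytest.approx(2.0)  # first record per annotator

    def test_errors(self):
        with pytest.raises(ValidationError):
            aggregate_clip([], 0.8)
        mixed = [
            ClipAnnotation("c1", "a0", "coral"),
            ClipAnnotation("c2", "a0", "coral"),
        ]
        with pytest.raises(ValidationError, match="mix"):
            aggregate_clip(mixed, 0.8)

    def test_support_bounds_and_first_seen_range(self):
        times = [1.0, 2.0, 9.0]
        anns = _clip([(f"a{i}", "coral", 1, t) for i, t in enumerate(times)])
        (r,) = aggregate_clip(anns, threshold=0.6)
        assert r.n_support <= r.n_annotators
        assert min(times) <= r.mean_first_seen_s <= max(times)


@st.composite
def clip_tables(draw):
    n_ann = draw(st.integers(1, 8))
    choices = ["coral", "fish", "nothing_here"]
    anns = []
    for i in range(n_ann):
        k = draw(st.integers(1, 2))
        selected = draw(
            st.lists(st.sampled_from(choices), min_size=k, max_size=k, unique=True)
        )
        for ch in selected:
            anns.append(ClipAnnotation("c1", f"a{i}", ch, 1, 1.0))
    return anns


class TestThresholdMonotonicity:
    @settings(max_examples=200, derandomize=True)
    @given(anns=clip_tables(), t1=st.floats(0.1, 1.0), t2=st.floats(0.1, 1.0))
    def test_retained_set_shrinks_as_threshold_rises(self, anns, t1, t2):
        lo, hi = sorted([t1, t2])
        retained_lo = {r.choice_id for r in aggregate_clip(anns, lo)}
        retained_hi = {r.choice_id for r in aggregate_clip(anns, hi)}
        assert retained_hi <= retained_lo


class TestAggregateAll:
    def test_compositional_with_per_clip_aggregation(self):
        rows = []
        for s in ("c1", "c2"):
            for i in range(8):
                choice = "coral" if (s == "c1" or i < 7) else "nothing_here"
                rows.append((s, f"a{i}", choice, 1, 2.0))
        df = pd.DataFrame(
            rows,
            columns=["subject_id", "annotator_id", "choice_id",
                     "individual_count", "first_seen_s"],
        )
        out = aggregate_all(df, threshold=0.8)
        # c1 unanimous coral; c2 has 7/8 coral -> retained too
        coral = out[out.choice_id == "coral"]
        assert set(coral.subject_id) == {"c1", "c2"}
        assert coral.set_index("subject_id").n_support.to_dict() == {"c1": 8, "c2": 7}

    def test_empty_table_and_empty_marker(self):
        empty = pd.DataFrame(
            columns=["subject_id", "annotator_id", "choice_id",
                     "individual_count", "first_seen_s"]
        )
        assert aggregate_all(empty, 0.8).empty
        # a clip where nothing reaches threshold still appears, with null choice
        df = pd.DataFrame(
            [("c1", "a0", "coral", 1, 1.0), ("c1", "a1", "fish", 1, 1.0)],
            columns=["subject_id", "annotator_id", "choice_id",
                     "individual_count", "first_seen_s"],
        )
        out = aggregate_all(df, 0.8)
        assert len(out) == 1 and out.iloc[0].subject_id == "c1"
        assert pd.isna(out.iloc[0].choice_id) and out.iloc[0].n_support == 0
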