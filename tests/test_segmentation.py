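"""Segmentation unit tests plus oracle-equivalence property tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrscape.io import ScoreTrack
from idrscape.segmentation import (
    SegmentationParams,
    cohort_idr_summary,
    has_idr,
    segment_idrs,
)

from .oracles import brute_force_segments

DEFAULTS = SegmentationParams()


def track(scores, pid="p"):
    return ScoreTrack(protein_id=pid, scores=tuple(scores))


class TestSegmentIdrs:
    def test_all_high_single_segment(self):
        prof = segment_idrs(track([0.9] * 50), DEFAULTS)
        (seg,) = prof.segments
        assert seg.interval() == (1, 50)
        assert seg.n_exceptional == 0
        assert seg.confidence == 1.0
        assert prof.idr_content_pct == 100.0

    def test_all_low_no_segments(self):
        prof = segment_idrs(track([0.2] * 50), DEFAULTS)
        assert prof.segments == ()
        assert prof.idr_content_pct == 0.0

    def test_bridgeable_gap_merged(self):
        scores = [0.8] * 15 + [0.3] * 8 + [0.8] * 20
        prof = segment_idrs(track(scores), DEFAULTS)
        (seg,) = prof.segments
        assert seg.interval() == (1, 43)
        assert seg.n_exceptional == 8
        assert seg.confidence == pytest.approx(1 - 8 / 43)
        assert [seg.interval()] == brute_force_segments(scores, 0.5, 30, 10)

    def test_unbridgeable_gap_not_merged(self):
        scores = [0.8] * 15 + [0.3] * 11 + [0.8] * 20
        prof = segment_idrs(track(scores), DEFAULTS)
        assert prof.segments == ()
        assert brute_force_segments(scores, 0.5, 30, 10) == []

    def test_segments_end_on_above_threshold_residues(self):
        scores = [0.3] * 5 + [0.8] * 40 + [0.3] * 5
        (seg,) = segment_idrs(track(scores), DEFAULTS).segments
        assert seg.interval() == (6, 45)

    def test_two_separate_segments_reported_separately(self):
        scores = [0.8] * 35 + [0.2] * 12 + [0.8] * 32
        profile = segment_idrs(track(scores), DEFAULTS)
        assert [s.interval() for s in profile.segments] == [(1, 35), (48, 79)]


class TestHasIdr:
    profile = segment_idrs(track([0.8] * 43), DEFAULTS)

    def test_length_43_vs_40(self):
        assert has_idr(self.profile, 40)

    def test_length_43_vs_44(self):
        assert not has_idr(self.profile, 44)

    def test_empty_profile(self):
        empty = segment_idrs(track([0.1] * 43), DEFAULTS)
        assert not has_idr(empty, 20)


class TestParams:
    def test_min_len_must_exceed_max_gap(self):
        with pytest.raises(ValueError):
            SegmentationParams(min_len=10, max_gap=10)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            SegmentationParams(threshold=0.0)


def test_exhaustive_two_level_tracks_match_oracle():
    """Exhaustive oracle equivalence on all two-level tracks up to length 10
    (scaled-down params so segments can exist at these lengths)."""
    params = SegmentationParams(threshold=0.5, min_len=4, max_gap=2)
    for n in range(1, 11):
        for combo in itertools.product((0.2, 0.8), repeat=n):
            got = [s.interval() for s in segment_idrs(track(combo), params).segments]
            expected = brute_force_segments(combo, 0.5, 4, 2)
            assert got == expected, f"mismatch on {combo}"


@given(st.data())
@settings(max_examples=200, deadline=None, derandomize=True)
def test_random_tracks_match_oracle(data):
    n = data.draw(st.integers(min_value=1, max_value=50))
    scores = data.draw(
        st.lists(st.sampled_from([0.1, 0.3, 0.6, 0.9]), min_size=n, max_size=n)
    )
    max_gap = data.draw(st.integers(min_value=0, max_value=6))
    min_len = data.draw(st.integers(min_value=max_gap + 1, max_value=15))
    params = SegmentationParams(threshold=0.5, min_len=min_len, max_gap=max_gap)
    got = [s.interval() for s in segment_idrs(track(scores), params).segments]
    assert got == brute_force_segments(scores, 0.5, min_len, max_gap)


@given(
    scores=st.lists(st.sampled_from([0.2, 0.45, 0.55, 0.8]), min_size=1, max_size=60)
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_min_len_monotonicity_and_reversal(scores):
    """Segments at min_len 40 are a subset of those at 30, which are a
    subset of those at 20; content is invariant under track reversal."""
    segs = {}
    for ml in (20, 30, 40):
        p = SegmentationParams(min_len=ml, max_gap=10)
        segs[ml] = {s.interval() for s in segment_idrs(track(scores), p).segments}
    assert segs[40] <= segs[30] <= segs[20]

    fwd = segment_idrs(track(scores), DEFAULTS).idr_content_pct
    rev = segment_idrs(track(scores[::-1]), DEFAULTS).idr_content_pct
    assert fwd == pytest.approx(rev)


@given(
    scores=st.lists(st.sampled_from([0.2, 0.8]), min_size=5, max_size=60)
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_confidence_bounds(scores):
    """Confidence is in (0, 1] and equals 1 exactly when no interior
    residue is sub-threshold."""
    params = SegmentationParams(min_len=5, max_gap=3)
    for seg in segment_idrs(track(scores), params).segments:
        assert 0.0 < seg.confidence <= 1.0
        assert (seg.confidence == 1.0) == (seg.n_exceptional == 0)


class TestCohortSummary:
    def test_single_protein_content(self):
        t = track([0.8] * 43 + [0.2] * 43, pid="a")
        summary = cohort_idr_summary([t], {"a": "reader"})
        assert summary["reader"].mean_content == pytest.approx(50.0)
        assert summary["reader"].frac_with_idr[40] == 1.0

    def test_mean_and_threshold_fraction(self):
        t1 = track([0.2] * 100, pid="a")
        t2 = track([0.8] * 50 + [0.2] * 50, pid="b")
        s = cohort_idr_summary([t1, t2], {"a": "g", "b": "g"})["g"]
        assert s.mean_content == pytest.approx(25.0)
        assert s.frac_content_ge_threshold == pytest.approx(0.5)

    def test_unannotated_protein_errors(self):
        with pytest.raises(ValueError, match="no group annotation"):
            cohort_idr_summary([track([0.8] * 40, pid="a")], {})

    def test_planted_cohort_mean_recovered(self, small_cohort):
        """Recovered group mean content agrees with the generator's planted
        ground truth within Monte-Carlo error."""
        summary = cohort_idr_summary(small_cohort.tracks, small_cohort.groups)
        for group in ("reader", "enzyme"):
            planted = np.array(
                [
                    gt["target_content_pct"]
                    for gt in small_cohort.ground_truth.values()
                    if gt["group"] == group
                ]
            )
            se = planted.std(ddof=1) / np.sqrt(len(planted))
            assert abs(summary[group].mean_content - planted.mean()) < 3 * se + 1.0
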