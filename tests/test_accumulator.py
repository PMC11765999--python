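"""Accumulator construction, morphology, watershed and blink extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blinkdetect import (
    Accumulator,
    ClassifierContract,
    SegmentationConfig,
    SequenceTooShortError,
    accumulate_predictions,
    detect_blinks,
    extract_blinks,
    extract_windows,
    morphological_close,
    watershed_segment,
)
from blinkdetect.types import ClassifierContractError

from conftest import VoteReplayClassifier, constant_classifier, gray_sequence

NS = 12


class TestExtractWindows:
    @pytest.mark.parametrize(
        "n, expected_starts",
        [(12, [1]), (24, list(range(1, 14))), (13, [1, 2]), (100, list(range(1, 90)))],
    )
    def test_dense_overlap_starts(self, n, expected_starts):
        windows = extract_windows(gray_sequence(n), NS)
        assert [w.start for w in windows] == expected_starts
        assert all(w.length == NS for w in windows)

    def test_windows_are_contiguous_views_of_parent(self):
        seq = gray_sequence(20)
        seq.frames[4] = 99  # frame 5
        for w in extract_windows(seq, NS):
            if w.start <= 5 <= w.end:
                assert (w.data[5 - w.start] == 99).all()

    def test_too_short_sequence_is_rejected(self):
        with pytest.raises(SequenceTooShortError):
            extract_windows(gray_sequence(11), NS)


def brute_force_coverage(n, ns):
    """Votes per frame when every window votes 1, by direct enumeration."""
    cover = np.zeros(n, dtype=int)
    for start in range(1, n - ns + 2):
        cover[start - 1 : start - 1 + ns] += 1
    return cover


class TestAccumulate:
    def test_all_negative_classifier_gives_zero_signal(self, default_cfg):
        acc = accumulate_predictions(gray_sequence(30), constant_classifier(0.0), default_cfg)
        assert (acc.values == 0).all()

    def test_always_positive_votes_trace_window_coverage(self, default_cfg):
        acc = accumulate_predictions(gray_sequence(24), constant_classifier(1.0), default_cfg)
        expected = list(range(1, 13)) + list(range(12, 0, -1))
        assert acc.values.tolist() == expected
        assert acc.values.tolist() == brute_force_coverage(24, NS).tolist()

    @pytest.mark.parametrize("n", [12, 13, 25, 47, 100])
    def test_coverage_formula(self, n, default_cfg):
        acc = accumulate_predictions(gray_sequence(n), constant_classifier(1.0), default_cfg)
        i = np.arange(1, n + 1)
        formula = np.minimum.reduce([i, np.full(n, n - NS + 1), np.full(n, NS), n - i + 1])
        assert (acc.values == formula).all()
        assert (acc.values == brute_force_coverage(n, NS)).all()

    def test_votes_from_windows_containing_one_frame(self, default_cfg):
        # classifier votes 1 iff the window covers frame 10 (N=20)
        votes = [1.0 if start <= 10 <= start + NS - 1 else 0.0 for start in range(1, 10)]
        clf = VoteReplayClassifier(votes)
        acc = accumulate_predictions(gray_sequence(20), clf, default_cfg)
        assert acc.values[9] == 9  # frame 10: all 9 windows
        assert acc.values[0] == 1  # frame 1: window 1 only
        assert acc.values[19] == 1  # frame 20: window 9 only

    @settings(deadline=None, max_examples=30)
    @given(st.data())
    def test_bound_holds_for_random_classifiers(self, data):
        n = data.draw(st.integers(min_value=NS, max_value=100))
        votes = data.draw(
            st.lists(st.floats(0, 1), min_size=n - NS + 1, max_size=n - NS + 1)
        )
        acc = accumulate_predictions(
            gray_sequence(n), VoteReplayClassifier(votes), SegmentationConfig()
        )
        assert acc.values.min() >= 0
        assert acc.values.max() <= NS
        assert np.issubdtype(acc.values.dtype, np.integer)

    def test_scores_outside_unit_interval_violate_contract(self, default_cfg):
        with pytest.raises(ClassifierContractError):
            accumulate_predictions(gray_sequence(20), constant_classifier(1.5), default_cfg)

    def test_soft_votes_sum_probabilities(self):
        cfg = SegmentationConfig(soft_votes=True)
        acc = accumulate_predictions(gray_sequence(24), constant_classifier(0.25), cfg)
        assert acc.values[11] == pytest.approx(12 * 0.25)


class TestMorphologicalClose:
    def test_one_frame_dip_is_filled(self):
        acc = Accumulator(values=np.array([5, 5, 0, 5, 5]), ns=NS)
        assert morphological_close(acc, 3).values.tolist() == [5] * 5

    def test_isolated_spike_is_preserved(self):
        acc = Accumulator(values=np.array([0, 0, 5, 0, 0]), ns=NS)
        assert morphological_close(acc, 3).values.tolist() == [0, 0, 5, 0, 0]

    def test_even_se_length_rejected(self):
        with pytest.raises(ValueError):
            morphological_close(Accumulator(values=np.zeros(4), ns=NS), 4)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, NS), min_size=1, max_size=40))
    def test_closing_is_extensive_and_idempotent(self, values):
        acc = Accumulator(values=np.array(values), ns=NS)
        closed = morphological_close(acc, 3)
        assert (closed.values >= acc.values).all()
        twice = morphological_close(closed, 3)
        assert (twice.values == closed.values).all()

    @settings(deadline=None, max_examples=60)
    @given(st.data())
    def test_closing_is_order_preserving(self, data):
        n = data.draw(st.integers(1, 30))
        lower = np.array(data.draw(st.lists(st.integers(0, NS), min_size=n, max_size=n)))
        bumps = np.array(data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n)))
        upper = np.minimum(lower + bumps, NS)
        c_low = morphological_close(Accumulator(values=lower, ns=NS), 3).values
        c_up = morphological_close(Accumulator(values=upper, ns=NS), 3).values
        assert (c_low <= c_up).all()


def regional_maxima_count(values):
    """Plateaus strictly above both neighbours, by direct scan."""
    values = list(values)
    n = len(values)
    count = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        if (i == 0 or values[i - 1] < values[i]) and (
            j == n - 1 or values[j + 1] < values[j]
        ):
            count += 1
        i = j + 1
    return count


class TestWatershed:
    def test_two_peaks_split_at_the_internal_minimum(self):
        acc = Accumulator(values=np.array([0, 1, 5, 1, 0, 1, 6, 1, 0]), ns=NS)
        labels = watershed_segment(acc)
        assert labels.tolist() == [1, 1, 1, 1, 1, 2, 2, 2, 2]

    @pytest.mark.parametrize(
        "values",
        [[0, 1, 2, 3, 4], [3, 3, 3, 3], [7], [5, 4, 3, 2]],
    )
    def test_monotone_or_constant_signal_is_one_segment(self, values):
        labels = watershed_segment(Accumulator(values=np.array(values), ns=NS))
        assert (labels == 1).all()

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, NS), min_size=1, max_size=50))
    def test_labels_partition_frames_one_segment_per_maximum(self, values):
        acc = Accumulator(values=np.array(values), ns=NS)
        labels = watershed_segment(acc)
        assert len(labels) == len(values)
        segs = np.unique(labels)
        assert segs.tolist() == list(range(1, len(segs) + 1))
        # contiguity: labels are non-decreasing and change by at most 1
        assert (np.diff(labels) >= 0).all() and (np.diff(labels) <= 1).all()
        assert len(segs) == regional_maxima_count(values)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, NS), min_size=2, max_size=40))
    def test_agrees_with_library_watershed_on_segment_count(self, values):
        from skimage.segmentation import watershed as sk_watershed

        signal = np.array(values)
        ours = watershed_segment(Accumulator(values=signal, ns=NS))
        theirs = sk_watershed(-signal)
        assert len(np.unique(ours)) == len(np.unique(theirs))


class TestExtractBlinks:
    def test_supra_threshold_run_containing_the_peak(self, default_cfg):
        values = np.zeros(200, dtype=int)
        values[99:108] = [6, 7, 9, 12, 12, 11, 8, 7, 6]  # frames 100..108
        values[95:99] = [1, 2, 3, 5]
        acc = Accumulator(values=values, ns=NS)
        labels = watershed_segment(acc)
        blinks = extract_blinks(acc, labels, default_cfg)
        assert [(b.start, b.end) for b in blinks] == [(100, 108)]

    def test_sub_threshold_segment_emits_nothing(self, default_cfg):
        values = np.array([0, 1, 2, 4, 4, 2, 1, 0])
        acc = Accumulator(values=values, ns=NS)
        blinks = extract_blinks(acc, watershed_segment(acc), default_cfg)
        assert blinks == []

    def test_two_segments_give_two_ordered_intervals(self, default_cfg):
        values = np.array([0, 2, 8, 9, 7, 2, 1, 3, 7, 10, 6, 1, 0])
        acc = Accumulator(values=values, ns=NS)
        blinks = extract_blinks(acc, watershed_segment(acc), default_cfg)
        assert [(b.start, b.end) for b in blinks] == [(3, 5), (9, 11)]
        assert blinks[0].end < blinks[1].start


def naive_close(values, se=3):
    n = len(values)
    r = se // 2
    pad_min, out = min(values), []
    for i in range(n):
        window = [values[j] if 0 <= j < n else pad_min for j in range(i - r, i + r + 1)]
        out.append(max(window))
    pad_max, closed = max(out), []
    for i in range(n):
        window = [out[j] if 0 <= j < n else pad_max for j in range(i - r, i + r + 1)]
        closed.append(min(window))
    return closed


def reference_detect(votes, n, ns, cfg):
    """Independent end-to-end reference: naive accumulation, naive closing,
    supra-threshold runs split at interior regional-minimum plateaus
    (minimum plateau assigned to the left piece)."""
    acc = [0] * n
    for k, v in enumerate(votes):
        if v >= cfg.binarize_cutoff:
            for i in range(k, k + ns):
                acc[i] += 1
    closed = naive_close(acc, cfg.se_length)
    runs, i = [], 0
    while i < n:
        if closed[i] >= cfg.threshold_T:
            j = i
            while j + 1 < n and closed[j + 1] >= cfg.threshold_T:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    intervals = []
    for lo, hi in runs:
        cut = lo
        k = lo + 1
        while k < hi:
            # regional minimum plateau strictly inside the run
            if closed[k] < closed[k - 1]:
                m = k
                while m + 1 <= hi and closed[m + 1] == closed[k]:
                    m += 1
                if m < hi and closed[m + 1] > closed[k]:
                    intervals.append((cut + 1, m + 1))  # 1-based
                    cut = m + 1
                    k = m + 1
                    continue
            k += 1
        intervals.append((cut + 1, hi + 1))
    return intervals


class TestDetectBlinks:
    def test_silent_classifier_detects_nothing(self, default_cfg):
        assert detect_blinks(gray_sequence(60), constant_classifier(0.0), default_cfg) == []

    @settings(deadline=None, max_examples=40)
    @given(st.data())
    def test_matches_brute_force_reference_for_short_sequences(self, data):
        n = data.draw(st.integers(NS, 60))
        votes = data.draw(
            st.lists(st.sampled_from([0.0, 1.0]), min_size=n - NS + 1, max_size=n - NS + 1)
        )
        cfg = SegmentationConfig()
        got = detect_blinks(gray_sequence(n), VoteReplayClassifier(votes), cfg)
        expected = reference_detect(votes, n, NS, cfg)
        assert [(b.start, b.end) for b in got] == expected

    def test_rapid_succession_blinks_stay_separate(self, default_cfg):
        # two vote bursts whose supra-threshold runs touch but leave a dip
        votes = np.zeros(39)
        votes[4:14] = 1  # windows 5..14
        votes[18:28] = 1  # windows 19..28
        blinks = detect_blinks(gray_sequence(50), VoteReplayClassifier(votes), default_cfg)
        assert len(blinks) == 2
        assert blinks[0].end < blinks[1].start
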