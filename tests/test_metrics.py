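"""Time-use, bout and transition metrics against independent oracles."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actipat.epochs import GAP, ActivityLabel, find_valid_segment
from actipat.metrics import (
    COUNTED_TRANSITION_PAIRS,
    DailyTimeUse,
    bin_bouts,
    count_transitions,
    detect_bouts,
    percent_sedentary,
    summarize_participant,
    time_use,
)

from .conftest import L, SI, ST, W, make_series

label_seqs = st.lists(st.integers(0, 3), min_size=1, max_size=400)


def brute_force_bouts(labels):
    """Independent run-length scan via itertools.groupby."""
    out, pos = [], 0
    for lab, grp in itertools.groupby(labels):
        n = len(list(grp))
        out.append((int(lab), pos, float(n)))
        pos += n
    return out


def brute_force_transitions(labels):
    counted = {(int(a), int(b)) for a, b in COUNTED_TRANSITION_PAIRS}
    pairs = Counter(zip(labels, labels[1:]))
    return {p: pairs.get(p, 0) for p in counted}


class TestTimeUse:
    def test_single_state_day(self):
        tu = time_use([np.full(1440, SI, dtype=np.int8)])
        assert (tu.minutes_walking, tu.minutes_standing) == (0, 0)
        assert (tu.minutes_sitting, tu.minutes_lying) == (1440, 0)

    def test_mean_over_two_days(self):
        tu = time_use(
            [np.full(1440, SI, dtype=np.int8), np.full(1440, L, dtype=np.int8)]
        )
        assert (tu.minutes_sitting, tu.minutes_lying) == (720, 720)

    def test_matches_label_tally(self, rng):
        window = rng.integers(0, 4, size=1440).astype(np.int8)
        tu = time_use([window])
        tally = Counter(window.tolist())
        assert tu.minutes_walking == tally[W]
        assert tu.minutes_standing == tally[ST]
        assert tu.minutes_sitting == tally[SI]
        assert tu.minutes_lying == tally[L]
        assert tu.total == 1440

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            time_use([])


class TestPercentSedentary:
    def test_published_daily_means_give_94_percent(self):
        # 17.6 min walking, 1.1 h standing, 9.9 h sitting, 12.7 h lying
        pct = percent_sedentary(DailyTimeUse(17.6, 66.0, 594.0, 762.0))
        assert pct == pytest.approx(94.1667, abs=1e-3)
        assert round(pct) == 94

    @pytest.mark.parametrize(
        "tu,expected",
        [(DailyTimeUse(0, 0, 720, 720), 100.0), (DailyTimeUse(1440, 0, 0, 0), 0.0)],
    )
    def test_boundary_cases(self, tu, expected):
        assert percent_sedentary(tu) == expected


class TestDetectBouts:
    def test_hand_run_length(self):
        bouts = detect_bouts(np.array([W, W, SI, SI, SI, W], dtype=np.int8))
        assert [(b.activity, b.duration_minutes) for b in bouts] == [
            (ActivityLabel.WALKING, 2.0),
            (ActivityLabel.SITTING, 3.0),
            (ActivityLabel.WALKING, 1.0),
        ]
        assert [b.start_epoch for b in bouts] == [0, 2, 5]

    def test_single_epoch(self):
        (bout,) = detect_bouts(np.array([L], dtype=np.int8))
        assert bout.activity is ActivityLabel.LYING
        assert bout.duration_minutes == 1.0

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            detect_bouts(np.array([SI, GAP, SI], dtype=np.int8))

    @given(label_seqs)
    def test_matches_groupby_oracle(self, labels):
        got = [
            (int(b.activity), b.start_epoch, b.duration_minutes)
            for b in detect_bouts(np.asarray(labels, dtype=np.int8))
        ]
        assert got == brute_force_bouts(labels)

    @given(label_seqs)
    def test_every_epoch_in_exactly_one_bout(self, labels):
        bouts = detect_bouts(np.asarray(labels, dtype=np.int8))
        assert sum(b.duration_minutes for b in bouts) == len(labels)
        starts = [b.start_epoch for b in bouts]
        assert starts == sorted(starts)

    @given(label_seqs, st.integers(1, 399))
    def test_split_concat_differs_only_at_cut(self, labels, cut):
        """Splitting mid-sequence changes the bout list only at the cut bout."""
        cut = min(cut, len(labels) - 1) or 1
        if cut >= len(labels):
            return
        arr = np.asarray(labels, dtype=np.int8)
        whole = detect_bouts(arr)
        left, right = detect_bouts(arr[:cut]), detect_bouts(arr[cut:])
        split_within_bout = labels[cut - 1] == labels[cut]
        assert len(left) + len(right) == len(whole) + (1 if split_within_bout else 0)


class TestBinBouts:
    @pytest.mark.parametrize(
        "activity,duration,expected_bin",
        [
            (ActivityLabel.WALKING, 2.0, "2-3"),
            (ActivityLabel.WALKING, 1.0, "1-2"),
            (ActivityLabel.WALKING, 30.0, ">30"),
            (ActivityLabel.STANDING, 9.0, "3-10"),
            (ActivityLabel.SITTING, 60.0, ">60"),
            (ActivityLabel.LYING, 5.0, "5-10"),
        ],
    )
    def test_half_open_bin_assignment(self, activity, duration, expected_bin):
        from actipat.metrics import Bout

        hists = bin_bouts([Bout(activity, 0, duration)], n_valid_days=1)
        h = hists[activity]
        assert h.daily_mean_counts.sum() == 1
        assert h.labels[int(np.argmax(h.daily_mean_counts))] == expected_bin

    def test_histogram_conserves_bout_count(self, rng):
        labels = rng.integers(0, 4, size=5000).astype(np.int8)
        bouts = detect_bouts(labels)
        hists = bin_bouts(bouts, n_valid_days=3)
        total = sum(h.daily_mean_counts.sum() for h in hists.values()) * 3
        assert total == pytest.approx(len(bouts))


class TestCountTransitions:
    def test_listed_pairs_only(self):
        ts = count_transitions(np.array([L, SI, ST, W, SI, W], dtype=np.int8))
        assert ts.total == 2  # sitting->standing and sitting->walking
        assert ts.per_pair_counts[(ActivityLabel.SITTING, ActivityLabel.STANDING)] == 1
        assert ts.per_pair_counts[(ActivityLabel.SITTING, ActivityLabel.WALKING)] == 1
        assert ts.per_pair_counts[(ActivityLabel.LYING, ActivityLabel.STANDING)] == 0

    def test_constant_day_has_none(self):
        assert count_transitions(np.full(1440, SI, dtype=np.int8)).total == 0

    @given(label_seqs)
    def test_matches_pair_scan_oracle(self, labels):
        ts = count_transitions(np.asarray(labels, dtype=np.int8))
        oracle = brute_force_transitions(labels)
        assert {tuple(map(int, k)): v for k, v in ts.per_pair_counts.items()} == oracle

    @given(label_seqs)
    def test_bounded_by_label_changes(self, labels):
        arr = np.asarray(labels, dtype=np.int8)
        ts = count_transitions(arr)
        n_changes = int(np.sum(arr[:-1] != arr[1:]))
        assert ts.total <= n_changes <= len(labels) - 1 if len(labels) > 1 else True

    @given(label_seqs.filter(lambda s: s[-1] != 2))
    def test_appending_sit_to_walk_pair_adds_exactly_one(self, labels):
        base = count_transitions(np.asarray(labels, dtype=np.int8)).total
        extended = count_transitions(np.asarray(labels + [SI, W], dtype=np.int8)).total
        assert extended == base + 1


class TestSummarizeParticipant:
    def test_all_sitting_degenerate_segment(self):
        seg = find_valid_segment(make_series([SI] * 1440))
        summary = summarize_participant(seg)
        assert summary.time_use.minutes_sitting == 1440
        sit_hist = summary.bout_histograms[ActivityLabel.SITTING]
        assert sit_hist.labels[-1] == ">60"
        assert sit_hist.daily_mean_counts[-1] == 1.0
        assert summary.transitions.total == 0

    def test_deterministic_for_identical_participants(self, rng):
        labels = rng.integers(0, 4, size=2880).astype(np.int8)
        rows = [
            summarize_participant(find_valid_segment(make_series(labels, pid=p))).to_row()
            for p in ("a", "a")
        ]
        assert rows[0] == rows[1]

    def test_daily_minutes_conserved(self, rng):
        labels = rng.integers(0, 4, size=3000).astype(np.int8)
        seg = find_valid_segment(make_series(labels))
        summary = summarize_participant(seg)
        assert summary.time_use.total == pytest.approx(1440.0)

    def test_boundary_bout_counted_once_on_starting_day(self):
        # one lying bout spanning the day-1/day-2 cut
        labels = [SI] * 1439 + [L] * 1441
        seg = find_valid_segment(make_series(labels))
        summary = summarize_participant(seg)
        lie = summary.bout_histograms[ActivityLabel.LYING]
        assert lie.daily_mean_counts.sum() * seg.n_valid_days == 1  # one bout total
        assert lie.labels[int(np.argmax(lie.daily_mean_counts))] == ">60"
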