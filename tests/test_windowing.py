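"""Window segmentation: date arithmetic, exclusion rules, hand calendars."""

from datetime import date, datetime, time, timedelta, timezone

import pytest

from searchtrace.archive_io import ClinicalTimeline, SearchArchive
from searchtrace.windowing import (
    ExclusionNotice,
    WindowingError,
    control_window,
    diagnostic_window,
    relapse_windows,
    window_manifest,
)
from tests.conftest import UTC, daily_archive, sq


def ssd(pid, *hosps):
    return ClinicalTimeline(pid, "SSD", [(date.fromisoformat(a), date.fromisoformat(d)) for a, d in hosps])


class TestDiagnosticWindow:
    def test_window_spans_28_days_before_first_admission(self):
        a = SearchArchive(
            "s1",
            [sq(datetime(2018, 3, 5, 9, tzinfo=UTC)), sq(datetime(2018, 3, 28, 9, tzinfo=UTC))],
        )
        w = diagnostic_window(a, ssd("s1", ("2018-03-29", "2018-04-05")))
        assert w.start == datetime(2018, 3, 1, tzinfo=UTC)
        assert w.end == datetime(2018, 3, 29, tzinfo=UTC)
        assert w.n_queries == 2 and w.label == "SSD"

    def test_no_pre_admission_data_yields_exclusion(self):
        a = daily_archive("s1", date(2018, 4, 10), date(2018, 6, 1))
        out = diagnostic_window(a, ssd("s1", ("2018-03-29", "2018-04-05")))
        assert isinstance(out, ExclusionNotice)

    def test_query_at_admission_instant_is_outside_half_open_window(self):
        a = SearchArchive(
            "s1",
            [
                sq(datetime(2018, 3, 29, 0, 0, tzinfo=UTC)),  # exactly at admission
                sq(datetime(2018, 3, 28, 23, 59, tzinfo=UTC)),
            ],
        )
        w = diagnostic_window(a, ssd("s1", ("2018-03-29", "2018-04-05")))
        assert w.n_queries == 1
        assert w.queries[0].timestamp.hour == 23

    def test_hv_timeline_is_a_usage_error(self):
        a = daily_archive("h1", date(2018, 1, 1), date(2018, 3, 1))
        with pytest.raises(WindowingError):
            diagnostic_window(a, ClinicalTimeline("h1", "HV", []))


class TestControlWindow:
    def test_archive_spanning_exactly_28_days_gives_unique_window(self):
        a = daily_archive("h1", date(2018, 1, 1), date(2018, 1, 28))
        w1 = control_window(a, rng_seed=1)
        w2 = control_window(a, rng_seed=99)
        assert w1.start == w2.start == datetime(2018, 1, 1, tzinfo=UTC)
        assert w1.n_queries == 28

    def test_same_seed_gives_identical_window(self):
        a = daily_archive("h1", date(2018, 1, 1), date(2018, 6, 1))
        w1, w2 = control_window(a, rng_seed=7), control_window(a, rng_seed=7)
        assert (w1.start, w1.end, w1.n_queries) == (w2.start, w2.end, w2.n_queries)

    def test_single_query_archive_finds_the_containing_window(self):
        # 60-day span, one query: only some candidate starts contain it,
        # the bounded redraw must land on one of them
        lone = sq(datetime(2018, 2, 1, 15, tzinfo=UTC))
        a = SearchArchive(
            "h1", [sq(datetime(2018, 1, 1, 9, tzinfo=UTC)), lone, sq(datetime(2018, 3, 1, 9, tzinfo=UTC))]
        )
        # exhaustively enumerate which candidate windows are nonempty
        candidates = [
            datetime(2018, 1, 1, tzinfo=UTC) + timedelta(days=k) for k in range(60 - 28 + 1)
        ]
        nonempty = [
            s for s in candidates
            if any(s <= q.timestamp < s + timedelta(days=28) for q in a.queries)
        ]
        for seed in range(5):
            w = control_window(a, rng_seed=seed)
            assert not isinstance(w, ExclusionNotice)
            assert w.start in nonempty and w.n_queries >= 1

    def test_short_archive_is_excluded(self):
        a = daily_archive("h1", date(2018, 1, 1), date(2018, 1, 10))
        assert isinstance(control_window(a, rng_seed=0), ExclusionNotice)

    def test_empty_archive_is_excluded(self):
        assert isinstance(control_window(SearchArchive("h1", []), 0), ExclusionNotice)


# --- hand-built relapse calendar -----------------------------------------
# A: single hospitalization                      -> 0 illness, 1 health
# B: two admissions 90 d apart                   -> 1 illness, 2 health
# C: 20 d between hospitalizations (<1 month)    -> 0 illness, 1 health
# D: archive ends before the first admission     -> 0 windows, all dropped
# E: 40 d gap (>=1 month but <2 months)          -> 1 illness, 1 health
# F: healthy volunteer                           -> usage error

CAL = {
    "A": (daily_archive("A", date(2018, 1, 1), date(2018, 6, 1)),
          ssd("A", ("2018-03-01", "2018-03-10"))),
    "B": (daily_archive("B", date(2018, 1, 1), date(2018, 8, 1)),
          ssd("B", ("2018-03-01", "2018-03-10"), ("2018-06-08", "2018-06-18"))),
    "C": (daily_archive("C", date(2018, 1, 1), date(2018, 6, 1)),
          ssd("C", ("2018-03-01", "2018-03-10"), ("2018-03-30", "2018-04-09"))),
    "D": (daily_archive("D", date(2018, 1, 1), date(2018, 2, 20)),
          ssd("D", ("2018-03-01", "2018-03-10"), ("2018-06-08", "2018-06-18"))),
    "E": (daily_archive("E", date(2018, 1, 1), date(2018, 7, 1)),
          ssd("E", ("2018-03-01", "2018-03-10"), ("2018-04-19", "2018-04-29"))),
}

EXPECTED_COUNTS = {"A": (0, 1), "B": (1, 2), "C": (0, 1), "D": (0, 0), "E": (1, 1)}


class TestRelapseWindows:
    @pytest.mark.parametrize("pid", sorted(CAL))
    def test_hand_calendar_counts(self, pid):
        archive, timeline = CAL[pid]
        windows, notices = relapse_windows(archive, timeline)
        n_ill = sum(w.label == "illness" for w in windows)
        n_health = sum(w.label == "health" for w in windows)
        assert (n_ill, n_health) == EXPECTED_COUNTS[pid]

    def test_well_spaced_pair_window_dates(self):
        windows, _ = relapse_windows(*CAL["B"])
        by = {(w.label, w.start.date()) for w in windows}
        assert by == {
            ("health", date(2018, 3, 10)),
            ("illness", date(2018, 5, 11)),
            ("health", date(2018, 6, 18)),
        }

    def test_short_gap_skips_both_window_types(self):
        windows, notices = relapse_windows(*CAL["C"])
        assert [w.label for w in windows] == ["health"]
        reasons = " ".join(n.reason for n in notices)
        assert "illness window" in reasons and "health window" in reasons

    def test_no_window_overlaps_an_inpatient_interval(self):
        for pid in CAL:
            windows, _ = relapse_windows(*CAL[pid])
            for w in windows:
                for adm, dis in CAL[pid][1].hospitalizations:
                    a = datetime.combine(adm, time.min, tzinfo=UTC)
                    d = datetime.combine(dis, time.min, tzinfo=UTC)
                    if w.label == "illness":
                        assert w.end <= a or w.start >= d

    def test_no_window_precedes_first_admission(self):
        for pid in CAL:
            windows, _ = relapse_windows(*CAL[pid])
            first = datetime.combine(
                CAL[pid][1].hospitalizations[0][0], time.min, tzinfo=UTC
            )
            for w in windows:
                assert w.start >= first
                for q in w.lookback_queries:
                    assert q.timestamp >= first

    def test_hv_timeline_is_a_usage_error(self):
        with pytest.raises(WindowingError):
            relapse_windows(CAL["A"][0], ClinicalTimeline("A", "HV", []))

    def test_month_days_is_configurable(self):
        # E's 40-day gap passes at month_days=28 but fails at month_days=45
        windows, _ = relapse_windows(*CAL["E"], month_days=45)
        assert [w.label for w in windows] == ["health"]

    def test_windows_are_28_days_and_half_open(self):
        for pid in CAL:
            windows, _ = relapse_windows(*CAL[pid])
            for w in windows:
                assert w.end - w.start == timedelta(days=28)
                assert all(w.start <= q.timestamp < w.end for q in w.queries)


def test_window_manifest_lists_windows_and_exclusions():
    windows, notices = relapse_windows(*CAL["C"])
    df = window_manifest(windows + notices)
    assert set(df.columns) >= {"participant_id", "task", "label", "n_queries"}
    assert (df["label"] == "excluded").sum() == len(notices)
    assert (df["label"] == "health").sum() == 1
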