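from datetime import datetime, timedelta

import numpy as np
import pytest

from acmkit.circular import format_clock
from acmkit.diary import (
    DiaryRecord,
    InsufficientDiaryError,
    binarize_sleep,
    msfsc,
    sleep_probability,
    social_jetlag,
)

from _oracles import sleep_probability_count
from conftest import START


def nightly_diary(onset_hm, offset_hm, sid="x", days=7, start=START):
    """Diary with the same onset->offset episode on each of `days` nights."""
    intervals = []
    for d in range(days):
        a = start + timedelta(days=d, hours=onset_hm)
        dur = (offset_hm - onset_hm) % 24
        intervals.append((a, a + timedelta(hours=dur)))
    return DiaryRecord(subject_id=sid, sleep_intervals=intervals)


class TestBinarizeSleep:
    def test_empty_diary_all_awake(self):
        d = DiaryRecord(subject_id="x")
        s = binarize_sleep(d, START, 7 * 144)
        assert s.values.sum() == 0

    def test_eight_hours_gives_48_epochs_per_day(self):
        d = nightly_diary(0.0, 8.0)
        s = binarize_sleep(d, START, 7 * 144)
        per_day = s.values.reshape(7, 144).sum(axis=1)
        assert (per_day == 48).all()

    def test_short_interval_straddling_midnight_hits_one_epoch(self):
        # 23:55-00:05: only the epoch labelled 00:00 has its midpoint inside
        a = START + timedelta(hours=23, minutes=55)
        d = DiaryRecord(subject_id="x", sleep_intervals=[(a, a + timedelta(minutes=10))])
        s = binarize_sleep(d, START, 2 * 144)
        assert list(np.flatnonzero(s.values)) == [144]

    def test_quantization_bound_one_epoch_per_boundary(self):
        rng = np.random.default_rng(4)
        intervals = []
        for d in range(7):
            onset = rng.uniform(0, 2)
            dur = rng.uniform(6, 9)
            a = START + timedelta(days=d, hours=onset)
            intervals.append((a, a + timedelta(hours=dur)))
        diary = DiaryRecord(subject_id="x", sleep_intervals=intervals)
        s = binarize_sleep(diary, START, 7 * 144)
        diary_min = sum((b - a).total_seconds() / 60 for a, b in intervals)
        series_min = s.values.sum() * 10
        assert abs(series_min - diary_min) <= 10 * 2 * len(intervals)

    def test_overlapping_intervals_rejected(self):
        a = START
        with pytest.raises(ValueError, match="overlapping"):
            DiaryRecord(
                subject_id="x",
                sleep_intervals=[
                    (a, a + timedelta(hours=8)),
                    (a + timedelta(hours=4), a + timedelta(hours=12)),
                ],
            )


class TestSleepProbability:
    def test_single_subject_is_all_or_nothing(self):
        s = binarize_sleep(nightly_diary(0.0, 8.0), START, 7 * 144)
        wf = sleep_probability([s])
        assert set(np.unique(wf.values)) <= {0.0, 100.0}
        assert wf.values[:48].sum() == 48 * 100.0

    def test_two_disjoint_sleepers_split_fifty_fifty(self):
        s1 = binarize_sleep(nightly_diary(0.0, 8.0), START, 7 * 144)
        s2 = binarize_sleep(nightly_diary(12.0, 20.0, sid="y"), START, 7 * 144)
        wf = sleep_probability([s1, s2])
        assert wf.values[0] == pytest.approx(50.0)
        assert wf.values[73] == pytest.approx(50.0)  # 12:10 slot
        assert wf.values[60] == pytest.approx(0.0)   # 10:00 slot

    def test_matches_direct_count_oracle(self):
        rng = np.random.default_rng(17)
        series, mats = [], []
        for i in range(10):
            onset = float(rng.uniform(0, 3))
            dur = float(rng.uniform(6, 9))
            s = binarize_sleep(nightly_diary(onset, onset + dur, sid=str(i)), START, 7 * 144)
            series.append(s)
            mats.append(s.values.reshape(7, 144))
        wf = sleep_probability(series)
        np.testing.assert_allclose(wf.values, sleep_probability_count(mats), atol=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            sleep_probability([])


class TestMsfsc:
    def test_identical_week_needs_no_correction(self):
        t = msfsc(nightly_diary(0.0, 8.0))
        assert format_clock(t.msw) == "04:00"
        assert format_clock(t.msf) == "04:00"
        assert format_clock(t.msfsc) == "04:00"
        assert t.sjl == pytest.approx(0.0)

    def test_worked_example_to_the_minute(self):
        # work nights 00:00-07:00, free nights 01:00-10:00:
        # MSF = 05:30, SD_week = 53/7 h, correction = 5/7 h -> MSFsc = 04:47
        intervals = []
        for d in range(7):
            date = START + timedelta(days=d)
            if date.weekday() in (4, 5):  # Friday, Saturday onsets = free
                a = date + timedelta(hours=1)
                intervals.append((a, a + timedelta(hours=9)))
            else:
                intervals.append((date, date + timedelta(hours=7)))
        t = msfsc(DiaryRecord(subject_id="x", sleep_intervals=intervals))
        assert t.sd_work == pytest.approx(7.0)
        assert t.sd_free == pytest.approx(9.0)
        assert format_clock(t.msf) == "05:30"
        assert format_clock(t.msfsc) == "04:47"
        assert t.sjl == pytest.approx(2.0)

    def test_shorter_free_sleep_goes_uncorrected(self):
        intervals = []
        for d in range(7):
            date = START + timedelta(days=d)
            if date.weekday() in (4, 5):
                a = date + timedelta(hours=2)
                intervals.append((a, a + timedelta(hours=6)))  # SD_f = 6 < SD_w
            else:
                intervals.append((date, date + timedelta(hours=8)))
        t = msfsc(DiaryRecord(subject_id="x", sleep_intervals=intervals))
        assert t.msfsc == pytest.approx(t.msf)

    def test_insufficient_nights_flagged(self):
        d = nightly_diary(0.0, 8.0, days=2)  # Mon, Tue only: no free nights
        with pytest.raises(InsufficientDiaryError):
            msfsc(d)

    def test_duration_matches_circular_offset_minus_onset(self):
        for onset, dur in ((23.0, 8.0), (1.5, 7.25)):
            d = nightly_diary(onset, (onset + dur) % 24)
            for a, b in d.sleep_intervals:
                assert (b - a).total_seconds() / 3600 == pytest.approx(dur)


class TestSocialJetlag:
    @pytest.mark.parametrize(
        "msw,msf,expected",
        [(3.0, 3.0, 0.0), (3.0, 5.0, 2.0), (23.5, 1.5, 2.0)],
    )
    def test_circular_cases(self, msw, msf, expected):
        assert social_jetlag(msw, msf) == pytest.approx(expected)
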