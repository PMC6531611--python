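"""Sleep-scoring rules: onset/offset patterns, splitting, main-sleep
selection, efficiency and off-wrist validity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from helpers import offset_oracle, onset_oracle

from actidaily import (DEFAULT_PARAMS, SyntheticConfig, generate_cohort,
                       score_offset, score_onset, score_participant,
                       score_sleep_wake, select_main_sleep, split_intervals,
                       validate_sleep_day)
from actidaily.sleep import SleepInterval, _make_interval
from conftest import make_wrist

QUIET = [0] * 40   # padding of quiet epochs
ACTIVE = [200] * 40


class TestOnsetOffset:
    def test_onset_reports_last_active_epoch(self):
        # counts 50,30,12 then sustained quiescence starting 23:01:30
        w = make_wrist([50, 30, 12] + [0] * 20, start="2017-09-12T23:00:00")
        assert score_onset(w) == np.datetime64("2017-09-12T23:01:00")
        quiet_conv = DEFAULT_PARAMS.replace(onset_epoch="quiet")
        assert score_onset(w, quiet_conv) == np.datetime64("2017-09-12T23:01:30")

    def test_short_quiet_run_does_not_anchor_onset(self):
        # 40 is followed by only 4 quiet epochs; 20 starts real quiescence
        w = make_wrist([40, 0, 0, 0, 0, 20] + [0] * 10)
        assert score_onset(w) == np.datetime64("2017-09-12T23:02:30")

    def test_all_quiet_has_no_onset(self):
        assert score_onset(make_wrist([3] * 50)) is None

    def test_offset_is_first_active_after_quiet_run(self):
        w = make_wrist([0] * 12 + [35, 60, 40])
        assert score_offset(w) == np.datetime64("2017-09-12T23:06:00")

    def test_unbroken_quiet_tail_has_no_offset(self):
        w = make_wrist([80, 90] + [0] * 30)
        assert score_offset(w) is None

    def test_segment_shorter_than_pattern(self):
        assert score_onset(make_wrist([50, 0, 0])) is None

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.choice([0, 3, 8, 15, 60], size=60,
                                p=[0.4, 0.15, 0.15, 0.15, 0.15])
            w = make_wrist(counts)
            wr = make_wrist(counts[::-1])
            on = score_onset(w)
            off = score_offset(wr)
            if on is None:
                assert off is None
            else:
                i = int((on - w.start) / np.timedelta64(30, "s"))
                j = int((off - wr.start) / np.timedelta64(30, "s"))
                assert j == len(counts) - 1 - i

    def test_matches_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(8, 120))
            counts = rng.choice([0, 5, 11, 80], size=n, p=[0.45, 0.2, 0.1, 0.25])
            off = rng.random(n) < 0.1
            w = make_wrist(counts, offwrist=off)
            for scorer, oracle in ((score_onset, onset_oracle),
                                   (score_offset, offset_oracle)):
                got = scorer(w)
                exp = oracle(counts, off)
                if exp is None:
                    assert got is None
                else:
                    assert got == w.start + exp * np.timedelta64(30, "s")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(counts=st.lists(st.sampled_from([0, 5, 11, 80]), min_size=1,
                           max_size=60))
    def test_onset_property_matches_oracle(self, counts):
        counts = np.asarray(counts)
        off = np.zeros(len(counts), bool)
        w = make_wrist(counts)
        got = score_onset(w)
        exp = onset_oracle(counts, off)
        if exp is None:
            assert got is None
        else:
            assert got == w.start + exp * np.timedelta64(30, "s")

    def test_offwrist_breaks_quiet_runs(self):
        counts = [50, 0, 0, 0, 0, 0, 0]
        off = np.array([0, 0, 0, 1, 0, 0, 0], bool)
        assert score_onset(make_wrist(counts, offwrist=off)) is None


class TestSplitAndSelect:
    def _rest_with_wake_block(self, wake_min):
        # 3 h sleep, wake block, 3 h sleep, flanked by active context
        counts = (ACTIVE + [0] * 360 + [300] * (wake_min * 2) + [0] * 360
                  + ACTIVE)
        return make_wrist(counts, start="2017-09-12T22:00:00")

    def test_70min_awakening_splits_interval(self):
        w = self._rest_with_wake_block(70)
        onset, offset = score_onset(w), score_offset(w)
        parts = split_intervals(w, onset, offset)
        assert len(parts) == 2

    def test_50min_awakening_does_not_split(self):
        w = self._rest_with_wake_block(50)
        onset, offset = score_onset(w), score_offset(w)
        parts = split_intervals(w, onset, offset)
        assert len(parts) == 1
        # the wake block still counts against efficiency
        assert parts[0].sme_pct < 90.0

    def test_no_wake_blocks_single_interval(self):
        w = make_wrist(ACTIVE + [0] * 480 + ACTIVE)
        parts = split_intervals(w, score_onset(w), score_offset(w))
        assert len(parts) == 1

    def _interval(self, onset, offset):
        on, off = np.datetime64(onset), np.datetime64(offset)
        dur = float((off - on) / np.timedelta64(1, "s")) / 60
        iv = SleepInterval("P", on, off, dur, dur, 100.0)
        return iv

    def test_night_beats_afternoon_nap(self):
        night = self._interval("2017-09-12T23:00:00", "2017-09-13T07:00:00")
        nap = self._interval("2017-09-13T14:00:00", "2017-09-13T15:00:00")
        # nap belongs to the next cut day; within its own day night wins
        main = select_main_sleep([night])
        assert main is night
        assert select_main_sleep([nap]) is None  # nap never touches the window

    def test_total_duration_decides_between_window_overlappers(self):
        first = self._interval("2017-09-12T22:30:00", "2017-09-13T02:00:00")
        second = self._interval("2017-09-13T03:00:00", "2017-09-13T07:30:00")
        assert select_main_sleep([first, second]) is second  # 4.5 h > 3.5 h

    def test_window_duration_mode(self):
        # long interval mostly outside the window vs short fully inside
        long_iv = self._interval("2017-09-13T05:00:00", "2017-09-13T13:00:00")
        short_iv = self._interval("2017-09-12T23:00:00", "2017-09-13T03:00:00")
        p = DEFAULT_PARAMS.replace(main_sleep_duration="window")
        assert select_main_sleep([long_iv, short_iv], p) is short_iv
        assert select_main_sleep([long_iv, short_iv]) is long_iv


class TestEfficiency:
    def test_all_quiet_interval_is_fully_asleep(self):
        w = make_wrist(ACTIVE + [0] * 480 + ACTIVE, start="2017-09-12T22:00:00")
        onset, offset = score_onset(w), score_offset(w)
        p = DEFAULT_PARAMS.replace(onset_epoch="quiet")
        onset_q = score_onset(w, p)
        iv = _make_interval(w, onset_q, offset, p)
        assert iv.sleep_min == pytest.approx(iv.duration_min)
        assert iv.sme_pct == pytest.approx(100.0)

    def test_efficiency_arithmetic(self):
        # 480-min interval with 40 min of wake -> 440/480 = 91.7%
        counts = [0] * 500 + [300] * 80 + [0] * 380
        w = make_wrist([200] + counts + [200], start="2017-09-12T22:00:00")
        iv = _make_interval(
            w, np.datetime64("2017-09-12T22:00:30"),
            np.datetime64("2017-09-13T06:00:30"),
            DEFAULT_PARAMS,
        )
        assert iv.duration_min == pytest.approx(480.0)
        assert iv.sme_pct == pytest.approx(100 * 440 / 480, abs=0.01)

    def test_efficiency_monotone_in_wake_threshold(self):
        rng = np.random.default_rng(3)
        counts = rng.choice([0, 4, 9, 20, 100], size=240)
        w = make_wrist(np.concatenate([[200], counts, [200]]))
        on = np.datetime64(w.start) + np.timedelta64(30, "s")
        off = on + np.timedelta64(240 * 30, "s")
        last = 101.0
        for thr in (100, 50, 10, 5, 0):
            asleep = score_sleep_wake(w, on, off,
                                      DEFAULT_PARAMS.replace(count_threshold=thr))
            eff = 100.0 * asleep.mean()
            assert eff <= last + 1e-12
            last = eff


class TestValidity:
    def _worn_day(self, off_runs, start="2017-09-12T12:00:00", n_ep=2880):
        off = np.zeros(n_ep, bool)
        for s, ln in off_runs:
            off[s: s + ln] = True
        counts = np.where(off, 0, 200)
        counts[1320:2340] = 0  # quiet night 23:00-07:30 (epochs from noon)
        counts[1319] = 250
        counts[2340] = 250
        return make_wrist(counts, start=start, offwrist=off)

    def _main(self, series):
        ivs = [iv for iv in score_participant(series) if iv.role == "main"]
        assert ivs
        return ivs[0]

    def test_fully_worn_day_is_valid(self):
        w = self._worn_day([])
        main = self._main(w)
        ok, why = validate_sleep_day(w, main, main.cut_day, False, False)
        assert ok and why == ""

    def test_offwrist_total_boundary(self):
        # 239 min off-wrist: valid; 240: invalid (middle days only)
        for minutes, expect in ((239, True), (240, False)):
            w = self._worn_day([(200, minutes * 2)])
            main = self._main(w)
            ok, why = validate_sleep_day(w, main, main.cut_day, False, False)
            assert ok is expect, (minutes, why)
            ok_last, _ = validate_sleep_day(w, main, main.cut_day, False, True)
            assert ok_last  # last-day exemption

    def test_offwrist_run_near_onset_invalidates(self):
        # 60-min run ending 5 min before the scored onset
        w = self._worn_day([(1320 - 130, 120)])
        main = self._main(w)
        ok, why = validate_sleep_day(w, main, main.cut_day, False, False)
        assert not ok and why == "offwrist_edge"

    def test_first_day_needs_two_hours_of_wear_before_onset(self):
        # recording starts 90 min before onset
        counts = np.concatenate([[250] * 180, [0] * 1020, [250] * 40])
        w = make_wrist(counts, start="2017-09-12T21:30:00")
        main = self._main(w)
        ok, why = validate_sleep_day(w, main, main.cut_day, True, False)
        assert not ok and why == "first_day_wear"

    def test_missing_main_sleep_invalid(self):
        w = self._worn_day([])
        ok, why = validate_sleep_day(w, None, np.datetime64("2017-09-12"),
                                     False, False)
        assert not ok and why == "no_main_sleep"


class TestPipelineRecovery:
    def test_clean_cohort_scored_exactly(self, clean_cohort):
        """Without arousal noise every scored onset/offset equals the
        rendered ground truth to the epoch."""
        truth = clean_cohort.truth.daily
        for w in clean_cohort.wrist:
            t = truth[truth["participant_id"] == w.participant_id]
            expected = {
                (pd.Timestamp(a), pd.Timestamp(b))
                for a, b in zip(t["onset_dt"], t["offset_dt"])
                if not pd.isna(b)
            }
            got = {
                (pd.Timestamp(iv.onset), pd.Timestamp(iv.offset))
                for iv in score_participant(w)
                if iv.role == "main" and not iv.truncated
            }
            assert got == expected

    def test_noisy_cohort_within_one_epoch(self):
        cohort = generate_cohort(
            SyntheticConfig(n_participants=6, n_days=5, seed=23, arousals=True)
        )
        truth = cohort.truth.daily
        n_tot = n_ok = 0
        for w in cohort.wrist:
            t = truth[truth["participant_id"] == w.participant_id]
            onsets = {pd.Timestamp(a) for a in t["onset_dt"]}
            for iv in score_participant(w):
                if iv.role != "main":
                    continue
                n_tot += 1
                near = any(
                    abs((pd.Timestamp(iv.onset) - o).total_seconds()) <= 30
                    for o in onsets
                )
                n_ok += near
        assert n_tot >= 30
        assert n_ok / n_tot >= 0.99
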