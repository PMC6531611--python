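"""Sleep-anchored day alignment: segmentation, validity, totals, clusters."""

import numpy as np
import pandas as pd
import pytest
from helpers import cluster_oracle

from actidaily import (DEFAULT_PARAMS, cluster_sample_strata,
                       filter_participants, light_means, merge_minutes,
                       midnight_centered_hours, mvpa_cluster, segment_days,
                       validate_pa_day)
from actidaily.sleep import SleepInterval, _cut_day
from conftest import make_wrist


def interval(onset, offset, role="main", valid=True, pid="P"):
    on = np.datetime64(onset, "s")
    off = np.datetime64(offset, "s") if offset is not None else np.datetime64("NaT")
    dur = (float((off - on) / np.timedelta64(1, "s")) / 60
           if offset is not None else np.nan)
    iv = SleepInterval(pid, on, off, dur, dur, 100.0, role=role, valid=valid)
    iv.cut_day = _cut_day(on)
    return iv


def quiet_wrist(start="2017-09-11T12:00:00", hours=96):
    n = hours * 120
    return make_wrist(np.full(n, 200), start=start)


def minute_table(start, n_min, mvpa_at=(), sed_at=(), nonwear_at=()):
    t0 = np.datetime64(start, "s")
    starts = t0 + np.arange(n_min) * np.timedelta64(60, "s")
    cls = np.full(n_min, "light", object)
    for a, b in mvpa_at:
        cls[a:b] = "MVPA"
    for a, b in sed_at:
        cls[a:b] = "sedentary"
    nw = np.zeros(n_min, bool)
    for a, b in nonwear_at:
        nw[a:b] = True
    return pd.DataFrame({"participant_id": "P", "minute_start": starts,
                         "raw_class": cls, "class3": cls, "nonwear": nw})


class TestMidnightCentering:
    @pytest.mark.parametrize("onset,expected", [
        ("2017-09-13T00:04:00", 4 / 60),
        ("2017-09-12T22:00:00", -2.0),
        ("2017-09-13T01:30:00", 1.5),
        ("2017-09-12T21:00:00", -3.0),
    ])
    def test_continuous_scale_across_midnight(self, onset, expected):
        cd = _cut_day(np.datetime64(onset, "s"))
        assert midnight_centered_hours(onset, cd) == pytest.approx(expected)


class TestSegmentDays:
    def test_worked_day_length_example(self):
        """Onset 10 PM then 11:30 PM the next night gives a 25.5-h day."""
        ivs = [interval("2017-09-12T22:00:00", "2017-09-13T06:00:00"),
               interval("2017-09-13T23:30:00", "2017-09-14T07:00:00")]
        days = segment_days(ivs, quiet_wrist())
        assert len(days) == 2
        assert days[0]["day_length_h"] == pytest.approx(25.5)
        assert not days[0]["forced_end"]

    def test_identical_onsets_give_24h_days(self):
        ivs = [interval(f"2017-09-{11 + d}T23:00:00", f"2017-09-{12 + d}T07:00:00")
               for d in range(4)]
        days = segment_days(ivs, quiet_wrist())
        assert [d["day_length_h"] for d in days[:-1]] == pytest.approx([24.0] * 3)

    def test_forced_end_at_offwrist_block(self):
        """With no terminating sleep, a 70-min off-wrist block at 21:00
        force-ends the day there."""
        w = quiet_wrist(start="2017-09-12T12:00:00", hours=48)
        off = w.offwrist.copy()
        i = w.index_of(np.datetime64("2017-09-13T21:00:00"))
        off[i: i + 140] = True
        w = make_wrist(w.counts, start="2017-09-12T12:00:00", offwrist=off)
        ivs = [interval("2017-09-12T23:00:00", "2017-09-13T07:00:00")]
        [day] = segment_days(ivs, w)
        assert day["forced_end"]
        assert day["day_end"] == np.datetime64("2017-09-13T21:00:00")

    def test_forced_end_at_apparent_sleep(self):
        ivs = [interval("2017-09-12T23:00:00", "2017-09-13T07:00:00"),
               interval("2017-09-13T22:40:00", None, valid=False)]
        [day] = segment_days(ivs, quiet_wrist())
        assert day["forced_end"]
        assert day["day_end"] == np.datetime64("2017-09-13T22:40:00")

    def test_weekend_flags(self):
        # 2017-09-15 is a Friday: Friday night / Saturday day
        ivs = [interval("2017-09-15T23:00:00", "2017-09-16T07:00:00"),
               interval("2017-09-16T23:00:00", "2017-09-17T07:00:00"),
               interval("2017-09-17T23:00:00", "2017-09-18T07:00:00")]
        days = segment_days(ivs, quiet_wrist(start="2017-09-15T12:00:00"))
        assert [d["weekend_night"] for d in days] == [True, True, False]
        assert [d["weekend_day"] for d in days] == [True, True, False]


class TestPaValidity:
    def _day(self, length_h=24.0, forced=False):
        return {"forced_end": forced, "day_length_h": length_h}

    @pytest.mark.parametrize("pct,expected", [(26.0, False), (25.0, True),
                                              (0.0, True)])
    def test_nonwear_percentage_rule(self, pct, expected):
        assert validate_pa_day(self._day(), pct) is expected

    def test_short_forced_day_invalid(self):
        assert validate_pa_day(self._day(19.5, forced=True), 0.0) is False
        assert validate_pa_day(self._day(20.5, forced=True), 0.0) is True
        assert validate_pa_day(self._day(19.5, forced=False), 0.0) is True


class TestMergeMinutes:
    def _day(self, start="2017-09-13T07:00:00", end="2017-09-13T23:00:00"):
        return {"participant_id": "P",
                "day_start": np.datetime64("2017-09-12T23:00:00"),
                "sleep_offset": np.datetime64(start, "s"),
                "day_end": np.datetime64(end, "s")}

    def test_sedentary_inside_nap_fully_excluded(self):
        day = self._day()
        mt = minute_table("2017-09-13T07:00:00", 960, sed_at=[(300, 330)])
        nap = interval("2017-09-13T12:00:00", "2017-09-13T12:30:00", role="nap")
        out = merge_minutes(day, mt, [nap])
        assert out["sedentary_min"] == 0

    def test_no_naps_keeps_raw_sedentary(self):
        day = self._day()
        mt = minute_table("2017-09-13T07:00:00", 960, sed_at=[(300, 360)])
        assert merge_minutes(day, mt, [])["sedentary_min"] == 60

    def test_half_overlapping_nap_counts_half(self):
        day = self._day()
        mt = minute_table("2017-09-13T07:00:00", 960, sed_at=[(300, 360)])
        # nap 12:30-13:30 over sedentary block 12:00-13:00 -> 30 counted
        nap = interval("2017-09-13T12:30:00", "2017-09-13T13:30:00", role="nap")
        assert merge_minutes(day, mt, [nap])["sedentary_min"] == 30

    def test_mvpa_and_nonwear_pct(self):
        day = self._day()
        mt = minute_table("2017-09-13T07:00:00", 960,
                          mvpa_at=[(100, 145)], nonwear_at=[(500, 740)])
        out = merge_minutes(day, mt, [])
        assert out["mvpa_min"] == 45
        assert out["nonwear_pct"] == pytest.approx(100 * 240 / 960)


class TestCluster:
    def _day(self, n_min=600):
        start = np.datetime64("2017-09-13T08:00:00")
        return ({"sleep_offset": start,
                 "day_end": start + n_min * np.timedelta64(60, "s")}, start)

    def test_concentrated_bout_fully_captured(self):
        day, start = self._day()
        mt = minute_table("2017-09-13T08:00:00", 600, mvpa_at=[(480, 525)])
        mid, count = mvpa_cluster(day, mt)
        assert count == 45
        # earliest maximizing window starts at minute 405 (=525-120)
        assert mid == start + (405 + 60) * np.timedelta64(60, "s")

    def test_zero_mvpa_degenerate(self):
        day, start = self._day()
        mt = minute_table("2017-09-13T08:00:00", 600)
        mid, count = mvpa_cluster(day, mt)
        assert count == 0
        assert mid == start + 60 * np.timedelta64(60, "s")

    def test_tie_breaks_earliest(self):
        day, start = self._day()
        mt = minute_table("2017-09-13T08:00:00", 600,
                          mvpa_at=[(60, 80), (500, 520)])
        mid, count = mvpa_cluster(day, mt)
        assert count == 20
        assert mid < start + 300 * np.timedelta64(60, "s")

    def test_short_daytime_span_gives_none(self):
        day, _ = self._day(n_min=100)
        mt = minute_table("2017-09-13T08:00:00", 100, mvpa_at=[(10, 20)])
        mid, count = mvpa_cluster(day, mt)
        assert pd.isna(mid) and np.isnan(count)

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(120, 700))
            is_mvpa = rng.random(n) < 0.08
            day, start = self._day(n_min=n)
            mt = minute_table("2017-09-13T08:00:00", n,
                              mvpa_at=[(i, i + 1) for i in np.nonzero(is_mvpa)[0]])
            mid, count = mvpa_cluster(day, mt)
            s_exp, c_exp = cluster_oracle(is_mvpa)
            assert count == c_exp
            assert mid == start + (s_exp + 60) * np.timedelta64(60, "s")


class TestLightMeans:
    def _day(self):
        return {"sleep_offset": np.datetime64("2017-09-13T08:00:00"),
                "day_end": np.datetime64("2017-09-13T20:00:00")}

    def test_constant_lux(self):
        w = make_wrist(np.full(2880, 200), start="2017-09-13T00:00:00",
                       lux=np.full(2880, 200.0))
        mid = np.datetime64("2017-09-13T12:00:00")
        d, c = light_means(self._day(), w, mid)
        assert d == pytest.approx(200.0) and c == pytest.approx(200.0)

    def test_missing_cluster_gives_missing_mean(self):
        w = make_wrist(np.full(2880, 200), start="2017-09-13T00:00:00",
                       lux=np.full(2880, 200.0))
        d, c = light_means(self._day(), w, np.datetime64("NaT"))
        assert d == pytest.approx(200.0) and np.isnan(c)

    def test_half_zero_half_400(self):
        lux = np.full(2880, 0.0)
        # daytime window 08:00-20:00 = epochs 960..2400; second half at 400
        lux[1680:2400] = 400.0
        w = make_wrist(np.full(2880, 200), start="2017-09-13T00:00:00", lux=lux)
        d, _ = light_means(self._day(), w, np.datetime64("NaT"))
        assert d == pytest.approx(200.0)

    def test_all_offwrist_daytime_missing(self):
        off = np.ones(2880, bool)
        w = make_wrist(np.zeros(2880, int), start="2017-09-13T00:00:00",
                       offwrist=off)
        d, c = light_means(self._day(), w, np.datetime64("NaT"))
        assert np.isnan(d) and np.isnan(c)


def _person_days(pid, cut_days, valid_pa=None, cluster=10.0, month=9):
    rows = []
    for i, d in enumerate(cut_days):
        rows.append({
            "participant_id": pid,
            "cut_day": np.datetime64(f"2017-{month:02d}-{10 + d:02d}"),
            "valid_pa": True if valid_pa is None else valid_pa[i],
            "cluster_mvpa_min": cluster,
        })
    return pd.DataFrame(rows)


class TestFilters:
    def test_three_consecutive_sleep_days_required(self):
        broken = _person_days("A", [1, 2, 4, 5])      # two runs of 2
        ok = _person_days("B", [1, 2, 3, 5])
        out = filter_participants(pd.concat([broken, ok], ignore_index=True))
        assert set(out["participant_id"]) == {"B"}

    def test_fully_valid_week_included(self):
        out = filter_participants(_person_days("A", list(range(7))))
        assert set(out["participant_id"]) == {"A"}

    def test_pa_day_count_rule(self):
        pd_days = _person_days("A", [1, 2, 3, 4],
                               valid_pa=[True, True, False, False])
        assert filter_participants(pd_days).empty

    def test_school_year_filter(self):
        july = _person_days("A", [1, 2, 3], month=7)
        sept = _person_days("B", [1, 2, 3], month=9)
        both = pd.concat([july, sept], ignore_index=True)
        assert set(filter_participants(both, season="school_year")
                   ["participant_id"]) == {"B"}
        assert set(filter_participants(both, season="summer")
                   ["participant_id"]) == {"A"}
        with pytest.raises(ValueError):
            filter_participants(both, season="winter")

    @pytest.mark.parametrize("mean,included", [(9.9, False), (10.0, True)])
    def test_cluster_strata_boundary(self, mean, included):
        days = _person_days("A", [1, 2, 3], cluster=mean)
        out = cluster_sample_strata(days)
        assert (not out.empty) is included

    def test_all_zero_mvpa_cohort_empty_stratum(self):
        days = _person_days("A", [1, 2, 3], cluster=0.0)
        assert cluster_sample_strata(days).empty
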