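"""Sleep-onset-anchored person-days.

A "day" runs from one night's main sleep onset to the next night's main
sleep onset, so its length floats with the sleep schedule (a 10 PM onset
followed by an 11:30 PM onset gives a 25.5-hour day).  When the terminating
night has no valid main sleep, the day is force-ended at the first of more
than one hour of off-wrist time or an apparent sleep interval after the
morning offset.  Each person-day carries that night's sleep metrics
(midnight-centered onset, 24-h-clock offset, duration, maintenance
efficiency), the following day's activity totals, the densest-MVPA-cluster
statistic, daytime light summaries, and validity flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_PARAMS, EPOCH_S, ScoringParams
from .sleep import SleepInterval, _runs
from .streams import SECOND, WristEpochSeries

HOUR = 3600.0
MIN_STEP = np.timedelta64(1, "m")


def _midnight(cut_day) -> np.datetime64:
    """Midnight inside the night window of a cut-point day (its end)."""
    return np.datetime64(cut_day, "D").astype("datetime64[s]") + np.timedelta64(24, "h")


def midnight_centered_hours(onset, cut_day) -> float:
    """Sleep onset as signed hours around the night's midnight:
    22:00 -> -2.0, 00:04 -> +0.067 (continuous across midnight)."""
    return float((np.datetime64(onset, "s") - _midnight(cut_day)) / SECOND) / HOUR


def _weekday(d) -> int:
    return int((np.datetime64(d, "D").view(np.int64) + 3) % 7)  # Monday=0


def segment_days(intervals: list[SleepInterval], series: WristEpochSeries,
                 params: ScoringParams = DEFAULT_PARAMS) -> list[dict]:
    """Build person-day skeletons from scored sleep intervals.

    One skeleton per valid main sleep night; the day ends at the next
    calendar night's valid main onset, or is force-ended otherwise.
    """
    mains = sorted(
        (iv for iv in intervals if iv.role == "main"), key=lambda iv: iv.onset
    )
    valid_mains = {iv.cut_day: iv for iv in mains if iv.valid and not iv.truncated}
    all_onsets = sorted(
        iv.onset for iv in intervals if not pd.isna(iv.onset)
    )
    off = series.offwrist
    days = []
    for iv in mains:
        if not iv.valid or iv.truncated:
            continue
        nxt = valid_mains.get(iv.cut_day + np.timedelta64(1, "D"))
        if nxt is not None:
            day_end, forced = nxt.onset, False
        else:
            day_end, forced = _forced_end(iv, all_onsets, series, off, params)
        length_h = float((day_end - iv.onset) / SECOND) / HOUR
        if length_h <= 0:
            continue
        cd = iv.cut_day
        days.append(
            {
                "participant_id": iv.participant_id,
                "cut_day": cd,
                "day_start": iv.onset,
                "day_end": day_end,
                "day_length_h": length_h,
                "forced_end": forced,
                "weekend_night": _weekday(cd) in (4, 5),        # Fri/Sat night
                "weekend_day": _weekday(cd + np.timedelta64(1, "D")) in (5, 6),
                "onset_mc_h": midnight_centered_hours(iv.onset, cd),
                "offset_h": float((iv.offset - _midnight(cd)) / SECOND) / HOUR,
                "sleep_offset": iv.offset,
                "duration_min": iv.duration_min,
                "sme_pct": iv.sme_pct,
            }
        )
    return days


def _forced_end(iv, all_onsets, series, off, params):
    """End-of-day instant when the terminating night's sleep is invalid:
    the first off-wrist run longer than one hour, or the first apparent
    sleep interval after this night's offset, whichever comes first."""
    t0 = iv.offset
    candidates = []
    j0 = series.index_of(t0)
    for rs, rl in _runs(off):
        if rs >= j0 and rl * EPOCH_S / 60.0 > 60.0:
            candidates.append(series.start + rs * EPOCH_S * SECOND)
            break
    nxt_onset = next((t for t in all_onsets if t > t0), None)
    if nxt_onset is not None:
        candidates.append(nxt_onset)
    if not candidates:
        return series.end, True
    return min(candidates), True


def _nap_windows(intervals, day) -> list[tuple]:
    """Scored sleep windows (naps or stray intervals) inside the wake
    portion of a day."""
    w0, w1 = day["sleep_offset"], day["day_end"]
    out = []
    for iv in intervals:
        if iv.truncated or iv.onset is None:
            continue
        if iv.offset > w0 and iv.onset < w1 and iv.onset >= day["day_start"]:
            if iv.onset != day["day_start"]:
                out.append((max(iv.onset, w0), min(iv.offset, w1)))
    return out


def merge_minutes(day: dict, minute_table: pd.DataFrame,
                  intervals: list[SleepInterval],
                  params: ScoringParams = DEFAULT_PARAMS) -> dict:
    """Daily MVPA and sedentary totals for the wake portion of a day.

    Sedentary-labeled minutes that overlap a scored daytime sleep interval
    (nap) by 30 s or more do not count toward sedentary time; MVPA minutes
    count wherever the classifier saw them.  Also computes the non-wear
    percentage of the wake portion (naps excluded from the denominator) and
    the physical-activity validity flag.
    """
    t = minute_table["minute_start"].to_numpy("datetime64[s]")
    # only minutes fully contained in the wake portion count; a minute
    # straddling the offset or the terminating onset belongs to sleep
    in_wake = (t >= day["sleep_offset"]) & (t + np.timedelta64(60, "s") <= day["day_end"])
    naps = _nap_windows(intervals, day)
    nap_overlap = np.zeros(len(t), bool)
    for a, b in naps:
        # a minute overlaps the nap by >=30 s iff its start is within
        # (a - 30 s, b - 30 s)
        nap_overlap |= (t > a - np.timedelta64(30, "s")) & (t < b - np.timedelta64(30, "s"))
    nw = minute_table["nonwear"].to_numpy(bool)
    cls = minute_table["class3"].to_numpy(object)
    mvpa = int(np.sum(in_wake & ~nw & (cls == "MVPA")))
    sed = int(np.sum(in_wake & ~nw & (cls == "sedentary") & ~nap_overlap))
    denom = int(np.sum(in_wake & ~nap_overlap))
    nonwear_pct = 100.0 * np.sum(in_wake & ~nap_overlap & nw) / denom if denom else np.nan
    return {"mvpa_min": mvpa, "sedentary_min": sed, "nonwear_pct": nonwear_pct}


def validate_pa_day(day: dict, nonwear_pct: float,
                    params: ScoringParams = DEFAULT_PARAMS) -> bool:
    """A physical-activity day is invalid when more than ``max_nonwear_frac``
    of its wake portion is non-wear, or when a force-ended day is shorter
    than ``min_forced_day_hours``."""
    if not np.isnan(nonwear_pct) and nonwear_pct > 100.0 * params.max_nonwear_frac:
        return False
    if day["forced_end"] and day["day_length_h"] < params.min_forced_day_hours:
        return False
    return True


def mvpa_cluster(day: dict, minute_table: pd.DataFrame,
                 params: ScoringParams = DEFAULT_PARAMS):
    """Densest MVPA cluster: slide a 120-min window at 1-min steps over the
    daytime span [sleep offset, next onset) and take the window holding the
    most MVPA minutes (ties break earliest).  Returns (midpoint instant,
    MVPA minutes in the window), or (NaT, nan) when the span is shorter than
    the window."""
    w = int(params.cluster_window_min)
    t = minute_table["minute_start"].to_numpy("datetime64[s]")
    in_day = (t >= day["sleep_offset"]) & (t + np.timedelta64(60, "s") <= day["day_end"])
    tt = t[in_day]
    if tt.size < w:
        return np.datetime64("NaT"), np.nan
    is_mvpa = (
        (minute_table["class3"].to_numpy(object) == "MVPA")
        & ~minute_table["nonwear"].to_numpy(bool)
    )[in_day].astype(int)
    sums = np.convolve(is_mvpa, np.ones(w, int), mode="valid")
    best = int(np.argmax(sums))  # argmax takes the earliest maximum
    count = int(sums[best])
    if params.cluster_midpoint == "centroid" and count > 0:
        inside = np.nonzero(is_mvpa[best: best + w])[0]
        mid = tt[best] + int(round(inside.mean() + 0.5)) * MIN_STEP
    else:
        mid = tt[best] + (w // 2) * MIN_STEP
    return mid, float(count)


def light_means(day: dict, series: WristEpochSeries, cluster_mid,
                params: ScoringParams = DEFAULT_PARAMS):
    """Mean white-light lux over worn wrist epochs in the daytime span and
    in the densest-MVPA-cluster window; missing when all off-wrist."""
    times = series.times()
    worn = ~series.offwrist
    day_mask = (times >= day["sleep_offset"]) & (times < day["day_end"]) & worn
    lux_day = float(series.lux[day_mask].mean()) if day_mask.any() else np.nan
    if pd.isna(cluster_mid):
        return lux_day, np.nan
    half = np.timedelta64(int(params.cluster_window_min * 30), "s")
    cmask = (times >= cluster_mid - half) & (times < cluster_mid + half) & worn
    lux_cluster = float(series.lux[cmask].mean()) if cmask.any() else np.nan
    return lux_day, lux_cluster


def build_person_days(intervals: list[SleepInterval], series: WristEpochSeries,
                      minute_table: pd.DataFrame,
                      params: ScoringParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Full day alignment for one participant."""
    rows = []
    for day in segment_days(intervals, series, params):
        totals = merge_minutes(day, minute_table, intervals, params)
        day.update(totals)
        day["valid_pa"] = validate_pa_day(day, totals["nonwear_pct"], params)
        mid, cmin = mvpa_cluster(day, minute_table, params)
        day["cluster_midpoint"] = mid
        day["cluster_mvpa_min"] = cmin
        day["lux_day_mean"], day["lux_cluster_mean"] = light_means(
            day, series, mid, params
        )
        rows.append(day)
    cols = ["participant_id", "cut_day", "day_start", "day_end", "day_length_h",
            "forced_end", "weekend_night", "weekend_day", "onset_mc_h", "offset_h",
            "sleep_offset", "duration_min", "sme_pct", "mvpa_min", "sedentary_min",
            "nonwear_pct", "valid_pa", "cluster_midpoint", "cluster_mvpa_min",
            "lux_day_mean", "lux_cluster_mean"]
    return pd.DataFrame(rows, columns=cols)


def filter_participants(person_days: pd.DataFrame,
                        params: ScoringParams = DEFAULT_PARAMS,
                        season: str = "all") -> pd.DataFrame:
    """Apply the cohort inclusion rules.

    Keeps participants with at least ``min_valid_sleep_days`` *consecutive*
    valid sleep days and at least ``min_valid_pa_days`` valid
    physical-activity days; the season filter keeps participants whose first
    valid day falls in September-May (``school_year``) or June-August
    (``summer``).
    """
    if season not in ("all", "school_year", "summer"):
        raise ValueError("season must be 'all', 'school_year' or 'summer'")
    keep = []
    for pid, g in person_days.groupby("participant_id", sort=True):
        days = np.sort(g["cut_day"].to_numpy("datetime64[D]"))
        if days.size == 0:
            continue
        # person-days exist only for valid sleep nights, so consecutiveness
        # is over their cut-day dates
        run = best = 1
        for i in range(1, days.size):
            run = run + 1 if days[i] - days[i - 1] == np.timedelta64(1, "D") else 1
            best = max(best, run)
        if best < params.min_valid_sleep_days:
            continue
        if int(g["valid_pa"].sum()) < params.min_valid_pa_days:
            continue
        month = int(str(days[0])[5:7])
        if season == "school_year" and month in (6, 7, 8):
            continue
        if season == "summer" and month not in (6, 7, 8):
            continue
        keep.append(pid)
    return person_days[person_days["participant_id"].isin(keep)].reset_index(drop=True)


def cluster_sample_strata(person_days: pd.DataFrame,
                          params: ScoringParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Participants averaging at least ``cluster_strata_min`` MVPA minutes
    in their daily densest cluster (exploratory stratification)."""
    means = person_days.groupby("participant_id")["cluster_mvpa_min"].mean()
    keep = means[means >= params.cluster_strata_min].index
    return person_days[person_days["participant_id"].isin(keep)].reset_index(drop=True)
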