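"""Rule-based sleep scoring of wrist epoch streams.

The scoring rules operate on 30-s epochs classified by a count threshold
(default 10): an epoch is *quiet* when worn with counts at or below the
threshold, *active* when worn above it, and off-wrist epochs are treated as
missing — they break quiet runs and can never anchor an onset or offset.

Sleep onset is the last active epoch followed by five consecutive quiet
epochs; sleep offset is the first active epoch that follows five consecutive
quiet epochs.  The published protocol had human scorers bracket candidate
rest periods before applying these rules; here an automatic wrapper finds
candidate rest periods from sustained immobility (runs of quiet epochs of at
least 20 min, merged across interruptions shorter than the one-hour
awakening rule) and applies the onset/offset rules inside each.

An awakening of at least one hour splits an interval into two; the interval
with the longest duration among those touching the 10 PM - 8 AM window of a
noon-to-noon cut-point day becomes that day's main sleep, the rest are naps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_PARAMS, EPOCH_S, ScoringParams
from .streams import SECOND, WristEpochSeries

_PAD = 20  # epochs of context kept around a rest period when scoring


@dataclass
class SleepInterval:
    """A scored sleep interval and its nightly metrics."""

    participant_id: str
    onset: np.datetime64
    offset: np.datetime64          # NaT when the recording ends mid-sleep
    duration_min: float
    sleep_min: float
    sme_pct: float                 # maintenance efficiency, 100 * sleep/duration
    role: str = "unassigned"       # main | nap | unassigned
    valid: bool = True
    reason: str = ""
    cut_day: object = None         # date of the noon-to-noon day owning it

    @property
    def truncated(self) -> bool:
        return pd.isna(self.offset)


def _epoch_classes(series: WristEpochSeries, params: ScoringParams):
    worn = ~series.offwrist
    quiet = worn & (series.counts <= params.count_threshold)
    active = worn & (series.counts > params.count_threshold)
    return quiet, active


def _all_quiet_runs(quiet: np.ndarray, k: int) -> np.ndarray:
    """allq[t] is True when quiet[t:t+k] are all quiet (False near the end)."""
    n = len(quiet)
    out = np.zeros(n, bool)
    if n >= k:
        c = np.cumsum(np.concatenate(([0], quiet.astype(np.int64))))
        out[: n - k + 1] = (c[k:] - c[:-k]) == k
    return out


def score_onset(series: WristEpochSeries, params: ScoringParams = DEFAULT_PARAMS,
                start: int = 0, stop: int | None = None):
    """Sleep onset within ``series[start:stop]``.

    Scans forward for the first active epoch immediately followed by
    ``quiet_run_epochs`` quiet epochs; returns its start time under the
    ``active`` convention, or the first quiet epoch's time under ``quiet``.
    Returns None when no qualifying pattern exists (including segments
    shorter than the pattern itself).
    """
    stop = len(series) if stop is None else stop
    quiet, active = _epoch_classes(series, params)
    k = params.quiet_run_epochs
    seg_q, seg_a = quiet[start:stop], active[start:stop]
    if len(seg_q) < k + 1:
        return None
    allq = _all_quiet_runs(seg_q, k)
    match = seg_a[:-1] & allq[1:]
    idx = np.nonzero(match)[0]
    if idx.size == 0:
        return None
    t = start + int(idx[0]) + (0 if params.onset_epoch == "active" else 1)
    return series.start + t * EPOCH_S * SECOND


def score_offset(series: WristEpochSeries, params: ScoringParams = DEFAULT_PARAMS,
                 start: int = 0, stop: int | None = None):
    """Sleep offset within ``series[start:stop]``: the last active epoch that
    is immediately preceded by ``quiet_run_epochs`` quiet epochs.  Returns
    None when the quiet tail is never broken."""
    stop = len(series) if stop is None else stop
    quiet, active = _epoch_classes(series, params)
    k = params.quiet_run_epochs
    seg_q, seg_a = quiet[start:stop], active[start:stop]
    if len(seg_q) < k + 1:
        return None
    allq = _all_quiet_runs(seg_q, k)
    match = np.zeros(len(seg_q), bool)
    match[k:] = seg_a[k:] & allq[:-k]
    idx = np.nonzero(match)[0]
    if idx.size == 0:
        return None
    return series.start + (start + int(idx[-1])) * EPOCH_S * SECOND


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs."""
    if mask.size == 0:
        return np.empty((0, 2), int)
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends - starts])


def find_rest_periods(series: WristEpochSeries,
                      params: ScoringParams = DEFAULT_PARAMS):
    """Candidate rest periods as (start_epoch, end_epoch) index pairs.

    A core is a run of consecutive quiet epochs of at least
    ``rest_core_min`` minutes; cores merge while every contiguous non-quiet
    run between them is shorter than ``rest_merge_break_min`` minutes (the
    awakening-split threshold), so interruptions that would not split an
    interval do not fragment the rest period either.
    """
    quiet, _ = _epoch_classes(series, params)
    core_len = int(params.rest_core_min * 60 / EPOCH_S)
    break_len = int(params.rest_merge_break_min * 60 / EPOCH_S)
    qruns = _runs(quiet)
    if len(qruns) == 0:
        return []
    # regions are bounded by non-quiet runs at least break_len long; inside
    # a region every interruption is shorter than the awakening-split rule
    blocks = []
    region: list = []
    prev_end = None
    for s, ln in qruns:
        if prev_end is not None and s - prev_end >= break_len:
            blocks.append(region)
            region = []
        region.append((int(s), int(ln)))
        prev_end = s + ln
    blocks.append(region)
    out = []
    for region in blocks:
        total_quiet = sum(ln for _, ln in region)
        if total_quiet >= core_len:
            out.append((region[0][0], region[-1][0] + region[-1][1]))
    return out


def score_sleep_wake(series: WristEpochSeries, onset, offset,
                     params: ScoringParams = DEFAULT_PARAMS) -> np.ndarray:
    """Per-epoch sleep/wake labels for [onset, offset): True = sleep.

    An epoch is sleep when worn with counts at or below the threshold
    (off-wrist epochs count as wake — absence of evidence of sleep)."""
    i0, i1 = series.index_of(onset), series.index_of(offset)
    quiet, _ = _epoch_classes(series, params)
    return quiet[i0:i1]


def _make_interval(series, onset, offset, params) -> SleepInterval:
    if pd.isna(offset):
        return SleepInterval(series.participant_id, onset, np.datetime64("NaT"),
                             np.nan, np.nan, np.nan, valid=False, reason="truncated")
    duration = float((offset - onset) / SECOND) / 60.0
    asleep = score_sleep_wake(series, onset, offset, params)
    sleep_min = float(asleep.sum()) * EPOCH_S / 60.0
    sme = 100.0 * sleep_min / duration if duration > 0 else np.nan
    return SleepInterval(series.participant_id, onset, offset, duration, sleep_min, sme)


def split_intervals(series: WristEpochSeries, onset, offset,
                    params: ScoringParams = DEFAULT_PARAMS) -> list[SleepInterval]:
    """Split a scored interval at awakenings of at least ``split_wake_min``
    minutes; each piece is re-scored for its own onset and offset."""
    i0, i1 = series.index_of(onset), series.index_of(offset)
    asleep = score_sleep_wake(series, onset, offset, params)
    wake_runs = [
        r for r in _runs(~asleep)
        if r[1] >= params.split_wake_min * 60 / EPOCH_S
    ]
    if not wake_runs:
        return [_make_interval(series, onset, offset, params)]
    pieces, prev = [], i0
    for s, ln in wake_runs:
        pieces.append((prev, i0 + s))
        prev = i0 + s + ln
    pieces.append((prev, i1))
    out = []
    for ps, pe in pieces:
        if pe <= ps:
            continue
        lo, hi = max(0, ps - _PAD), min(len(series), pe + _PAD)
        on = score_onset(series, params, lo, hi)
        off = score_offset(series, params, lo, hi)
        if on is not None and off is not None and off > on:
            out.append(_make_interval(series, on, off, params))
    return out


def _cut_day(t: np.datetime64):
    """Date of the noon-to-noon cut-point day containing instant t."""
    return (np.datetime64(t, "s") - np.timedelta64(12, "h")).astype("datetime64[D]")


def select_main_sleep(intervals: list[SleepInterval],
                      params: ScoringParams = DEFAULT_PARAMS) -> SleepInterval | None:
    """Pick the main sleep among one cut-point day's intervals.

    Candidates must overlap the nighttime window (default 10 PM - 8 AM of
    the cut-point day).  The default compares candidates' *total* duration
    (``main_sleep_duration="total"``); ``"window"`` compares only the
    overlapping portion.  Ties break by larger overlap, then earlier onset.
    Returns None when no interval touches the window (invalid sleep day).
    """
    if not intervals:
        return None
    day = _cut_day(intervals[0].onset)
    w0 = day.astype("datetime64[s]") + np.timedelta64(params.main_window[0], "h")
    w1 = day.astype("datetime64[s]") + np.timedelta64(24 + params.main_window[1], "h")
    best, best_key = None, None
    for iv in intervals:
        end = iv.offset if not iv.truncated else iv.onset + np.timedelta64(1, "h")
        ov = (min(end, w1) - max(iv.onset, w0)) / SECOND
        ov = float(max(ov, 0.0))
        if ov <= 0:
            continue
        dur = ov / 60.0 if params.main_sleep_duration == "window" else (
            iv.duration_min if not iv.truncated else ov / 60.0
        )
        key = (dur, ov, -(iv.onset.astype("datetime64[s]").astype(np.int64)))
        if best is None or key > best_key:
            best, best_key = iv, key
    return best


def validate_sleep_day(series: WristEpochSeries, main: SleepInterval | None,
                       cut_day, is_first: bool, is_last: bool,
                       params: ScoringParams = DEFAULT_PARAMS) -> tuple[bool, str]:
    """Apply the off-wrist validity rules to one cut-point day.

    Invalid when (a) total off-wrist time reaches ``offwrist_invalid_min``
    (except the first and last recording days), (b) on the first day the
    device was worn less than ``first_day_wear_min`` before sleep onset, or
    (c) an off-wrist run of at least ``edge_offwrist_min`` starts or ends
    within ``edge_margin_min`` of the main sleep onset or offset.
    """
    if main is None:
        return False, "no_main_sleep"
    day0 = np.datetime64(cut_day, "s") + np.timedelta64(12, "h")
    day1 = day0 + np.timedelta64(24, "h")
    i0 = max(0, series.index_of(day0))
    i1 = min(len(series), max(series.index_of(day1), 0))
    off = series.offwrist
    off_min_total = float(off[i0:i1].sum()) * EPOCH_S / 60.0
    if not (is_first or is_last) and off_min_total >= params.offwrist_invalid_min:
        return False, "offwrist_total"
    if is_first:
        j = series.index_of(main.onset)
        worn_min = float((~off[:j]).sum()) * EPOCH_S / 60.0
        if worn_min < params.first_day_wear_min:
            return False, "first_day_wear"
    margin = params.edge_margin_min * 60.0
    edges = [main.onset]
    if not main.truncated:
        edges.append(main.offset)
    for rs, rl in _runs(off):
        if rl * EPOCH_S / 60.0 < params.edge_offwrist_min:
            continue
        t_start = series.start + rs * EPOCH_S * SECOND
        t_end = series.start + (rs + rl) * EPOCH_S * SECOND
        for b in (t_start, t_end):
            for edge in edges:
                if abs(float((b - edge) / SECOND)) <= margin:
                    return False, "offwrist_edge"
    return True, ""


def score_participant(series: WristEpochSeries,
                      params: ScoringParams = DEFAULT_PARAMS) -> list[SleepInterval]:
    """Score one wrist stream into labeled, validated sleep intervals."""
    n = len(series)
    intervals: list[SleepInterval] = []
    for bs, be in find_rest_periods(series, params):
        lo, hi = max(0, bs - _PAD), min(n, be + _PAD)
        onset = score_onset(series, params, lo, hi)
        offset = score_offset(series, params, lo, hi)
        if onset is None:
            continue
        if offset is None or offset <= onset:
            if hi >= n:  # recording ends during sleep: keep onset as anchor
                intervals.append(
                    SleepInterval(series.participant_id, onset, np.datetime64("NaT"),
                                  np.nan, np.nan, np.nan, valid=False,
                                  reason="truncated")
                )
            continue
        intervals.extend(split_intervals(series, onset, offset, params))
    for iv in intervals:
        iv.cut_day = _cut_day(iv.onset)
    days = sorted({iv.cut_day for iv in intervals})
    if not days:
        return []
    for d in days:
        todays = [iv for iv in intervals if iv.cut_day == d]
        main = select_main_sleep(todays, params)
        for iv in todays:
            iv.role = "main" if iv is main else "nap"
        ok, why = validate_sleep_day(
            series, main, d, is_first=(d == days[0]), is_last=(d == days[-1]), params=params
        )
        if main is not None and not main.truncated:
            main.valid, main.reason = ok, why
        elif main is not None:
            main.valid = False
    return intervals


def intervals_to_frame(intervals: list[SleepInterval]) -> pd.DataFrame:
    """One row per scored interval, ready to write as delimited text."""
    return pd.DataFrame(
        [
            {
                "participant_id": iv.participant_id,
                "date": iv.cut_day,
                "role": iv.role,
                "onset": iv.onset,
                "offset": iv.offset,
                "duration_min": iv.duration_min,
                "sleep_min": iv.sleep_min,
                "sme_pct": iv.sme_pct,
                "valid": iv.valid,
                "reason": iv.reason,
            }
            for iv in intervals
        ],
        columns=["participant_id", "date", "role", "onset", "offset",
                 "duration_min", "sleep_min", "sme_pct", "valid", "reason"],
    )
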