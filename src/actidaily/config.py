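"""Shared configuration objects.

All scoring thresholds are exposed as named fields of :class:`ScoringParams`
because they *are* the method: the count threshold that separates mobile from
immobile wrist epochs, the run lengths that define onset/offset, the non-wear
window geometry, and the validity cutoffs all change the scored output in
ways a user must be able to see and override.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScoringParams:
    """Thresholds and conventions for sleep scoring, activity processing and
    day alignment.

    Defaults implement the published rule set for wrist-scored adolescent
    sleep (30-s epochs) and hip-count activity processing (1-s epochs).

    Attributes
    ----------
    count_threshold : int
        Wrist epoch is "active" when its count exceeds this (default 10).
    quiet_run_epochs : int
        Number of consecutive quiet epochs that must follow (precede) the
        last (first) active epoch at sleep onset (offset); default 5.
    onset_epoch : str
        Which epoch's start time is reported as sleep onset: ``"active"``
        reports the last active epoch (the literal rule), ``"quiet"`` reports
        the first quiet epoch (immobility start); the two differ by 30 s.
    split_wake_min : float
        An awakening at least this long (minutes) splits a sleep interval in
        two (default 60).
    main_window : tuple
        Clock hours bounding the nighttime window used to pick the main
        sleep interval, default (22, 8) i.e. 10 PM - 8 AM.
    main_sleep_duration : str
        ``"total"`` compares each candidate interval's full duration
        (default); ``"window"`` compares only the portion inside the window.
    offwrist_invalid_min : float
        Total off-wrist minutes at or above which a (non-first/last) sleep
        day is invalid (default 240).
    first_day_wear_min : float
        Minimum worn minutes required before sleep onset on the first day
        (default 120).
    edge_offwrist_min : float
        An off-wrist run at least this long (default 60) ...
    edge_margin_min : float
        ... starting or ending within this many minutes (default 10) of the
        main sleep onset/offset invalidates the sleep day.
    rest_core_min : float
        Minimum run of consecutive quiet epochs (minutes) that seeds a
        candidate rest period (wrapper around the onset/offset rules; the
        published protocol used human scorers here).
    rest_merge_break_min : float
        Two rest cores merge into one candidate rest period when no
        contiguous non-quiet run between them reaches this length (minutes);
        default 60, matching the interval-splitting rule.
    nonwear_min : float
        Minimum length (minutes) of a hip non-wear interval (default 90).
    nonwear_spike_max : float
        Maximum length (minutes) of an interior nonzero spike tolerated
        inside a non-wear interval (default 2).
    nonwear_flank_min : float
        Consecutive zero minutes required on both sides of a tolerated spike
        (default 30).
    max_nonwear_frac : float
        A physical-activity day is invalid when the non-wear fraction of its
        wake portion exceeds this (default 0.25).
    min_forced_day_hours : float
        A forced-ended day shorter than this (default 20 h) is invalid.
    cluster_window_min : int
        Width of the sliding window for the densest-MVPA cluster (120 min).
    cluster_midpoint : str
        ``"window"`` (default) reports the center of the maximizing window;
        ``"centroid"`` reports the mean time of the MVPA minutes inside it.
    cluster_strata_min : float
        Participants averaging at least this many cluster MVPA minutes form
        the stratified subsample (default 10).
    min_valid_sleep_days : int
        Consecutive valid sleep days required for inclusion (default 3).
    min_valid_pa_days : int
        Valid physical-activity days required for inclusion (default 3).
    """

    count_threshold: int = 10
    quiet_run_epochs: int = 5
    onset_epoch: str = "active"
    split_wake_min: float = 60.0
    main_window: tuple = (22, 8)
    main_sleep_duration: str = "total"
    offwrist_invalid_min: float = 240.0
    first_day_wear_min: float = 120.0
    edge_offwrist_min: float = 60.0
    edge_margin_min: float = 10.0
    rest_core_min: float = 20.0
    rest_merge_break_min: float = 60.0
    nonwear_min: float = 90.0
    nonwear_spike_max: float = 2.0
    nonwear_flank_min: float = 30.0
    max_nonwear_frac: float = 0.25
    min_forced_day_hours: float = 20.0
    cluster_window_min: int = 120
    cluster_midpoint: str = "window"
    cluster_strata_min: float = 10.0
    min_valid_sleep_days: int = 3
    min_valid_pa_days: int = 3

    def __post_init__(self):
        if self.onset_epoch not in ("active", "quiet"):
            raise ValueError("onset_epoch must be 'active' or 'quiet'")
        if self.main_sleep_duration not in ("total", "window"):
            raise ValueError("main_sleep_duration must be 'total' or 'window'")
        if self.cluster_midpoint not in ("window", "centroid"):
            raise ValueError("cluster_midpoint must be 'window' or 'centroid'")

    def replace(self, **kw) -> "ScoringParams":
        return dataclasses.replace(self, **kw)


EPOCH_S = 30          # wrist epoch length, seconds
HIP_EPOCH_S = 1       # hip epoch length, seconds

DEFAULT_PARAMS = ScoringParams()
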