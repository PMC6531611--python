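"""Synthetic dual-device actigraphy cohorts with known ground truth.

The generator works in two stages:

1.  A *daily structural model* draws, for every participant and day, the true
    nightly sleep outcomes (midnight-centered onset, offset, maintenance
    efficiency) and daily activity totals (MVPA and sedentary minutes) from

        value = population mean + person intercept + weekend shift
                + coupling x (lagged predictor's within-person deviation)
                + AR(1) residual,

    so the within-person coupling coefficients and the day-to-day residual
    autocorrelation are known exactly.

2.  A *rendering* stage turns those daily truths into raw device streams:
    a 30-s wrist epoch series (counts, off-wrist flag, lux) in which sleep
    shows as sustained runs of counts <= 10 bracketed by active epochs, and
    a 1-s hip count series whose per-minute count texture differs by
    activity type so that minute classification is learnable but not
    trivial.  Optional naps, brief nocturnal arousals and injected non-wear
    gaps exercise the downstream splitting, efficiency and validity rules.

Stage 1 alone (``generate_daily_truth``) is cheap enough for large
parameter-recovery simulations; ``generate_cohort`` runs both stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .streams import SECOND, HipCountSeries, WristEpochSeries
from .config import EPOCH_S

MIN = np.timedelta64(60, "s")

#: sleep predictors are in hours (onset/offset) or percent (sme); activity
#: predictors are in minutes.  Couplings are outcome-units per predictor-unit.
DEFAULT_COUPLING = {
    "mvpa->onset": -0.005,
    "mvpa->offset": 0.001,
    "mvpa->sme": 0.01,
    "sedentary->onset": 0.005,
    "sedentary->offset": 0.003,
    "sedentary->sme": 0.002,
    "onset->mvpa": -0.39,
    "onset->sedentary": -9.54,
    "offset->mvpa": -3.70,
    "offset->sedentary": -11.67,
}

_SLEEP_VARS = ("onset", "offset", "sme")
_PA_VARS = ("mvpa", "sedentary")
_VALID_KEYS = {f"{p}->{s}" for p in _PA_VARS for s in _SLEEP_VARS} | {
    f"{s}->{p}" for s in _SLEEP_VARS + ("duration",) for p in _PA_VARS
}

RAW_CLASSES = ("sedentary", "light", "moderate-vigorous", "walking", "running")
MVPA_CLASSES = ("moderate-vigorous", "walking", "running")

# per-second hip count texture by activity type: (mean, AR(1) phi, innovation sd)
_HIP_TEXTURE = {
    "light": (12.0, 0.3, 10.0),
    "moderate-vigorous": (50.0, 0.5, 30.0),
    "walking": (35.0, 0.85, 6.0),
    "running": (80.0, 0.85, 12.0),
}
_SED_ZERO_P = 0.9       # P(second has zero counts) while sedentary / asleep
_SED_LAM = 3.0          # Poisson mean of the nonzero sedentary seconds


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating conditions for a synthetic cohort.

    Defaults emulate the descriptive statistics of a school-year adolescent
    cohort: mean sleep onset a few minutes after midnight, offset near 7:49,
    ~45 daily MVPA minutes and ~390 sedentary minutes, with weekend shifts
    taken from the fitted daily covariate effects.  Between-person SDs are
    free parameters chosen to give plausible total SDs (the source tables
    report no variance decomposition).
    """

    n_participants: int = 100
    n_days: int = 7
    seed: int = 0
    start_date: str = "2017-09-11"      # a Monday in September
    stagger_start: bool = True          # participant i starts (i mod 7) days later

    onset_mean: float = 4.0 / 60.0      # midnight-centered hours (00:04)
    onset_sd_between: float = 0.9
    offset_mean: float = 7.0 + 49.0 / 60.0   # hours since midnight (07:49)
    offset_sd_between: float = 0.9
    sme_mean: float = 90.9
    sme_sd_between: float = 2.0
    mvpa_daily_mean: float = 45.3
    mvpa_sd_between: float = 15.0
    sedentary_daily_mean: float = 390.0
    sedentary_sd_between: float = 60.0

    coupling: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    ar1_rho: float = 0.2
    resid_sd_by_outcome: dict = field(
        default_factory=lambda: {
            "onset": 0.6, "offset": 0.6, "sme": 1.8, "mvpa": 18.0, "sedentary": 65.0
        }
    )
    weekend_effects: dict = field(
        default_factory=lambda: {
            "onset": 0.93, "offset": 1.86, "sme": 0.0, "mvpa": -21.0, "sedentary": -18.0
        }
    )
    #: correlation of the onset/offset person intercepts and of their nightly
    #: residual innovations (late sleepers wake late; long nights end late).
    onset_offset_corr_between: float = 0.7
    onset_offset_corr_within: float = 0.5

    nonwear_rate: float = 0.0           # expected injected gaps per day
    nap_prob: float = 0.0               # P(nap) per day
    arousals: bool = True               # render brief nocturnal wake bouts

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_days < 3:
            raise ValueError(
                "n_days must be >= 3: shorter wear periods cannot satisfy the "
                ">=3-valid-day inclusion rule"
            )
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must lie in (-1, 1)")
        if any(v < 0 for v in self.resid_sd_by_outcome.values()):
            raise ValueError("residual SDs must be non-negative")
        for name in ("onset_sd_between", "offset_sd_between", "sme_sd_between",
                     "mvpa_sd_between", "sedentary_sd_between"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.nap_prob <= 1.0):
            raise ValueError("nap_prob must be a probability")
        if self.nonwear_rate < 0:
            raise ValueError("nonwear_rate must be non-negative")
        unknown = set(self.coupling) - _VALID_KEYS
        if unknown:
            raise ValueError(f"unknown coupling keys: {sorted(unknown)}")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``daily`` has one row per person-day (night-t sleep followed by day-t
    activity) plus one terminal row per participant holding only the closing
    night's sleep (its onset bounds the last day).  ``minute_labels`` and
    ``nonwear_windows`` are populated by the rendering stage.
    """

    daily: pd.DataFrame
    participants: pd.DataFrame
    coupling: dict
    minute_labels: pd.DataFrame | None = None
    nonwear_windows: pd.DataFrame | None = None


def _ar1_path(rng, n_p, n_t, rho, sd):
    """Stationary AR(1) residual paths, persons x time."""
    z = rng.standard_normal((n_p, n_t))
    e = np.empty((n_p, n_t))
    e[:, 0] = sd * z[:, 0]
    scale = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_t):
        e[:, t] = rho * e[:, t - 1] + scale * z[:, t]
    return e


def _corr_pair(rng, shape, corr):
    z1 = rng.standard_normal(shape)
    z2 = corr * z1 + np.sqrt(1.0 - corr**2) * rng.standard_normal(shape)
    return z1, z2


def generate_daily_truth(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the daily structural model only (no device streams).

    Returns ``(daily, participants)``; identical seed and config give
    identical output.
    """
    n_p, n_d = config.n_participants, config.n_days
    n_nights = n_d + 1
    rng = np.random.default_rng([config.seed, 0])
    c = {k: config.coupling.get(k, 0.0) for k in _VALID_KEYS}
    rho = config.ar1_rho
    rsd = config.resid_sd_by_outcome
    wk = config.weekend_effects

    # person intercepts; onset/offset correlated
    z_on, z_off = _corr_pair(rng, n_p, config.onset_offset_corr_between)
    u = {
        "onset": config.onset_sd_between * z_on,
        "offset": config.offset_sd_between * z_off,
        "sme": config.sme_sd_between * rng.standard_normal(n_p),
        "mvpa": config.mvpa_sd_between * rng.standard_normal(n_p),
        "sedentary": config.sedentary_sd_between * rng.standard_normal(n_p),
    }
    # configured means are marginal (what a cohort table reports); the
    # baseline absorbs the expected daily deviation, i.e. the weekend shift
    # (exactly 2/7 under staggered start weekdays) plus what the coupling
    # terms propagate from other outcomes' expected deviations (fixed point)
    wk_frac = 2.0 / 7.0
    ed = {k: wk_frac * wk[k] for k in ("onset", "offset", "sme", "mvpa", "sedentary")}
    for _ in range(4):
        nxt = {}
        for s in _SLEEP_VARS:
            nxt[s] = wk_frac * wk[s] + sum(
                c[f"{p}->{s}"] * ed[p] for p in _PA_VARS
            )
        for p in _PA_VARS:
            nxt[p] = wk_frac * wk[p] + sum(
                c[f"{s}->{p}"] * ed[s] for s in _SLEEP_VARS
            ) + c[f"duration->{p}"] * (ed["offset"] - ed["onset"]) * 60.0
        ed = nxt
    means = {
        "onset": config.onset_mean - ed["onset"],
        "offset": config.offset_mean - ed["offset"],
        "sme": config.sme_mean - ed["sme"],
        "mvpa": config.mvpa_daily_mean - ed["mvpa"],
        "sedentary": config.sedentary_daily_mean - ed["sedentary"],
    }

    # AR(1) residual paths; onset/offset innovations correlated
    zc1, zc2 = _corr_pair(rng, (n_p, n_nights), config.onset_offset_corr_within)
    e_on = np.empty((n_p, n_nights))
    e_off = np.empty((n_p, n_nights))
    for e_arr, z_arr, sd in ((e_on, zc1, rsd["onset"]), (e_off, zc2, rsd["offset"])):
        e_arr[:, 0] = sd * z_arr[:, 0]
        s = sd * np.sqrt(1.0 - rho**2)
        for t in range(1, n_nights):
            e_arr[:, t] = rho * e_arr[:, t - 1] + s * z_arr[:, t]
    e = {
        "onset": e_on,
        "offset": e_off,
        "sme": _ar1_path(rng, n_p, n_nights, rho, rsd["sme"]),
        "mvpa": _ar1_path(rng, n_p, n_d, rho, rsd["mvpa"]),
        "sedentary": _ar1_path(rng, n_p, n_d, rho, rsd["sedentary"]),
    }

    base = np.datetime64(config.start_date, "D")
    offsets = (np.arange(n_p) % 7) if config.stagger_start else np.zeros(n_p, int)
    start_dates = base + offsets.astype("timedelta64[D]")
    # weekend indicator for night t = evening date is Friday/Saturday;
    # the following day is then Saturday/Sunday, so one flag serves both.
    night_dates = start_dates[:, None] + np.arange(n_nights).astype("timedelta64[D]")
    dow = (night_dates.astype("datetime64[D]").view(np.int64) + 3) % 7  # 1970-01-01 is a Thursday
    weekend = (dow == 4) | (dow == 5)

    onset = np.empty((n_p, n_nights)); offset = np.empty((n_p, n_nights))
    sme = np.empty((n_p, n_nights))
    mvpa = np.empty((n_p, n_d)); sed = np.empty((n_p, n_d))
    dev = {k: None for k in ("onset", "offset", "mvpa", "sedentary")}

    for t in range(n_nights):
        d_on = e["onset"][:, t] + weekend[:, t] * wk["onset"]
        d_off = e["offset"][:, t] + weekend[:, t] * wk["offset"]
        d_sme = e["sme"][:, t] + weekend[:, t] * wk["sme"]
        if t > 0:
            for pa, arr in (("mvpa", dev["mvpa"]), ("sedentary", dev["sedentary"])):
                d_on += c[f"{pa}->onset"] * arr
                d_off += c[f"{pa}->offset"] * arr
                d_sme += c[f"{pa}->sme"] * arr
        onset[:, t] = np.clip(means["onset"] + u["onset"] + d_on, -6.0, 10.0)
        offset[:, t] = np.clip(
            means["offset"] + u["offset"] + d_off,
            onset[:, t] + 3.0,
            np.minimum(onset[:, t] + 14.0, 18.0),
        )
        sme[:, t] = np.clip(means["sme"] + u["sme"] + d_sme, 55.0, 100.0)
        # couplings act on the realized deviation from the person's latent
        # mean (weekend shift included) — the quantity a within-person
        # decomposition of the daily panel actually sees
        on_dev = onset[:, t] - means["onset"] - u["onset"]
        off_dev = offset[:, t] - means["offset"] - u["offset"]
        if t < n_d:
            for pa, arr in (("mvpa", mvpa), ("sedentary", sed)):
                d = e[pa][:, t] + weekend[:, t] * wk[pa]
                d += c[f"onset->{pa}"] * on_dev + c[f"offset->{pa}"] * off_dev
                d += c[f"duration->{pa}"] * (off_dev - on_dev) * 60.0
                d += c[f"sme->{pa}"] * (sme[:, t] - means["sme"] - u["sme"])
                arr[:, t] = np.clip(means[pa] + u[pa] + d, 0.0, 800.0)
        dev["onset"], dev["offset"] = on_dev, off_dev
        if t < n_d:
            dev["mvpa"] = mvpa[:, t] - means["mvpa"] - u["mvpa"]
            dev["sedentary"] = sed[:, t] - means["sedentary"] - u["sedentary"]

    pids = np.array([f"P{i:04d}" for i in range(n_p)])
    rows = []
    for t in range(n_nights):
        is_day = t < n_d
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pids,
                    "day_index": t,
                    "night_date": night_dates[:, t],
                    "weekend": weekend[:, t],
                    "onset_mc_h": onset[:, t],
                    "offset_h": offset[:, t],
                    "duration_min": (offset[:, t] - onset[:, t]) * 60.0,
                    "sme_pct": sme[:, t],
                    "mvpa_min": mvpa[:, t] if is_day else np.nan,
                    "sedentary_min": sed[:, t] if is_day else np.nan,
                }
            )
        )
    daily = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["participant_id", "day_index"])
        .reset_index(drop=True)
    )
    participants = pd.DataFrame(
        {"participant_id": pids, "start_date": start_dates}
        | {f"u_{k}": u[k] for k in u}
    )
    return daily, participants


# --- Table-1-style covariate marginals ------------------------------------

_COVARIATE_LEVELS = {
    "sex": (["Male", "Female"], [0.47, 0.53]),
    "race": (
        ["White, non-Hispanic", "Black, non-Hispanic", "Hispanic", "Other"],
        [0.15, 0.43, 0.28, 0.14],
    ),
    "mother_education": (
        ["Less than High School", "High School or Equivalent",
         "Some College/Technical School", "College or Graduate School"],
        [0.18, 0.19, 0.48, 0.15],
    ),
    "family_structure": (
        ["Biomother + Biofather", "Other Living Arrangements",
         "Biomother + New Partner", "Biomother Only"],
        [0.30, 0.09, 0.24, 0.37],
    ),
    "income_band": (
        ["<49%", "50-99%", "100-199%", "200-299%", ">=300%"],
        [0.13, 0.17, 0.28, 0.14, 0.28],
    ),
}


def generate_covariates(n_participants: int, seed: int) -> pd.DataFrame:
    """Participant covariate table with realistic category frequencies."""
    rng = np.random.default_rng([seed, 1])
    out = {"participant_id": [f"P{i:04d}" for i in range(n_participants)]}
    for name, (levels, probs) in _COVARIATE_LEVELS.items():
        out[name] = rng.choice(levels, size=n_participants, p=probs)
    out["age"] = np.round(rng.normal(15.5, 0.6, n_participants), 1)
    out["bmi_pct"] = np.round(np.clip(rng.normal(73.4, 25.1, n_participants), 1, 99), 1)
    return pd.DataFrame(out)


# --- rendering ------------------------------------------------------------


def _round_to_grid(t: np.datetime64, grid_start: np.datetime64) -> np.datetime64:
    k = round(float((t - grid_start) / SECOND) / EPOCH_S)
    return grid_start + int(k * EPOCH_S) * SECOND


def _hip_texture_counts(rng, label: str, n_sec: int) -> np.ndarray:
    if label in ("sedentary", "sleep"):
        nz = rng.random(n_sec) >= _SED_ZERO_P
        out = np.zeros(n_sec)
        out[nz] = rng.poisson(_SED_LAM, int(nz.sum()))
        return out
    mu, phi, sig = _HIP_TEXTURE[label]
    innov = rng.standard_normal(n_sec) * sig
    innov[0] = rng.standard_normal() * sig / np.sqrt(1 - phi**2)
    x = mu + lfilter([1.0], [1.0, -phi], innov)
    return np.clip(np.round(x), 0, None)


def _place_blocks(rng, free: np.ndarray, total: int, lo: int, hi: int) -> np.ndarray:
    """Mark ``total`` minutes inside the boolean free mask as occupied, in
    contiguous blocks of lo..hi minutes.  Returns chosen minute indices."""
    chosen = []
    remaining = total
    guard = 0
    while remaining > 0 and guard < 500:
        guard += 1
        blk = int(min(remaining, rng.integers(lo, hi + 1)))
        idx = np.nonzero(free)[0]
        if idx.size == 0:
            break
        s = int(rng.choice(idx))
        run = 0
        while run < blk and s + run < len(free) and free[s + run]:
            run += 1
        if run == 0:
            continue
        sel = np.arange(s, s + min(run, blk))
        free[sel] = False
        chosen.append(sel)
        remaining -= len(sel)
    return np.concatenate(chosen) if chosen else np.array([], dtype=int)


def _render_participant(cfg: SyntheticConfig, pid_idx: int, truth_rows: pd.DataFrame):
    """Render one participant's wrist and hip streams from daily truth.

    Returns (wrist, hip, updated truth rows, minute-label frame, gap list).
    """
    rng = np.random.default_rng([cfg.seed, 2, pid_idx])
    rows = truth_rows.sort_values("day_index").reset_index(drop=True)
    n_nights = len(rows)
    pid = rows["participant_id"].iloc[0]

    midnights = rows["night_date"].to_numpy("datetime64[D]").astype("datetime64[s]") + np.timedelta64(24 * 3600, "s")
    onset_c = midnights + np.round(rows["onset_mc_h"].to_numpy() * 3600).astype("timedelta64[s]")
    offset_c = midnights + np.round(rows["offset_h"].to_numpy() * 3600).astype("timedelta64[s]")

    # the recording ends 90 min into the terminal night: that night
    # contributes only its onset, which closes the last person-day
    start = np.datetime64(onset_c[0] - np.timedelta64(3, "h"), "m").astype("datetime64[s]")
    end = np.datetime64(onset_c[-1] + np.timedelta64(90, "m"), "m").astype("datetime64[s]")
    n_ep = int((end - start) / SECOND) // EPOCH_S
    onset_g = np.array([_round_to_grid(t, start) for t in onset_c])
    offset_g = np.array([_round_to_grid(t, start) for t in offset_c])

    # wrist baseline: daytime activity (never <= 10), daytime lux
    counts = 20 + rng.poisson(150.0, n_ep)
    lux = rng.gamma(2.0, 150.0, n_ep)
    sleep_mask = np.zeros(n_ep, bool)

    n_min = n_ep // 2
    labels = np.full(n_min, "light", dtype=object)

    def ep_idx(t):
        return int((t - start) / SECOND) // EPOCH_S

    nap_windows = []
    offset_g_rec = offset_g.copy()
    offset_g_rec[-1] = np.datetime64("NaT")  # terminal offset unobserved
    rows = rows.assign(
        onset_dt=onset_g, offset_dt=offset_g_rec,
        nap_start=np.datetime64("NaT", "s"), nap_end=np.datetime64("NaT", "s"),
        wake_min=0.0,
    )

    for t in range(n_nights):
        terminal = t == n_nights - 1
        i0 = ep_idx(onset_g[t])
        i1 = n_ep if terminal else ep_idx(offset_g[t])
        # epoch at onset stays active (the "last active epoch"); quiet after
        quiet = slice(i0 + 1, i1)
        nq = i1 - (i0 + 1)
        counts[quiet] = np.minimum(rng.poisson(1.2, nq), 10)
        lux[quiet] = rng.uniform(0, 3, nq)
        sleep_mask[i0:i1] = True
        if terminal:
            continue
        counts[i1] = 20 + rng.poisson(40.0)  # offset epoch: first active
        # nocturnal arousals realize the SME target
        dur_min = (i1 - i0) / 2.0
        if cfg.arousals:
            wake_target = max(0.0, dur_min * (1.0 - rows.loc[t, "sme_pct"] / 100.0) - 0.5)
            wake_ep = int(round(wake_target * 2))
            placed = 0
            attempts = 0
            taken = np.zeros(i1 - i0, bool)
            while placed < wake_ep and attempts < 200:
                attempts += 1
                blk = int(min(wake_ep - placed, rng.integers(2, 7)))
                lo, hi = 20, (i1 - i0) - 20 - blk   # >=10 min from both edges
                if hi <= lo:
                    break
                s = int(rng.integers(lo, hi))
                if taken[max(0, s - 6): s + blk + 6].any():
                    continue
                taken[s: s + blk] = True
                counts[i0 + s: i0 + s + blk] = 20 + rng.poisson(40.0, blk)
                placed += blk
            rows.loc[t, "wake_min"] = placed / 2.0

    # minute labels: sleep minutes -> sedentary texture; day minutes placed
    min_starts = start + np.arange(n_min).astype("timedelta64[m]").astype("timedelta64[s]")
    for t in range(n_nights):
        m0 = int((onset_g[t] - start) / MIN)
        if t == n_nights - 1:
            m1 = n_min
        else:
            m1 = -(-int((offset_g[t] - start) / SECOND) // 60)  # ceil
        labels[m0: min(m1, n_min)] = "sleep"

    for t in range(n_nights - 1):
        w0 = -(-int((offset_g[t] - start) / SECOND) // 60) + 2      # margin
        w1 = int((onset_g[t + 1] - start) / MIN) - 2
        if w1 - w0 < 60:
            continue
        free = np.zeros(n_min, bool)
        free[w0:w1] = True
        # nap first: a quiet wrist window, hip sedentary, excluded from truth totals
        if rng.random() < cfg.nap_prob:
            nap_len = int(rng.integers(30, 91))
            ns = w0 + int((w1 - w0) * rng.uniform(0.3, 0.6))
            ne = min(ns + nap_len, w1 - 1)
            if ne - ns >= 30:
                free[ns:ne] = False
                labels[ns:ne] = "sleep"
                nap_windows.append((t, min_starts[ns], min_starts[ne]))
                rows.loc[t, "nap_start"] = min_starts[ns]
                rows.loc[t, "nap_end"] = min_starts[ne]
                e0, e1 = ns * 2, ne * 2
                counts[e0:e1] = np.minimum(rng.poisson(1.2, e1 - e0), 10)
                counts[e0 - 1] = 20 + rng.poisson(40.0)
                counts[e1] = 20 + rng.poisson(40.0)
                sleep_mask[e0:e1] = True
        avail = int(free.sum())
        mv_total = int(np.clip(round(rows.loc[t, "mvpa_min"]), 0, avail // 2))
        mv_idx = _place_blocks(rng, free, mv_total, 5, 20)
        for s in np.split(mv_idx, np.nonzero(np.diff(mv_idx) > 1)[0] + 1):
            if s.size:
                labels[s] = rng.choice(MVPA_CLASSES, p=[0.4, 0.4, 0.2])
        sed_total = int(np.clip(round(rows.loc[t, "sedentary_min"]), 0, free.sum()))
        sed_idx = _place_blocks(rng, free, sed_total, 20, 60)
        labels[sed_idx] = "sedentary"
        rows.loc[t, "mvpa_min"] = float(len(mv_idx))
        rows.loc[t, "sedentary_min"] = float(len(sed_idx))

    # hip counts from minute labels, per contiguous same-label run
    hip = np.empty(n_min * 60)
    run_start = 0
    for i in range(1, n_min + 1):
        if i == n_min or labels[i] != labels[run_start]:
            hip[run_start * 60: i * 60] = _hip_texture_counts(
                rng, labels[run_start], (i - run_start) * 60
            )
            run_start = i

    offwrist = np.zeros(n_ep, bool)
    wrist = WristEpochSeries(pid, start, counts[: n_min * 2], offwrist[: n_min * 2], lux[: n_min * 2])
    hip_s = HipCountSeries(pid, start, hip)

    # injected non-wear gaps (both devices off together), daytime placement
    gaps = []
    if cfg.nonwear_rate > 0:
        for t in range(n_nights - 1):
            for _ in range(rng.poisson(cfg.nonwear_rate)):
                g_len = int(rng.integers(90, 181))
                w0 = -(-int((offset_g[t] - start) / SECOND) // 60) + 5
                w1 = int((onset_g[t + 1] - start) / MIN) - 5 - g_len
                if w1 <= w0:
                    continue
                gs = int(rng.integers(w0, w1))
                gaps.append((min_starts[gs], min_starts[gs] + g_len * MIN))
    if gaps:
        wrist, hip_s = inject_nonwear(wrist, gaps), inject_nonwear(hip_s, gaps)

    gap_mask = np.zeros(n_min, bool)
    for gs, ge in _merge_windows(gaps):
        gap_mask[int((gs - start) / MIN): int((ge - start) / MIN)] = True

    # realized daily totals after gap removal
    for t in range(n_nights - 1):
        w0 = -(-int((offset_g[t] - start) / SECOND) // 60)
        w1 = int((onset_g[t + 1] - start) / MIN)
        seg, gseg = labels[w0:w1], gap_mask[w0:w1]
        rows.loc[t, "mvpa_min"] = float(np.sum(np.isin(seg, MVPA_CLASSES) & ~gseg))
        napless = seg == "sedentary"
        rows.loc[t, "sedentary_min"] = float(np.sum(napless & ~gseg))

    minute_frame = pd.DataFrame(
        {
            "participant_id": pid,
            "minute_start": min_starts,
            "true_class": labels,
            "nonwear": gap_mask,
        }
    )
    return wrist, hip_s, rows, minute_frame, gaps


@dataclass
class Cohort:
    wrist: list
    hip: list
    covariates: pd.DataFrame
    truth: GroundTruth


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full synthetic cohort: device streams, covariates, truth."""
    daily, participants = generate_daily_truth(config)
    cov = generate_covariates(config.n_participants, config.seed)
    wrist, hip, frames, minutes, gap_rows = [], [], [], [], []
    for i, (pid, g) in enumerate(daily.groupby("participant_id", sort=True)):
        w, h, rows, mf, gaps = _render_participant(config, i, g)
        wrist.append(w)
        hip.append(h)
        frames.append(rows)
        minutes.append(mf)
        for gs, ge in gaps:
            gap_rows.append({"participant_id": pid, "start": gs, "end": ge})
    truth = GroundTruth(
        daily=pd.concat(frames, ignore_index=True),
        participants=participants,
        coupling=dict(config.coupling),
        minute_labels=pd.concat(minutes, ignore_index=True),
        nonwear_windows=pd.DataFrame(gap_rows, columns=["participant_id", "start", "end"]),
    )
    return Cohort(wrist=wrist, hip=hip, covariates=cov, truth=truth)


def training_minutes(n_per_class: int = 800, seed: int = 0):
    """Balanced labeled feature minutes for training the reference
    activity-type classifier.

    Draws ``n_per_class`` independent one-minute count windows per activity
    type from the same per-second texture model the cohort renderer uses,
    and summarizes each with the five percentiles and lag-one
    autocorrelation.  Returns ``(features, labels)``.
    """
    from .activity import _lag1  # texture features; no import cycle

    rng = np.random.default_rng([seed, 3])
    frames = []
    for label in RAW_CLASSES:
        x = np.stack([
            _hip_texture_counts(rng, label, 60) for _ in range(n_per_class)
        ]).astype(float)
        pct = np.percentile(x, [10, 25, 50, 75, 90], axis=1)
        frames.append(pd.DataFrame({
            "p10": pct[0], "p25": pct[1], "p50": pct[2], "p75": pct[3],
            "p90": pct[4], "lag1_autocorr": _lag1(x), "label": label,
        }))
    df = pd.concat(frames, ignore_index=True)
    return df.drop(columns="label"), df["label"].to_numpy()


def truth_minute_table(truth: GroundTruth, participant_id: str) -> pd.DataFrame:
    """Ground-truth minute labels in the processed-minute-table layout
    (``minute_start, raw_class, class3, nonwear``), for oracle comparisons
    that bypass the trained classifier."""
    t = truth.minute_labels
    g = t[t["participant_id"] == participant_id].reset_index(drop=True)
    cls3 = g["true_class"].map(
        {"sedentary": "sedentary", "light": "light", "sleep": "sedentary"}
    ).fillna("MVPA")
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "minute_start": g["minute_start"],
            "raw_class": g["true_class"].where(g["true_class"] != "sleep", "sedentary"),
            "class3": cls3,
            "nonwear": g["nonwear"],
        }
    )


def _merge_windows(windows):
    """Merge overlapping/touching (start, end) windows."""
    if not windows:
        return []
    ws = sorted((np.datetime64(a, "s"), np.datetime64(b, "s")) for a, b in windows)
    merged = [list(ws[0])]
    for a, b in ws[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def inject_nonwear(stream, windows):
    """Zero out the given time windows of a stream as device non-wear.

    Hip streams get zero counts; wrist streams additionally get the
    off-wrist flag set and lux zeroed.  Overlapping windows are merged.
    Windows must lie within the stream span.  Returns a modified copy.
    """
    merged = _merge_windows(windows)
    for a, b in merged:
        if a < stream.start or b > stream.end:
            raise ValueError(f"non-wear window {a}..{b} outside stream span")
    if isinstance(stream, WristEpochSeries):
        counts = stream.counts.copy()
        off = stream.offwrist.copy()
        lux = stream.lux.copy()
        for a, b in merged:
            i0, i1 = stream.index_of(a), -(-int((b - stream.start) / SECOND) // stream.epoch_s)
            counts[i0:i1] = 0
            lux[i0:i1] = 0.0
            off[i0:i1] = True
        return WristEpochSeries(stream.participant_id, stream.start, counts, off, lux)
    counts = stream.counts.copy()
    for a, b in merged:
        i0 = stream.index_of(a)
        i1 = -(-int((b - stream.start) / SECOND) // stream.epoch_s)
        counts[i0:i1] = 0
    return HipCountSeries(stream.participant_id, stream.start, counts)
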