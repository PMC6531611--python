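"""Epoch-stream containers and delimited-text I/O.

Both devices produce fixed-rate count streams, so a stream is stored as a
start instant plus dense arrays on an implicit grid (30-s wrist epochs,
1-s hip epochs).  This keeps a week of hip data (~600k samples) cheap while
the on-disk representation stays an explicit long-format delimited table:

wrist:  ``participant_id,timestamp,counts,offwrist,lux``
hip:    ``participant_id,timestamp,counts``

Timestamps are ISO-8601 naive local time; spacing must be exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EPOCH_S, HIP_EPOCH_S

SECOND = np.timedelta64(1, "s")


def _as_dt64(t) -> np.datetime64:
    return np.datetime64(pd.Timestamp(t), "s")


@dataclass
class WristEpochSeries:
    """Wrist device stream: 30-s epochs of activity counts, an off-wrist
    flag, and white-light lux."""

    participant_id: str
    start: np.datetime64
    counts: np.ndarray          # non-negative int
    offwrist: np.ndarray        # bool
    lux: np.ndarray             # non-negative float

    epoch_s: int = EPOCH_S

    def __post_init__(self):
        self.start = _as_dt64(self.start)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.offwrist = np.asarray(self.offwrist, dtype=bool)
        self.lux = np.asarray(self.lux, dtype=float)
        n = len(self.counts)
        if len(self.offwrist) != n or len(self.lux) != n:
            raise ValueError("counts, offwrist and lux must have equal length")
        if (self.counts < 0).any() or (self.lux < 0).any():
            raise ValueError("counts and lux must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> np.datetime64:
        return self.start + len(self) * self.epoch_s * SECOND

    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self)) * self.epoch_s * SECOND

    def index_of(self, t) -> int:
        """Index of the epoch containing instant ``t`` (floor)."""
        return int((_as_dt64(t) - self.start) // (self.epoch_s * SECOND))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "timestamp": self.times(),
                "counts": self.counts,
                "offwrist": self.offwrist.astype(int),
                "lux": self.lux,
            }
        )


@dataclass
class HipCountSeries:
    """Hip device stream: vertical-axis activity counts on 1-s epochs."""

    participant_id: str
    start: np.datetime64
    counts: np.ndarray

    epoch_s: int = HIP_EPOCH_S

    def __post_init__(self):
        self.start = _as_dt64(self.start)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> np.datetime64:
        return self.start + len(self) * self.epoch_s * SECOND

    def index_of(self, t) -> int:
        return int((_as_dt64(t) - self.start) // (self.epoch_s * SECOND))

    def minute_sums(self) -> tuple[np.datetime64, np.ndarray]:
        """Sum 1-s counts into full clock-aligned minutes.

        Returns the start of the first full minute and the per-minute sums;
        a partial trailing (or leading) minute is dropped.
        """
        first_min = np.datetime64(self.start, "m")
        if np.datetime64(first_min, "s") < self.start:
            first_min = first_min + np.timedelta64(1, "m")
        off = int((np.datetime64(first_min, "s") - self.start) // SECOND)
        usable = (len(self) - off) // 60
        body = self.counts[off : off + usable * 60]
        return np.datetime64(first_min, "s"), body.reshape(usable, 60).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        t = self.start + np.arange(len(self)) * self.epoch_s * SECOND
        return pd.DataFrame(
            {"participant_id": self.participant_id, "timestamp": t, "counts": self.counts}
        )


def _check_spacing(ts: np.ndarray, step_s: int, path: str) -> None:
    d = np.diff(ts.astype("datetime64[s]").astype(np.int64))
    bad = np.nonzero(d != step_s)[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"{path}: timestamps must be strictly increasing with constant "
            f"{step_s}-s spacing; violated at data row {i + 2} "
            f"(after {ts[i]})"
        )


def write_wrist(streams, path) -> None:
    """Write one or more wrist streams as delimited text."""
    frames = [s.to_frame() for s in ([streams] if isinstance(streams, WristEpochSeries) else streams)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_hip(streams, path) -> None:
    frames = [s.to_frame() for s in ([streams] if isinstance(streams, HipCountSeries) else streams)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_wrist(path) -> list[WristEpochSeries]:
    """Read a wrist delimited-text file into one stream per participant."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        ts = g["timestamp"].to_numpy(dtype="datetime64[s]")
        _check_spacing(ts, EPOCH_S, str(path))
        out.append(
            WristEpochSeries(
                participant_id=str(pid),
                start=ts[0],
                counts=g["counts"].to_numpy(),
                offwrist=g["offwrist"].to_numpy().astype(bool),
                lux=g["lux"].to_numpy(),
            )
        )
    return out


def read_hip(path) -> list[HipCountSeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        ts = g["timestamp"].to_numpy(dtype="datetime64[s]")
        _check_spacing(ts, HIP_EPOCH_S, str(path))
        out.append(
            HipCountSeries(
                participant_id=str(pid), start=ts[0], counts=g["counts"].to_numpy()
            )
        )
    return out
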