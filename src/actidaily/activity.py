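"""Hip count processing: non-wear detection, minute features, classification.

The hip device records vertical-axis counts on 1-s epochs.  Processing is
minute-based: counts are summed to clock-aligned 60-s windows for non-wear
detection, and each worn minute is summarized by five count percentiles and
the lag-one autocorrelation of its sixty 1-s counts, the feature set used by
count-based activity-type classifiers.  The published activity-type network
itself is not redistributable, so a reference classifier trained on
synthetic labeled minutes stands behind the same interface; any estimator
with ``predict`` over the six features can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .config import DEFAULT_PARAMS, ScoringParams
from .streams import HipCountSeries

log = logging.getLogger(__name__)

RAW_CLASSES = ("sedentary", "light", "moderate-vigorous", "walking", "running")
COLLAPSE = {
    "sedentary": "sedentary",
    "light": "light",
    "moderate-vigorous": "MVPA",
    "walking": "MVPA",
    "running": "MVPA",
}
FEATURE_COLS = ["p10", "p25", "p50", "p75", "p90", "lag1_autocorr"]


def nonwear_minutes(minute_sums: np.ndarray,
                    params: ScoringParams = DEFAULT_PARAMS) -> list[tuple[int, int]]:
    """Non-wear intervals over per-minute count sums, as [start, end) pairs.

    A non-wear interval is a run of zero-count minutes of at least
    ``nonwear_min`` minutes; interior nonzero spikes of at most
    ``nonwear_spike_max`` minutes are tolerated when immediately flanked on
    both sides by at least ``nonwear_flank_min`` consecutive zero minutes.
    """
    zero = np.asarray(minute_sums) == 0
    n = len(zero)
    if n == 0:
        return []
    # run-length encode
    runs = []          # (start, length, is_zero)
    s = 0
    for i in range(1, n + 1):
        if i == n or zero[i] != zero[s]:
            runs.append((s, i - s, bool(zero[s])))
            s = i
    out = []
    i = 0
    while i < len(runs):
        s0, ln, z = runs[i]
        if not z:
            i += 1
            continue
        end = s0 + ln
        j = i
        # absorb spike + next zero run while the spike is short and both
        # immediate flanks are long enough
        while (
            j + 2 < len(runs)
            and runs[j + 1][1] <= params.nonwear_spike_max
            and runs[j][1] >= params.nonwear_flank_min
            and runs[j + 2][1] >= params.nonwear_flank_min
        ):
            j += 2
            end = runs[j][0] + runs[j][1]
        if end - s0 >= params.nonwear_min:
            out.append((s0, end))
        i = j + 1
    return out


def detect_nonwear(series: HipCountSeries,
                   params: ScoringParams = DEFAULT_PARAMS):
    """Non-wear windows of a hip stream as (start, end) instants."""
    first_min, sums = series.minute_sums()
    step = np.timedelta64(1, "m")
    return [(first_min + s * step, first_min + e * step)
            for s, e in nonwear_minutes(sums, params)]


def _lag1(x2d: np.ndarray) -> np.ndarray:
    """Row-wise lag-one autocorrelation; 0 for zero-variance rows."""
    xc = x2d - x2d.mean(axis=1, keepdims=True)
    c0 = (xc * xc).sum(axis=1)
    c1 = (xc[:, :-1] * xc[:, 1:]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(c0 > 0, c1 / np.where(c0 > 0, c0, 1.0), 0.0)
    return r


def extract_features(series: HipCountSeries,
                     params: ScoringParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Per-minute count percentiles and lag-one autocorrelation.

    Percentiles use linear interpolation between order statistics.  Partial
    leading/trailing minutes are dropped (with a log notice).
    """
    first_min, sums = series.minute_sums()
    n_min = len(sums)
    off = int((first_min - series.start) / np.timedelta64(1, "s"))
    dropped = len(series) - n_min * 60
    if dropped:
        log.info("extract_features: dropped %d seconds of partial minutes", dropped)
    x = series.counts[off: off + n_min * 60].reshape(n_min, 60).astype(float)
    pct = np.percentile(x, [10, 25, 50, 75, 90], axis=1)
    return pd.DataFrame(
        {
            "minute_start": first_min + np.arange(n_min) * np.timedelta64(1, "m"),
            "p10": pct[0], "p25": pct[1], "p50": pct[2],
            "p75": pct[3], "p90": pct[4],
            "lag1_autocorr": _lag1(x),
        }
    )


@dataclass
class ReferenceClassifier:
    """Stand-in activity-type classifier: a small feed-forward network
    trained on synthetic labeled minutes, deterministic given its seed."""

    model: object
    classes_: tuple
    seed: int
    holdout_accuracy: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict(np.asarray(features[FEATURE_COLS], dtype=float))


def train_reference_classifier(features: pd.DataFrame, labels,
                               seed: int = 0,
                               holdout_frac: float = 0.2) -> ReferenceClassifier:
    """Train the reference minute classifier on labeled synthetic minutes.

    Requires all five activity classes to be present.  A random (seeded)
    holdout split reports generalization accuracy; rerunning with the same
    inputs and seed reproduces the model and its accuracy exactly.
    """
    y = np.asarray(labels)
    missing = set(RAW_CLASSES) - set(np.unique(y))
    if missing:
        raise ValueError(f"training data is missing classes: {sorted(missing)}")
    X = np.asarray(features[FEATURE_COLS], dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    n_hold = max(1, int(round(holdout_frac * len(y))))
    hold, train = perm[:n_hold], perm[n_hold:]
    model = make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=(16,), max_iter=600,
                      random_state=int(seed) & 0x7FFFFFFF),
    )
    model.fit(X[train], y[train])
    acc = float((model.predict(X[hold]) == y[hold]).mean())
    return ReferenceClassifier(model=model, classes_=RAW_CLASSES, seed=seed,
                               holdout_accuracy=acc)


def classify_minutes(features: pd.DataFrame, classifier,
                     nonwear_windows=(),
                     params: ScoringParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Label worn minutes with raw and collapsed activity classes.

    Minutes falling inside non-wear windows are removed from the output.
    A classifier emitting an unknown class is a hard error.
    """
    raw = np.asarray(classifier.predict(features))
    unknown = set(np.unique(raw)) - set(RAW_CLASSES)
    if unknown:
        raise ValueError(f"classifier produced unknown classes: {sorted(unknown)}")
    out = pd.DataFrame(
        {
            "minute_start": features["minute_start"].to_numpy(),
            "raw_class": raw,
            "class3": [COLLAPSE[c] for c in raw],
        }
    )
    keep = np.ones(len(out), bool)
    t = out["minute_start"].to_numpy("datetime64[s]")
    for a, b in nonwear_windows:
        keep &= ~((t >= np.datetime64(a, "s")) & (t < np.datetime64(b, "s")))
    return out[keep].reset_index(drop=True)


def process_hip(series: HipCountSeries, classifier,
                params: ScoringParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Full hip processing: non-wear detection, features, classification.

    Returns the minute table ``participant_id, minute_start, raw_class,
    class3, nonwear``; non-wear minutes are retained in this table (flagged)
    so downstream wear-percentage rules can see them, but carry no class.
    """
    windows = detect_nonwear(series, params)
    feats = extract_features(series, params)
    labeled = classify_minutes(feats, classifier, windows, params)
    table = pd.DataFrame(
        {
            "participant_id": series.participant_id,
            "minute_start": feats["minute_start"].to_numpy(),
        }
    )
    table = table.merge(labeled, on="minute_start", how="left")
    t = table["minute_start"].to_numpy("datetime64[s]")
    nw = np.zeros(len(table), bool)
    for a, b in windows:
        nw |= (t >= np.datetime64(a, "s")) & (t < np.datetime64(b, "s"))
    table["nonwear"] = nw
    return table
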