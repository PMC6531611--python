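"""End-to-end orchestration: generate/read -> score -> classify -> align -> model.

The pipeline writes a bundle of delimited-text artifacts (sleep intervals,
minute labels, person-days, per-model coefficient tables) plus a JSON
manifest echoing the configuration, seed and package versions so a run is
reproducible byte-for-byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import process_hip, train_reference_classifier
from .config import DEFAULT_PARAMS, ScoringParams
from .days import build_person_days, filter_participants
from .mlm import ModelFit, run_model_suite, scale_coefficient, suite_tables, VARIABLE_UNITS
from .sleep import intervals_to_frame, score_participant
from .streams import read_hip, read_wrist
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger(__name__)

_RUN_KEYS = {
    "synthetic", "wrist_path", "hip_path", "covariates_path", "season",
    "seed", "out_dir", "scoring", "classifier_train_minutes", "estimation",
    "covariate_adjustment",
}


@dataclass
class RunConfig:
    """Flat run configuration; unknown keys are rejected."""

    out_dir: str = "actidaily_run"
    seed: int = 0
    season: str = "all"
    synthetic: dict | None = None          # SyntheticConfig fields, or None
    wrist_path: str | None = None
    hip_path: str | None = None
    covariates_path: str | None = None
    scoring: dict = field(default_factory=dict)     # ScoringParams overrides
    classifier_train_minutes: int = 4000
    estimation: str = "ML"
    covariate_adjustment: str = "full"      # full | none

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _RUN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def params(self) -> ScoringParams:
        return DEFAULT_PARAMS.replace(**self.scoring)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def _train_classifier(config: RunConfig):
    """Train the reference activity classifier on balanced synthetic labeled
    minutes (the published network's weights are not redistributable)."""
    from .synthetic import training_minutes

    n_per_class = max(200, config.classifier_train_minutes // 5)
    X, y = training_minutes(n_per_class=n_per_class,
                            seed=(config.seed * 7919 + 13) % (2**31))
    return train_reference_classifier(X, y, seed=config.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and write the artifact bundle.

    Returns a dict of artifact paths and in-memory results.  On stage
    failure a :class:`PipelineError` carries the stage name; artifacts
    written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params()
    artifacts: dict = {"out_dir": str(out)}

    stage = "ingest"
    try:
        if config.synthetic is not None:
            syn = SyntheticConfig(**({"seed": config.seed} | dict(config.synthetic)))
            cohort = generate_cohort(syn)
            wrist, hip, covariates = cohort.wrist, cohort.hip, cohort.covariates
            artifacts["truth"] = cohort.truth
        else:
            if not (config.wrist_path and config.hip_path):
                raise ValueError("need wrist_path and hip_path (or synthetic)")
            wrist = read_wrist(config.wrist_path)
            hip = read_hip(config.hip_path)
            covariates = (
                pd.read_csv(config.covariates_path)
                if config.covariates_path else None
            )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    try:
        stage = "score-sleep"
        intervals = {w.participant_id: score_participant(w, params) for w in wrist}
        sleep_table = pd.concat(
            [intervals_to_frame(v) for v in intervals.values()], ignore_index=True
        )
        sleep_path = out / "sleep_intervals.csv"
        sleep_table.to_csv(sleep_path, index=False)
        artifacts["sleep_intervals"] = str(sleep_path)

        stage = "classify-activity"
        classifier = _train_classifier(config)
        minute_tables = {h.participant_id: process_hip(h, classifier, params) for h in hip}
        minutes = pd.concat(minute_tables.values(), ignore_index=True)
        minutes_path = out / "minute_labels.csv"
        minutes.to_csv(minutes_path, index=False)
        artifacts["minute_labels"] = str(minutes_path)
        artifacts["classifier_holdout_accuracy"] = classifier.holdout_accuracy

        stage = "align"
        wrist_by_id = {w.participant_id: w for w in wrist}
        pdays = pd.concat(
            [
                build_person_days(intervals[pid], wrist_by_id[pid],
                                  minute_tables[pid], params)
                for pid in sorted(intervals)
                if pid in minute_tables
            ],
            ignore_index=True,
        )
        pdays_path = out / "person_days.csv"
        pdays.to_csv(pdays_path, index=False)
        artifacts["person_days"] = str(pdays_path)

        analysis = filter_participants(pdays, params, season=config.season)
        analysis_path = out / "analysis_days.csv"
        analysis.to_csv(analysis_path, index=False)
        artifacts["analysis_days"] = str(analysis_path)
        artifacts["n_participants"] = int(analysis["participant_id"].nunique())
        if analysis.empty:
            log.warning("analysis set is empty after validity/season filters "
                        "(season=%s)", config.season)

        stage = "model"
        results: dict = {}
        if artifacts["n_participants"] >= 2:
            cov = covariates if config.covariate_adjustment == "full" else None
            results = run_model_suite(analysis, cov,
                                      estimation=config.estimation)
            for name, table in suite_tables(results).items():
                p = out / f"model_{name.replace('->', '_to_')}.csv"
                table.to_csv(p, index=False)
            artifacts["models"] = {
                k: (v if isinstance(v, ModelFit) else repr(v))
                for k, v in results.items()
            }

        stage = "manifest"
        cfg = config.to_dict()
        blob = json.dumps(cfg, sort_keys=True, default=str)
        manifest = {
            "package_version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "scoring_params": dataclasses.asdict(params),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        artifacts["manifest"] = str(out / "manifest.json")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return artifacts


_DESCRIPTIVE_ROWS = [
    ("Sleep Onset (time)", "onset_mc_h", "clock_midnight"),
    ("Sleep Offset (time)", "offset_h", "clock"),
    ("Sleep Duration (min)", "duration_min", "num"),
    ("Sleep Maintenance Efficiency (%)", "sme_pct", "num"),
    ("MVPA (min)", "mvpa_min", "num"),
    ("Sedentary Time (min)", "sedentary_min", "num"),
]


def _fmt_clock(hours: float) -> str:
    h = hours % 24.0
    return f"{int(h):02d}:{int(round((h - int(h)) * 60)) % 60:02d}"


def report(out_dir) -> str:
    """Human-readable summary of a bundle: descriptive statistics in the
    standard row order plus each model's headline within-person coefficient
    with its per-hour scaled effect.  Reads only bundle files."""
    out = Path(out_dir)
    analysis = pd.read_csv(out / "analysis_days.csv")
    lines = ["Cohort descriptives (valid person-days)", "=" * 42]
    if analysis.empty:
        return "no valid participants in the analysis set"
    n = analysis["participant_id"].nunique()
    lines.append(f"participants: {n}, person-days: {len(analysis)}")
    for label, col, kind in _DESCRIPTIVE_ROWS:
        x = analysis[col].dropna()
        m, s = float(x.mean()), float(x.std())
        if kind == "clock_midnight":
            lines.append(f"{label:38s} {_fmt_clock(m)} (SD {s:.2f} h)")
        elif kind == "clock":
            lines.append(f"{label:38s} {_fmt_clock(m)} (SD {s:.2f} h)")
        else:
            lines.append(f"{label:38s} {m:.1f} ({s:.1f})")
    model_files = sorted(out.glob("model_*.csv"))
    if model_files:
        lines += ["", "Within-person focal coefficients", "=" * 42]
        for mf in model_files:
            tab = pd.read_csv(mf)
            focal = tab[tab["term"].str.endswith("(within)")]
            if focal.empty:
                continue
            row = focal.iloc[0]
            pred, outcome = mf.stem.removeprefix("model_").split("_to_", 1)
            p_unit = VARIABLE_UNITS.get(pred, "minutes")
            o_unit = VARIABLE_UNITS.get(outcome, "minutes")
            if p_unit == "minutes":
                eff = scale_coefficient(row["B"], o_unit)
            else:  # predictor already per hour (or per percentage point)
                eff = row["B"] * (60.0 if o_unit == "hours" else 1.0)
            qual = "per hour" if p_unit in ("minutes", "hours") else "per point"
            suffix = "%" if o_unit == "percent" else "min"
            lines.append(
                f"{pred} -> {outcome}: B={row['B']:+.4f} (SE {row['SE']:.4f}, "
                f"p={row['p']:.3g}); {qual}: {eff:+.1f} {suffix}"
            )
    return "\n".join(lines)
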