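"""End-to-end pipeline: simulate -> score -> features -> train -> evaluate.

The PipelineConfig is a schema-checked mapping (unknown keys rejected) that
is embedded verbatim in every report, so a report can be regenerated from
its own metadata plus the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import evaluate as ev
from .features import extract_features, hourly_summary
from .io import write_features, write_hypnogram
from .scoring import (
    calibrate_thresholds,
    compute_epoch_metrics,
    smooth_microstates,
    threshold_score,
    ScoringThresholds,
)
from .synthetic import SimulationConfig, simulate_recording

log = logging.getLogger("remhf")

__all__ = ["PipelineConfig", "run_pipeline", "cohens_kappa"]

STAGES = ("simulate", "score", "features", "evaluate")


def cohens_kappa(y1, y2) -> float:
    """Chance-corrected agreement between two label sequences."""
    y1 = np.asarray(y1, dtype=object)
    y2 = np.asarray(y2, dtype=object)
    if len(y1) != len(y2):
        raise ValueError("label sequences differ in length")
    cats = sorted(set(y1.tolist()) | set(y2.tolist()), key=str)
    po = float(np.mean(y1 == y2))
    pe = sum(float(np.mean(y1 == c)) * float(np.mean(y2 == c)) for c in cats)
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def _check_keys(name: str, data: dict, allowed) -> dict:
    unknown = set(data) - set(allowed)
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    return dict(data)


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    seed: int = 0
    stage: str = "evaluate"
    simulation: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)  # {emg_rms, delta_power, theta_power} or {}
    features: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        sim_fields = {f.name for f in fields(SimulationConfig)}
        _check_keys("simulation", self.simulation, sim_fields)
        _check_keys("scoring", self.scoring,
                    {"emg_rms", "delta_power", "theta_power", "min_run_epochs",
                     "eeg_channel"})
        _check_keys("features", self.features,
                    {"channel", "artifact_threshold", "pad_ms",
                     "max_excised_fraction", "grubbs_alpha", "band_power_mode"})
        _check_keys("classifier", self.classifier,
                    {"method", "priors", "bandwidth", "k"})
        _check_keys("evaluation", self.evaluation,
                    {"n_shuffles", "train_fraction"})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = {f.name for f in fields(cls)}
        return cls(**_check_keys("pipeline", data, allowed))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stage": self.stage,
            "simulation": dict(self.simulation),
            "scoring": dict(self.scoring),
            "features": dict(self.features),
            "classifier": dict(self.classifier),
            "evaluation": dict(self.evaluation),
            "log_level": self.log_level,
        }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the configured stages and return (and optionally write) a report.

    Deterministic in ``config.seed``; every stage logs its parameters.
    """
    report: dict = {"config": config.to_dict(), "seed": config.seed}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    sim_kwargs = dict(config.simulation)
    sim_kwargs["seed"] = config.seed
    sim_cfg = SimulationConfig(**sim_kwargs)
    log.info("simulate: %d epochs, seed %d", sim_cfg.n_epochs, config.seed)
    recording, truth, artifact_times = simulate_recording(sim_cfg)
    report["simulate"] = {
        "n_epochs": len(truth),
        "state_fractions": {s.value: f for s, f in truth.fractions().items()},
        "n_artifacts": len(artifact_times),
    }
    if out is not None:
        write_hypnogram(truth, out / "hypnogram_truth.csv")
    if config.stage == "simulate":
        return _finish(report, out)

    sc = dict(config.scoring)
    min_run = int(sc.pop("min_run_epochs", 3))
    eeg_channel = sc.pop("eeg_channel", "eeg_v1")
    metrics = compute_epoch_metrics(recording, sim_cfg.epoch_seconds,
                                    eeg_channel=eeg_channel)
    if sc:
        thresholds = ScoringThresholds(**sc)
    else:
        thresholds = calibrate_thresholds(metrics, truth)
    scored = smooth_microstates(threshold_score(metrics, thresholds), min_run)
    kappa = cohens_kappa(scored.labels, truth.labels)
    log.info("score: kappa vs ground truth %.3f", kappa)
    report["score"] = {
        "thresholds": {"emg_rms": thresholds.emg_rms,
                       "delta_power": thresholds.delta_power,
                       "theta_power": thresholds.theta_power},
        "kappa_vs_truth": kappa,
        "accuracy_vs_truth": float(np.mean(scored.labels == truth.labels)),
    }
    if out is not None:
        write_hypnogram(scored, out / "hypnogram_scored.csv")
    if config.stage == "score":
        return _finish(report, out)

    feat_kwargs = dict(config.features)
    channel = feat_kwargs.pop("channel", "eeg_v1")
    fm = extract_features(recording, scored, channel=channel, **feat_kwargs)
    report["features"] = {
        "n_epochs": fm.n_epochs,
        "n_dropped": len(fm.dropped_epochs),
        "n_outliers": int(fm.outlier_mask.sum()),
        "channel": channel,
    }
    if out is not None:
        write_features(fm, out / "features.csv", out / "features_audit.json")
    if config.stage == "features":
        return _finish(report, out)

    spec = ev.ClassifierSpec(**config.classifier)
    eval_kwargs = dict(config.evaluation)
    X, y = ev.binary_wake_rem(fm)
    rep = ev.repeated_evaluation(X, y, spec, seed=config.seed, **eval_kwargs)
    report["evaluate"] = rep.to_dict()

    per_hour = int(round(3600.0 / sim_cfg.epoch_seconds))
    if len(scored) >= 3 * per_hour:  # correlations need >= 3 hourly bins
        import warnings

        hs = hourly_summary(fm, scored)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report["hourly_correlation"] = ev.hourly_correlation(hs)
    return _finish(report, out)


def _finish(report: dict, out) -> dict:
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
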