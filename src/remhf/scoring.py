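"""Threshold-based reference scoring of vigilance states.

Implements the semi-automated rules: per-epoch EMG RMS plus delta and theta
band power, manual thresholds deciding WAKE / NREM / REM, and absorption of
micro-states (runs shorter than 3 epochs) into the surrounding state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import band_average_power, epoch_band_powers, BandTable, segment_epochs
from .recording import Recording
from .states import Hypnogram, VigilanceState

__all__ = [
    "ScoringThresholds",
    "EpochMetrics",
    "compute_epoch_metrics",
    "threshold_score",
    "smooth_microstates",
    "calibrate_thresholds",
]

DELTA_BAND = (0.1, 4.0)
THETA_BAND = (4.0, 8.0)  # matches the feature table; rodent theta is often 6-9


@dataclass(frozen=True)
class ScoringThresholds:
    """Manual thresholds on EMG RMS, delta power and theta power."""

    emg_rms: float
    delta_power: float
    theta_power: float

    def __post_init__(self) -> None:
        if min(self.emg_rms, self.delta_power, self.theta_power) <= 0:
            raise ValueError("all scoring thresholds must be positive")


@dataclass
class EpochMetrics:
    """Per-epoch EMG RMS and delta/theta average power."""

    emg_rms: np.ndarray
    delta_power: np.ndarray
    theta_power: np.ndarray
    epoch_seconds: float = 4.0
    start_hour_of_day: float = 9.0

    def __post_init__(self) -> None:
        self.emg_rms = np.asarray(self.emg_rms, dtype=float)
        self.delta_power = np.asarray(self.delta_power, dtype=float)
        self.theta_power = np.asarray(self.theta_power, dtype=float)
        n = len(self.emg_rms)
        if len(self.delta_power) != n or len(self.theta_power) != n:
            raise ValueError("metric arrays must share one length")
        for name in ("emg_rms", "delta_power", "theta_power"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")

    def __len__(self) -> int:
        return len(self.emg_rms)


def compute_epoch_metrics(
    recording: Recording,
    epoch_seconds: float = 4.0,
    eeg_channel: str = "eeg_v1",
    delta_band=DELTA_BAND,
    theta_band=THETA_BAND,
) -> EpochMetrics:
    """EMG RMS plus delta/theta average power per epoch.

    Raises if the recording lacks an EMG-role channel or the requested EEG
    channel.
    """
    emg_name = recording.emg_channel()
    if eeg_channel not in recording.channels:
        raise ValueError(
            f"EEG channel {eeg_channel!r} not found in {list(recording.channels)}"
        )
    fs = recording.sampling_rate_hz
    emg_epochs = segment_epochs(recording.channels[emg_name], fs, epoch_seconds)
    emg_rms = np.sqrt(np.mean(emg_epochs**2, axis=1))
    eeg_epochs = segment_epochs(recording.channels[eeg_channel], fs, epoch_seconds)
    powers = epoch_band_powers(
        eeg_epochs, fs, BandTable((tuple(delta_band), tuple(theta_band)))
    )
    return EpochMetrics(emg_rms, powers[:, 0], powers[:, 1], epoch_seconds)


def threshold_score(
    metrics: EpochMetrics, thresholds: ScoringThresholds
) -> Hypnogram:
    """Apply the three decision rules per epoch.

    WAKE: EMG RMS at/above threshold. NREM: EMG below threshold and delta
    above threshold. REM: EMG below threshold, delta below threshold, theta
    above threshold. Low-EMG epochs with neither delta nor theta evidence
    match no rule and are conservatively assigned WAKE (rule-gap epochs).
    """
    low_emg = metrics.emg_rms < thresholds.emg_rms
    high_delta = metrics.delta_power > thresholds.delta_power
    high_theta = metrics.theta_power > thresholds.theta_power
    codes = np.zeros(len(metrics), dtype=np.int8)  # default WAKE (incl. rule gap)
    codes[low_emg & high_delta] = 1
    codes[low_emg & ~high_delta & high_theta] = 2
    return Hypnogram.from_codes(
        codes, metrics.epoch_seconds, metrics.start_hour_of_day
    )


def smooth_microstates(hypnogram: Hypnogram, min_run_epochs: int = 3) -> Hypnogram:
    """Absorb state runs shorter than ``min_run_epochs`` into the preceding
    surviving state (a leading short run takes the following state).

    Idempotent; the output contains no run shorter than the minimum unless
    the whole sequence is a single shorter run.
    """
    if min_run_epochs < 1:
        raise ValueError("min_run_epochs must be >= 1")
    codes = hypnogram.codes.copy()
    n = len(codes)
    # run-length encode
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [n]]))
    runs = list(zip(codes[starts].tolist(), lengths.tolist()))

    merged: list[list] = []  # surviving [code, length] runs
    pending = 0  # leading short-run epochs waiting for the first surviving state
    for code, length in runs:
        if length < min_run_epochs:
            if merged:
                merged[-1][1] += length  # absorb into the previous surviving run
            else:
                pending += length  # leading short run takes the following state
            continue
        if merged and merged[-1][0] == code:
            merged[-1][1] += length
        else:
            merged.append([code, length + pending])
            pending = 0
    if not merged:
        # no run reaches the minimum: collapse to the majority label
        vals, counts = np.unique(codes, return_counts=True)
        merged = [[int(vals[np.argmax(counts)]), n]]
        pending = 0
    if pending:
        merged[-1][1] += pending

    out = np.concatenate([np.full(L, c, dtype=np.int8) for c, L in merged])
    assert len(out) == n
    return Hypnogram.from_codes(out, hypnogram.epoch_seconds, hypnogram.start_hour_of_day)


def calibrate_thresholds(metrics: EpochMetrics, hypnogram: Hypnogram) -> ScoringThresholds:
    """Midpoints of class-conditional metric means on labelled data.

    Convenience helper (not part of the original scoring procedure, which
    used manually chosen thresholds): EMG threshold midway between wake and
    sleep means, delta threshold midway between NREM and non-NREM means,
    theta threshold midway between REM and NREM means.
    """
    if len(metrics) != len(hypnogram):
        raise ValueError("metrics and hypnogram lengths differ")
    c = hypnogram.codes
    wake, nrem, rem = c == 0, c == 1, c == 2
    if not (wake.any() and nrem.any() and rem.any()):
        raise ValueError("calibration needs every state present")
    emg_thr = 0.5 * (metrics.emg_rms[wake].mean() + metrics.emg_rms[~wake].mean())
    delta_thr = 0.5 * (metrics.delta_power[nrem].mean() + metrics.delta_power[~nrem].mean())
    theta_thr = 0.5 * (metrics.theta_power[rem].mean() + metrics.theta_power[nrem].mean())
    return ScoringThresholds(emg_thr, delta_thr, theta_thr)
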