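"""Text-format I/O: hypnogram CSV, feature table CSV, YAML configs."""

from __future__ import annotations

import json
import re

import numpy as np
import pandas as pd
import yaml

from .features import BandTable, FeatureMatrix
from .states import Hypnogram, parse_state

__all__ = [
    "write_hypnogram",
    "read_hypnogram",
    "write_features",
    "read_features",
    "load_yaml",
    "dump_yaml",
]

HYPNO_COLUMNS = ["epoch_index", "start_time_s", "state"]


def write_hypnogram(hypnogram: Hypnogram, path) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(len(hypnogram)),
        "start_time_s": np.arange(len(hypnogram)) * hypnogram.epoch_seconds,
        "state": [s.value for s in hypnogram.labels],
    })
    df.to_csv(path, index=False)


def read_hypnogram(path, start_hour_of_day: float = 9.0) -> Hypnogram:
    df = pd.read_csv(path)
    if list(df.columns) != HYPNO_COLUMNS:
        raise ValueError(
            f"hypnogram CSV must have columns {HYPNO_COLUMNS}, got {list(df.columns)}"
        )
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        gap = int(np.flatnonzero(idx != np.arange(len(df)))[0])
        raise ValueError(f"epoch_index not contiguous from 0 at row {gap}")
    labels = []
    for row, token in enumerate(df["state"]):
        try:
            labels.append(parse_state(token))
        except ValueError as exc:
            raise ValueError(f"row {row}: {exc}") from None
    if len(df) > 1:
        eps = float(df["start_time_s"].iloc[1] - df["start_time_s"].iloc[0])
    else:
        eps = 4.0
    return Hypnogram(labels, eps, start_hour_of_day)


def write_features(features: FeatureMatrix, path, sidecar_path=None) -> None:
    """Feature table CSV (one band column per band) + JSON audit sidecar."""
    df = pd.DataFrame(features.values, columns=features.bands.names)
    df.insert(0, "epoch_index", features.epoch_indices)
    df.insert(1, "state", [s.value for s in features.labels])
    df.insert(2, "channel", features.channel_name)
    df.to_csv(path, index=False)
    if sidecar_path is not None:
        audit = {
            "channel": features.channel_name,
            "zscored": bool(features.zscored),
            "n_epochs": int(features.n_epochs),
            "dropped_epochs": [int(i) for i in features.dropped_epochs],
            "outliers_per_band": {
                name: int(features.outlier_mask[:, j].sum())
                for j, name in enumerate(features.bands.names)
            },
        }
        with open(sidecar_path, "w") as fh:
            json.dump(audit, fh, indent=2)


_BAND_RE = re.compile(r"^([0-9.]+)-([0-9.]+)Hz$")


def read_features(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    band_cols = [c for c in df.columns if _BAND_RE.match(c)]
    if not band_cols:
        raise ValueError(f"no band columns found in {path}")
    bands = BandTable(tuple(
        (float(m.group(1)), float(m.group(2)))
        for m in (_BAND_RE.match(c) for c in band_cols)
    ))
    labels = [parse_state(s) for s in df["state"]]
    channel = str(df["channel"].iloc[0]) if "channel" in df else ""
    return FeatureMatrix(
        df[band_cols].to_numpy(dtype=float),
        labels,
        bands,
        channel_name=channel,
        zscored=True,
        epoch_indices=df["epoch_index"].to_numpy(dtype=int)
        if "epoch_index" in df else None,
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
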