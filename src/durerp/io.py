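"""File formats, configuration, and run metadata.

Event tables travel as BIDS-style tab-separated ``events.tsv`` (columns
``onset``/``duration``/``trial_type`` plus covariates, onsets in seconds).
Continuous signals are stored as raw little-endian float64 plus a JSON
sidecar holding the sampling rate and shape. Every output gets a sidecar
recording the config hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import Signal

REQUIRED_EVENT_COLUMNS = ("onset", "duration", "trial_type")


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv, validating schema and onsets."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} is missing required columns: {missing}")
    for col in ("onset", "duration"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row} of {path}"
            )
        df[col] = numeric
    onsets = df["onset"].to_numpy(float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"onsets in {path} are not strictly increasing")
    return df


def write_events(events: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write an events.tsv (9 significant digits; optional JSON sidecar)."""
    events.to_csv(path, sep="\t", index=False, float_format="%.9g")
    if meta is not None:
        write_sidecar(path, meta)


def write_signal(signal: Signal, path, meta: dict | None = None) -> None:
    """Raw little-endian float64 samples + JSON sidecar with shape and rate."""
    path = Path(path)
    signal.data.astype("<f8").tofile(path)
    sidecar = {"sfreq": signal.sfreq, "n_channels": signal.n_channels,
               "n_samples": signal.n_samples, "dtype": "<f8"}
    if meta:
        sidecar.update(meta)
    write_sidecar(path, sidecar)


def read_signal(path) -> Signal:
    path = Path(path)
    sidecar = json.loads(sidecar_path(path).read_text())
    data = np.fromfile(path, dtype="<f8")
    data = data.reshape(sidecar["n_channels"], sidecar["n_samples"])
    return Signal(data, sidecar["sfreq"])


def sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_sidecar(path, meta: dict) -> None:
    sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True,
                                             default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def load_config(path) -> dict:
    """Load a YAML run config (flat mapping of sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping (for output provenance)."""
    canon = json.dumps(cfg, sort_keys=True, default=_json_default)
    return hashlib.sha1(canon.encode()).hexdigest()[:12]
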