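"""CSV / YAML round-tripping with provenance headers.

Every table the pipeline writes carries a comment header recording the run
seed and a hash of the run configuration, so any output file identifies
the run that produced it; readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, *, seed=None, cfg_hash=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_epochs(path) -> pd.DataFrame:
    """Epoch CSV: participant_id, timestamp (ISO-8601 minute), counts,
    wear (0/1), sleep (0/1)."""
    df = pd.read_csv(path, comment="#")
    required = {"participant_id", "timestamp", "counts", "wear", "sleep"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch file {path} missing columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def save_config(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
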