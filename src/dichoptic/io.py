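"""File formats: trial tables as CSV, configs and results as YAML.

The trial-table dialect is comma-separated UTF-8 with a header row and '.'
decimals; columns are observer, condition, target_eye, contrast, trial,
correct (0/1).  Results and configuration are human-readable YAML.  Every
command writes its resolved configuration next to its outputs so a run can be
reproduced from the artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRIAL_COLUMNS = ["observer", "condition", "target_eye", "contrast", "trial", "correct"]


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse trial table {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "trial"]
    if missing:
        raise ValueError(
            f"trial table {path} is missing required columns {missing}; "
            f"found {list(df.columns)}"
        )
    if df["correct"].isna().any():
        bad = int(df["correct"].isna().idxmax())
        raise ValueError(f"trial table {path}: missing 'correct' value at row {bad}")
    return df


def _plain(obj):
    """Recursively convert numpy / dataclass objects to YAML-friendly types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _plain(obj.to_dict(orient="records"))
    return obj


def write_yaml(data, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(data), fh, sort_keys=False)


def read_yaml(path):
    try:
        with open(path) as fh:
            return yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed YAML in {path}: {exc}") from exc


def write_field(field: np.ndarray, grid, path) -> None:
    """Export a (x, theta) field as CSV with axis headers."""
    df = pd.DataFrame(field, index=grid.x, columns=grid.theta)
    df.index.name = "x_deg"
    df.columns.name = "theta_deg"
    df.to_csv(path)


def write_run_config(path: Path, command: str, options: dict) -> None:
    """Record the resolved configuration of a run next to its outputs."""
    cfg = {"command": command, "options": _plain(options)}
    write_yaml(cfg, Path(path))
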