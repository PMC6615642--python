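"""CSV / JSON / YAML round-trips for trajectories, parameter records and chains."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def trajectory_frame(t, w, m) -> pd.DataFrame:
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    m = np.asarray(m, dtype=float)
    tot = w + m
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(tot > 0, m / np.maximum(tot, 1e-300), np.nan)
    return pd.DataFrame({"t": t, "w": w, "m": m, "h": h})


def write_trajectory(path, t, w, m) -> None:
    trajectory_frame(t, w, m).to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"t", "w", "m"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file lacks columns: {sorted(missing)}")
    return df


def params_to_dict(obj) -> dict:
    """Dataclass parameter record -> plain dict (field names as keys)."""
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            out[f.name] = params_to_dict(v) if dataclasses.is_dataclass(v) else v
        return out
    return obj


def write_params(path, obj) -> None:
    path = Path(path)
    data = params_to_dict(obj)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def read_params(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
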