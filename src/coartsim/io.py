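"""Trajectory CSV I/O with JSON sidecar metadata.

Schema: header ``t_ms,ch00,ch01,...``; one file per trial. The sidecar
``<name>.meta.json`` records intent/mode/seed so a trial file is
self-describing for the CLI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .primitives import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path,
                     meta: dict | None = None) -> None:
    path = Path(path)
    n_ch = traj.n_channels
    df = pd.DataFrame(traj.values, columns=[f"ch{j:02d}" for j in range(n_ch)])
    df.insert(0, "t_ms", traj.times)
    df.to_csv(path, index=False)
    payload = dict(traj.meta)
    if meta:
        payload.update(meta)
    sidecar_path(path).write_text(json.dumps(payload, indent=2, default=str))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    if "t_ms" not in df.columns:
        raise ValueError(f"{path} is not a trajectory CSV (missing t_ms column)")
    channels = [c for c in df.columns if c.startswith("ch")]
    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    return Trajectory(df["t_ms"].to_numpy(float),
                      df[channels].to_numpy(float), meta=meta)
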