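"""Result persistence: tidy trajectory CSVs, screen CSVs and run manifests."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ModelConfig
from .screen import SCREEN_COLUMNS
from .simulate import Trajectory

__all__ = [
    "trajectory_to_frame",
    "write_trajectory",
    "write_manifest",
    "read_screen_csv",
]


def trajectory_to_frame(traj: Trajectory, config: ModelConfig) -> pd.DataFrame:
    """Tidy long-format view of a trajectory.

    Columns: time, species_index (1-based), species_class
    (healthy/preleukemic), clone_index (1-based), abundance.
    """
    q, m = config.q, config.m
    n_t = len(traj.times)
    species = np.tile(np.arange(1, m + 1), n_t)
    return pd.DataFrame({
        "time": np.repeat(traj.times, m),
        "species_index": species,
        "species_class": np.where(species <= q, "healthy", "preleukemic"),
        "clone_index": (species - 1) % q + 1,
        "abundance": traj.states.ravel(),
    })


def write_trajectory(traj: Trajectory, config: ModelConfig, path: str | Path) -> Path:
    path = Path(path)
    trajectory_to_frame(traj, config).to_csv(path, index=False)
    return path


def write_manifest(path: str | Path, config: ModelConfig, **extra) -> Path:
    """JSON sidecar describing a run: full config, software version,
    timestamp, plus any run-specific fields (seed, convergence, grid...)."""
    payload = {
        "tniche_version": __version__,
        "python": platform.python_version(),
        "written_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
    }
    payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_screen_csv(path: str | Path) -> pd.DataFrame:
    """Read a screen CSV, validating the expected column set."""
    df = pd.read_csv(path)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen CSV {path} is missing columns: {missing}")
    for col in ("mono_converged", "poly_converged", "mono_premalignant",
                "poly_controlled", "consistent"):
        df[col] = df[col].astype(bool)
    return df
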