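"""CSV/JSON serialisation of runs, snapshots and sweeps."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterPartition
from .model import SimParams, Trajectory
from .reproduction import MateAssignment


def write_trajectory(traj: Trajectory, csv_path, params_path=None) -> None:
    """One row per generation, plus a JSON sidecar of parameters and seed."""
    csv_path = Path(csv_path)
    traj.to_frame().to_csv(csv_path, index=False)
    if params_path is None:
        params_path = csv_path.with_suffix(".json")
    payload = {
        "params": asdict(traj.params),
        "seed_used": traj.seed_used,
        "extinct": traj.extinct,
        "extinction_generation": traj.extinction_generation,
    }
    Path(params_path).write_text(json.dumps(payload, indent=2))


def write_snapshot(coords, path, partition: ClusterPartition | None = None, spanning_labels=None) -> None:
    """Per-organism snapshot: id, position, cluster label, spanning membership."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    n = len(coords)
    df = pd.DataFrame(
        {
            "organism_id": np.arange(n),
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
    if partition is not None:
        df["cluster_label"] = partition.labels
        spanning = spanning_labels or set()
        df["is_spanning_member"] = np.isin(partition.labels, list(spanning))
    df.to_csv(path, index=False)


def write_mate_assignment(mates: MateAssignment, path) -> None:
    pd.DataFrame(
        {
            "organism_id": np.arange(mates.n),
            "mate_id": mates.mate,
            "alternate_id": mates.alternate,
        }
    ).to_csv(path, index=False)


def read_points_csv(path) -> np.ndarray:
    """Read a 2-column (x, y) point set; header optional."""
    df = pd.read_csv(path)
    if {"x", "y"} <= set(df.columns):
        return df[["x", "y"]].to_numpy(dtype=float)
    raw = pd.read_csv(path, header=None)
    if raw.shape[1] < 2:
        raise ValueError("point CSV must have two columns (x, y)")
    try:
        return raw.iloc[:, :2].to_numpy(dtype=float)
    except ValueError:  # a non-numeric header row pandas kept as data
        return raw.iloc[1:, :2].to_numpy(dtype=float)


def write_manifest(path, params: SimParams | None = None, **extra) -> None:
    """JSON manifest of a run or sweep: parameters, seeds, package version."""
    from . import __version__

    payload = {"phenosim_version": __version__}
    if params is not None:
        payload["params"] = asdict(params)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
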