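"""Trajectory persistence and run manifests.

Trajectories are stored as a columnar NumPy ``.npz`` container (one array
per field) with the configuration embedded as a JSON string, plus an
optional human-readable CSV export (one row per frame and subsystem).
Every CLI run also writes a RunManifest recording the exact configuration,
seeds and analysis decisions needed to reproduce the output.
"""

from __future__ import annotations

import csv
import json
import platform
import zipfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .config import EnsembleConfig
from .soup import Trajectory

SCHEMA_VERSION = 1


class TrajectoryFormatError(IOError):
    """Raised when a trajectory container is truncated or from another schema."""


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        schema_version=np.int64(SCHEMA_VERSION),
        config_json=json.dumps(traj.config.to_dict()),
        times=traj.times,
        positions=traj.positions,
        velocities=traj.velocities,
        chem=traj.chem,
        kappa=traj.kappa,
        closed_mask=traj.closed_mask,
    )


def load_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as z:
            keys = set(z.files)
            required = {
                "schema_version",
                "config_json",
                "times",
                "positions",
                "velocities",
                "chem",
                "kappa",
                "closed_mask",
            }
            missing = required - keys
            if missing:
                raise TrajectoryFormatError(
                    f"{path} is not a trajectory container (missing: {sorted(missing)})"
                )
            version = int(z["schema_version"])
            if version != SCHEMA_VERSION:
                raise TrajectoryFormatError(
                    f"trajectory schema version {version} != supported {SCHEMA_VERSION}"
                )
            config = EnsembleConfig.from_dict(json.loads(str(z["config_json"])))
            return Trajectory(
                config=config,
                times=z["times"],
                positions=z["positions"],
                velocities=z["velocities"],
                chem=z["chem"],
                kappa=z["kappa"],
                closed_mask=z["closed_mask"].astype(bool),
            )
    except (ValueError, OSError, KeyError, zipfile.BadZipFile) as exc:
        if isinstance(exc, TrajectoryFormatError):
            raise
        raise TrajectoryFormatError(f"cannot read trajectory container {path}: {exc}") from exc


def export_csv(traj: Trajectory, path: str | Path) -> None:
    """Flat per-frame export: n_frames * n_subsystems rows."""
    path = Path(path)
    d = traj.positions.shape[2]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        header = (
            ["time", "subsystem"]
            + [f"pos_{ax}" for ax in range(d)]
            + [f"vel_{ax}" for ax in range(d)]
            + ["chem_1", "chem_2", "chem_3", "kappa", "closed"]
        )
        w.writerow(header)
        for f in range(traj.n_frames):
            t = traj.times[f]
            for i in range(traj.n):
                w.writerow(
                    [f"{t:.6g}", i]
                    + [f"{v:.9g}" for v in traj.positions[f, i]]
                    + [f"{v:.9g}" for v in traj.velocities[f, i]]
                    + [f"{v:.9g}" for v in traj.chem[f, i]]
                    + [f"{traj.kappa[i]:.9g}", int(traj.closed_mask[i])]
                )


@dataclass
class RunManifest:
    """Provenance of a CLI run: enough to reproduce its outputs exactly."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str]
    decisions: dict = field(default_factory=dict)
    software: str = field(
        default_factory=lambda: f"ergosoup 0.1.0 / numpy {np.__version__} / python {platform.python_version()}"
    )
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def manifest_path_for(output: str | Path) -> Path:
    output = Path(output)
    return output.with_name(output.stem + ".manifest.json")
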