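"""Lesion experiments: autopoiesis probed by functional closure.

A lesion renders every subsystem with a chosen blanket role (sensory,
active or internal) functionally closed: Newtonian interactions are
untouched, but the lesioned subsystems can no longer influence anyone's
electrochemical states.  If the spatial organization of the internal
states and their blanket is actively maintained — autopoiesis — closing
any part of the loop should let the arrangement decay and disperse
("oscillator death"), while an unlesioned control continued from the same
state with the same noise stays put.

Integrity is quantified by the mean distance of the internal-and-blanket
subsystems from their centroid: ``final_over_initial_dispersion`` near one
means the configuration was preserved; values well above one mean
dispersion.  ``extrusion_count`` counts internal subsystems that end up
beyond the median blanket radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .blanket import BlanketPartition
from .config import EnsembleConfig
from .soup import EnsembleState, Trajectory, simulate

logger = logging.getLogger(__name__)

TARGETS = ("none", "sensory", "active", "internal")


@dataclass(frozen=True)
class LesionSpec:
    target: str = "none"
    duration: float = 512.0

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown lesion target {self.target!r}; expected one of {TARGETS}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")


@dataclass
class IntegrityReport:
    """Structural-integrity metrics of a continuation run."""

    target: str
    dispersion_series: np.ndarray       # mean centroid distance of internal + blanket
    extrusion_count: int
    final_over_initial_dispersion: float
    times: np.ndarray
    note: str = "dispersion >> 1 relative to control indicates oscillator death"

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "dispersion_series": self.dispersion_series.tolist(),
            "times": self.times.tolist(),
            "extrusion_count": self.extrusion_count,
            "final_over_initial_dispersion": self.final_over_initial_dispersion,
            "note": self.note,
        }


def apply_lesion(
    state: EnsembleState, partition: BlanketPartition, spec: LesionSpec
) -> EnsembleState:
    """Close every subsystem carrying the target label; nothing else changes.

    Idempotent: subsystems already closed stay closed.  ``target='none'``
    returns an identical copy (the control arm).
    """
    new = state.copy()
    if spec.target != "none":
        new.closed_mask = new.closed_mask | (partition.labels == spec.target)
    return new


def _dispersion_series(traj: Trajectory, members: np.ndarray) -> np.ndarray:
    pos = traj.positions[:, members, :]
    centroid = pos.mean(axis=1, keepdims=True)
    return np.linalg.norm(pos - centroid, axis=2).mean(axis=1)


def integrity_report(
    traj: Trajectory, partition: BlanketPartition, target: str
) -> IntegrityReport:
    """Integrity metrics of a (continuation) trajectory for a given partition."""
    members = np.concatenate([partition.internal, partition.blanket])
    disp = _dispersion_series(traj, members)
    pos_final = traj.positions[-1]
    centroid = pos_final[members].mean(axis=0)
    radii_internal = np.linalg.norm(pos_final[partition.internal] - centroid, axis=1)
    radii_blanket = np.linalg.norm(pos_final[partition.blanket] - centroid, axis=1)
    median_blanket = float(np.median(radii_blanket)) if radii_blanket.size else np.inf
    extrusion = int((radii_internal > median_blanket).sum())
    ratio = float(disp[-1] / disp[0]) if disp[0] > 0 else float("nan")
    return IntegrityReport(
        target=target,
        dispersion_series=disp,
        extrusion_count=extrusion,
        final_over_initial_dispersion=ratio,
        times=traj.times.copy(),
    )


def run_lesion_experiment(
    traj: Trajectory,
    partition: BlanketPartition,
    spec: LesionSpec,
    seed: int,
    config: EnsembleConfig | None = None,
) -> tuple[IntegrityReport, IntegrityReport, Trajectory, Trajectory]:
    """Continue from the trajectory's final state with and without the lesion.

    Both arms restart from the identical state and consume an identically
    seeded noise stream, so any divergence in the integrity metrics is
    attributable to the lesion alone.  Returns (lesion_report,
    control_report, lesion_trajectory, control_trajectory).
    """
    if config is None:
        config = traj.config
    start = traj.final_state()
    lesioned = apply_lesion(start, partition, spec)

    rng_l = np.random.default_rng(seed)
    rng_c = np.random.default_rng(seed)
    traj_l = simulate(config, initial_state=lesioned, duration=spec.duration, rng=rng_l)
    traj_c = simulate(config, initial_state=start, duration=spec.duration, rng=rng_c)
    rep_l = integrity_report(traj_l, partition, spec.target)
    rep_c = integrity_report(traj_c, partition, "none")
    logger.info(
        "lesion %s: dispersion ratio %.3f (control %.3f)",
        spec.target,
        rep_l.final_over_initial_dispersion,
        rep_c.final_over_initial_dispersion,
    )
    return rep_l, rep_c, traj_l, traj_c
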