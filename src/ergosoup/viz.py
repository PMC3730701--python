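"""Static figures: ensemble snapshots coloured by chemistry or blanket role."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .blanket import BlanketPartition
from .soup import EnsembleState, Trajectory

#: blanket-role colour scheme: hidden cyan, sensory magenta, active red, internal blue
ROLE_COLORS = {
    "external": "cyan",
    "sensory": "magenta",
    "active": "red",
    "internal": "blue",
}


def chem_to_rgb(chem: np.ndarray) -> np.ndarray:
    """Softmax of the three electrochemical states mapped to RGB.

    Equal states give neutral grey (1/3, 1/3, 1/3); dominance of one state
    saturates the corresponding channel.
    """
    z = chem - chem.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def plot_ensemble(
    obj: EnsembleState | Trajectory,
    path: str | Path,
    partition: BlanketPartition | None = None,
    frame: int = -1,
) -> Path:
    """Scatter the subsystem positions of a state (or trajectory frame).

    Colours follow the blanket-role scheme when a partition is given and an
    RGB softmax of the electrochemical states otherwise.
    """
    if isinstance(obj, Trajectory):
        positions = obj.positions[frame]
        chem = obj.chem[frame]
    else:
        positions = obj.positions
        chem = obj.chem
    fig, ax = plt.subplots(figsize=(6, 6))
    if partition is not None:
        for label, color in ROLE_COLORS.items():
            idx = partition.indices(label)
            ax.scatter(
                positions[idx, 0], positions[idx, 1], s=36, c=color, label=label, edgecolors="k",
                linewidths=0.3,
            )
        ax.legend(loc="upper right", fontsize=8)
    else:
        ax.scatter(
            positions[:, 0], positions[:, 1], s=36, c=chem_to_rgb(chem), edgecolors="k",
            linewidths=0.3,
        )
    ax.set_aspect("equal")
    ax.set_xlabel("x (length units)")
    ax.set_ylabel("y (length units)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
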