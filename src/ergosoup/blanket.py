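"""Markov blanket discovery from the ensemble's contact graph.

Because electrochemical influence is mediated by the same short-range
contacts as the physical interactions, the adjacency matrix of the ensemble
encodes its conditional-dependency structure.  The Markov blanket of a set
of nodes chi (children, parents and parents of children) is read off the
blanket matrix

    B = A + A^T + A^T A

whose row support collects exactly those three relations (column i of A
holds the directed edges from i to its children).  The principal
eigenvector of B is nonnegative on the dominant connected cluster
(Perron–Frobenius), so its k largest entries pick out the most densely
interconnected subsystems — the *internal* states.  Their blanket [B chi]
is then split into *sensory* states (blanket members influenced by some
external subsystem) and *active* states (the rest); everything else is
*external* (hidden).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .soup import Trajectory, contact_neighbors

logger = logging.getLogger(__name__)

LABELS = ("external", "sensory", "active", "internal")


class DegeneratePartitionError(ValueError):
    """Raised when no principal cluster exists (e.g. an empty blanket matrix)."""


@dataclass
class BlanketPartition:
    """Spectral partition of the ensemble into the four blanket roles."""

    labels: np.ndarray          # (n,) strings from LABELS
    chi: np.ndarray             # (n,) binary internal indicator
    A_window: np.ndarray        # (n, n) windowed adjacency that induced it
    B: np.ndarray               # (n, n) blanket matrix
    eigenvector: np.ndarray     # (n,) principal eigenvector of (B + B^T)/2
    k: int

    def indices(self, label: str) -> np.ndarray:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
        return np.flatnonzero(self.labels == label)

    @property
    def internal(self) -> np.ndarray:
        return self.indices("internal")

    @property
    def sensory(self) -> np.ndarray:
        return self.indices("sensory")

    @property
    def active(self) -> np.ndarray:
        return self.indices("active")

    @property
    def external(self) -> np.ndarray:
        return self.indices("external")

    @property
    def blanket(self) -> np.ndarray:
        """Sensory and active indices together."""
        return np.flatnonzero((self.labels == "sensory") | (self.labels == "active"))

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LABELS}

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "k": self.k,
            "counts": self.counts(),
            "internal": self.internal.tolist(),
            "sensory": self.sensory.tolist(),
            "active": self.active.tolist(),
            "external": self.external.tolist(),
        }


@dataclass
class BlanketReport:
    """Result of checking the defining conditional-independence structure."""

    violations: list[tuple[int, int]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return len(self.violations) == 0


def window_adjacency(traj: Trajectory, window: float) -> np.ndarray:
    """Element-wise OR of contact adjacency over the trailing ``window`` seconds.

    The contact graph fluctuates with the random motion; a pair counts as
    coupled if it was within the coupling radius on at least one saved frame
    of the window.
    """
    if window > traj.duration + 1e-9:
        raise ValueError(
            f"window ({window} s) exceeds trajectory duration ({traj.duration} s)"
        )
    t_start = traj.times[-1] - window
    sel = np.flatnonzero(traj.times >= t_start - 1e-9)
    A = np.zeros((traj.n, traj.n), dtype=np.int8)
    for f in sel:
        A |= contact_neighbors(
            traj.positions[f], traj.config.coupling_radius, traj.closed_mask
        )
    return (A > 0).astype(np.int8)


def blanket_matrix(A: np.ndarray) -> np.ndarray:
    """B = A + A^T + A^T A: children, parents and parents of children."""
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    Af = A.astype(np.float64)
    return Af + Af.T + Af.T @ Af


def principal_partition(A: np.ndarray, k: int) -> BlanketPartition:
    """Partition the ensemble by the principal eigenvector of the blanket matrix.

    Internal states are the k largest entries of the principal eigenvector
    (ties broken toward the lowest index, logged); their blanket [B chi] is
    split into sensory states — blanket members with an incoming edge in A
    from some external subsystem — and active states.  The remainder is
    external.
    """
    A = np.asarray(A)
    n = A.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the number of subsystems ({n})")
    B = blanket_matrix(A)
    if not B.any():
        raise DegeneratePartitionError("blanket matrix is identically zero: no principal cluster")
    # B is symmetric by construction; the symmetrization below is a recorded
    # no-op guard so the eigenproblem is always real.
    Bs = (B + B.T) / 2.0
    w, V = np.linalg.eigh(Bs)
    v = V[:, -1]
    # Perron sign convention: make the dominant component nonnegative
    if v.sum() < 0:
        v = -v
    comp = _component_of_support(Bs, v)
    if comp is not None:
        logger.warning(
            "blanket matrix is disconnected; using the component with the largest eigenvalue"
        )
    # k largest entries, ties to the lowest index: stable sort on (-v, index)
    order = np.lexsort((np.arange(n), -v))
    internal = np.sort(order[:k])
    if k < n and np.isclose(v[order[k - 1]], v[order[k]]):
        logger.info("eigenvector tie at rank k broken toward the lowest index")
    chi = np.zeros(n, dtype=np.int8)
    chi[internal] = 1
    bc = B @ chi
    blanket = np.flatnonzero((bc > 1e-12) & (chi == 0))
    labels = np.full(n, "external", dtype=object)
    labels[internal] = "internal"
    external_mask = np.ones(n, dtype=bool)
    external_mask[internal] = False
    external_mask[blanket] = False
    # sensory: blanket members influenced by (receiving an edge from) an external state
    for i in blanket:
        if A[i, external_mask].any():
            labels[i] = "sensory"
        else:
            labels[i] = "active"
    labels = labels.astype("U8")
    return BlanketPartition(labels=labels, chi=chi, A_window=A.copy(), B=B, eigenvector=v, k=k)


def _component_of_support(Bs: np.ndarray, v: np.ndarray):
    """Return a note when the graph of Bs has several nontrivial components."""
    from scipy.sparse.csgraph import connected_components

    n_comp, lab = connected_components((Bs > 0).astype(np.int8), directed=False)
    sizes = np.bincount(lab)
    if (sizes > 1).sum() > 1:
        return lab
    return None


def verify_blanket(A: np.ndarray, partition: BlanketPartition) -> BlanketReport:
    """Check that no edge (in either direction) joins internal and external states."""
    A = np.asarray(A)
    internal = partition.internal
    external = partition.external
    violations = []
    for i in internal:
        for e in external:
            if A[i, e] or A[e, i]:
                violations.append((int(i), int(e)))
    report = BlanketReport(violations=violations, counts=partition.counts())
    if violations:
        logger.warning("blanket verification failed: %d internal-external edges", len(violations))
    return report
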