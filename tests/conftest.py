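"""Shared fixtures: reduced-scale study runs used by several test modules.

The reduced study conditions are n=64 subsystems integrated for 512 s with
the shipped default force parameters, analysed with a 256 s adjacency
window and k=8 internal states — five seeds.  The five simulations are
expensive, so they are computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import ergosoup as es

STUDY_SEEDS = (1, 2, 3, 4, 5)
REDUCED_N = 64
REDUCED_DURATION = 512.0
WINDOW = 256.0
K_INTERNAL = 8


@pytest.fixture(scope="session")
def study_runs():
    """Five seeded reduced-scale runs with their window adjacency and partition."""
    runs = []
    for seed in STUDY_SEEDS:
        cfg = es.EnsembleConfig(
            n_subsystems=REDUCED_N, duration=REDUCED_DURATION, seed=seed
        )
        traj = es.simulate(cfg)
        A = es.window_adjacency(traj, WINDOW)
        part = es.principal_partition(A, K_INTERNAL)
        runs.append((traj, A, part))
    return runs


@pytest.fixture(scope="session")
def one_run():
    """A single reduced-scale run (kept independent of the 5-seed battery)."""
    cfg = es.EnsembleConfig(n_subsystems=REDUCED_N, duration=REDUCED_DURATION, seed=1)
    traj = es.simulate(cfg)
    A = es.window_adjacency(traj, WINDOW)
    part = es.principal_partition(A, K_INTERNAL)
    return traj, A, part


def brute_force_markov_blanket(A: np.ndarray, i: int) -> set[int]:
    """Set-based Markov blanket of node i in a digraph.

    Column j of A holds the edges from j, so A[c, i] = 1 means i -> c.
    The blanket is children ∪ parents ∪ parents-of-children, minus i.
    """
    n = A.shape[0]
    children = {c for c in range(n) if A[c, i]}
    parents = {p for p in range(n) if A[i, p]}
    parents_of_children = {p for c in children for p in range(n) if A[c, p]}
    return (children | parents | parents_of_children) - {i}
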