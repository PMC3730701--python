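"""The synthetic primordial soup.

An ensemble of n subsystems, each carrying structural states (position and
velocity in a d-dimensional Euclidean space) and three electrochemical
states evolving under Lorenz-form dynamics.  Subsystems couple only at
short range: two subsystems interact when they lie within ``coupling_radius``
of one another, so the instantaneous adjacency matrix — and hence the
statistical dependency structure of the whole ensemble — is itself a
function of position.

Electrochemical states follow a Lorenz system whose inputs are replaced by
the local average of the states of in-neighbours (self included), entering
the flow both linearly and through the nonlinear products, which makes the
effective Rayleigh parameter state- and neighbourhood-dependent and opens
the door to generalized synchronization.  Each subsystem has its own rate
constant kappa in (0, 1]; most are fast (kappa near one), a few slow.

Structural states obey Newtonian dynamics: a strong inverse-square
repulsion, a weaker attraction gated by the coherence of the third
electrochemical state (synchronized subsystems attract, incoherent ones
repel on balance), viscous drag, and a quadratic potential well that keeps
the soup together.  A random third of the subsystems are functionally
"closed": their electrochemical states cannot influence anyone else (their
column of the adjacency matrix is zeroed) although they still move, sense
and repel.

Integration is forward Euler–Maruyama with unit-variance Gaussian
increments scaled by sqrt(dt) on the velocity and electrochemical
equations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .config import EnsembleConfig

logger = logging.getLogger(__name__)

#: pairwise distances are clamped here to keep the inverse-square law finite
MIN_DISTANCE = 1e-6

#: width**2 scale of the coherence gate on the attractive force
COHERENCE_SCALE = 8.0


class IntegrationBlowUpError(RuntimeError):
    """Raised when the state leaves the finite range during integration."""

    def __init__(self, time: float, subsystem: int):
        self.time = time
        self.subsystem = subsystem
        super().__init__(
            f"non-finite state at t={time:.4f} s (first offending subsystem index {subsystem})"
        )


@dataclass
class EnsembleState:
    """Instantaneous state of the ensemble.

    positions, velocities : (n, d) arrays, length units and length/s
    chem                  : (n, 3) array of electrochemical states
    kappa                 : (n,) per-subsystem rate constants in (0, 1]
    closed_mask           : (n,) booleans, True for functionally closed
    time                  : seconds
    """

    positions: np.ndarray
    velocities: np.ndarray
    chem: np.ndarray
    kappa: np.ndarray
    closed_mask: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        for name in ("velocities", "chem", "kappa", "closed_mask"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} leading dimension must equal n={n}")
        if self.chem.shape[1] != 3:
            raise ValueError("chem must have exactly 3 columns")
        if not np.all(self.kappa > 0):
            raise ValueError("kappa must be strictly positive")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "EnsembleState":
        return EnsembleState(
            self.positions.copy(),
            self.velocities.copy(),
            self.chem.copy(),
            self.kappa.copy(),
            self.closed_mask.copy(),
            self.time,
        )


@dataclass
class Trajectory:
    """Saved frames of a simulation at ``save_interval`` spacing."""

    config: EnsembleConfig
    times: np.ndarray            # (F,)
    positions: np.ndarray        # (F, n, d)
    velocities: np.ndarray       # (F, n, d)
    chem: np.ndarray             # (F, n, 3)
    kappa: np.ndarray            # (n,)
    closed_mask: np.ndarray      # (n,)

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def final_state(self) -> EnsembleState:
        return EnsembleState(
            self.positions[-1].copy(),
            self.velocities[-1].copy(),
            self.chem[-1].copy(),
            self.kappa.copy(),
            self.closed_mask.copy(),
            float(self.times[-1]),
        )


def init_ensemble(config: EnsembleConfig, rng: np.random.Generator | None = None) -> EnsembleState:
    """Draw the initial ensemble state from the seeded generator.

    Positions, velocities and electrochemical states are standard normal.
    Rate constants are kappa = U**(1/4) with U uniform on (0, 1), giving a
    majority of fast subsystems and a thin tail of slow ones.  Exactly
    round(n * closed_fraction) subsystems, chosen uniformly at random, are
    flagged functionally closed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, d = config.n_subsystems, config.space_dim
    positions = rng.standard_normal((n, d))
    velocities = rng.standard_normal((n, d))
    chem = rng.standard_normal((n, 3))
    u = rng.uniform(0.0, 1.0, size=n)
    kappa = np.clip(u, 1e-12, None) ** 0.25
    n_closed = round(n * config.closed_fraction)
    closed_mask = np.zeros(n, dtype=bool)
    if n_closed > 0:
        closed_mask[rng.choice(n, size=n_closed, replace=False)] = True
    return EnsembleState(positions, velocities, chem, kappa, closed_mask, time=0.0)


def contact_neighbors(
    positions: np.ndarray,
    coupling_radius: float,
    closed_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary adjacency of electrochemical influence from current positions.

    A[i, j] = 1 iff i != j, the Euclidean distance between i and j is at
    most ``coupling_radius``, and j is not closed.  Column j encodes the
    directed influences *from* subsystem j to its children, so closing a
    subsystem zeroes its column while leaving its row (what it senses)
    intact.
    """
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    A = (d2 <= coupling_radius**2).astype(np.int8)
    np.fill_diagonal(A, 0)
    if closed_mask is not None:
        A[:, np.asarray(closed_mask, dtype=bool)] = 0
    return A


def local_averages(chem: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Local mean of chem over {i} and the in-neighbours of every i (rows of A)."""
    counts = 1.0 + A.sum(axis=1)
    return (chem + A @ chem) / counts[:, None]


def local_average(chem: np.ndarray, A: np.ndarray, i: int) -> np.ndarray:
    """Local mean of chem over subsystem i and its in-neighbours.

    The subsystem itself is included so the average is well defined for
    isolated subsystems.
    """
    return local_averages(chem, A)[i]


def electrochemical_flow(
    state: EnsembleState,
    A: np.ndarray,
    lorenz_params: tuple[float, float, float] = (10.0, 32.0, 8.0 / 3.0),
) -> np.ndarray:
    """Deterministic part of d(chem)/dt: coupled Lorenz-form dynamics.

    With xb the local average of in-neighbour states (self included) and
    (sigma, rho, beta) the Prandtl-, Rayleigh- and geometry-like parameters,
    subsystem i flows as

        kappa_i * [ sigma * (x_2 - x_1),
                    rho * xb_1 - x_2 - xb_1 * x_3,
                    xb_1 * x_2 - beta * x_3 ]

    The first state's local average replaces the first state wherever it
    drives the flow — linearly in the Rayleigh term and nonlinearly in the
    products — the substitution used to induce generalized synchronization;
    own-state damping is untouched, so the Lorenz trapping region survives
    coupling.  Relative to a subsystem with x_1 = xb_1, the coupling
    effectively rescales the Rayleigh parameter by xb_1 / x_1, making it
    state-dependent.  An isolated subsystem (xb = x) recovers the textbook
    Lorenz system scaled by kappa_i.
    """
    sigma, rho, beta = lorenz_params
    xb1 = local_averages(state.chem, A)[:, 0]
    x1, x2, x3 = state.chem[:, 0], state.chem[:, 1], state.chem[:, 2]
    flow = np.empty_like(state.chem)
    flow[:, 0] = sigma * (x2 - x1)
    flow[:, 1] = rho * xb1 - x2 - xb1 * x3
    flow[:, 2] = xb1 * x2 - beta * x3
    return state.kappa[:, None] * flow


def pairwise_forces(
    positions: np.ndarray,
    chem3: np.ndarray,
    repulsion_strength: float,
    attraction_strength: float,
    closed_mask: np.ndarray | None = None,
    coupling_radius: float = np.inf,
) -> np.ndarray:
    """Net pairwise force phi_i on every subsystem.

    Each ordered pair contributes, along the unit vector from j to i,

        repulsion_strength / d_ij**2
        - attraction_strength * g_ij * [reciprocally coupled] / d_ij

    with the coherence gate g_ij = exp(-(x3_i - x3_j)**2 / 8).  The
    inverse-square repulsion acts between all pairs; the weaker attraction
    is an electrochemical influence carried by the coupling, so it acts
    only between reciprocally coupled pairs — both within the coupling
    radius and both functionally open — and only when their third
    electrochemical states are coherent.  A closed subsystem can therefore
    never bind: it senses but is a purely repulsive body.  The reciprocity
    condition is symmetric in (i, j), so every pair contribution is exactly
    antisymmetric (Newton's third law).  Distances below ``MIN_DISTANCE``
    are clamped.
    """
    diff = positions[:, None, :] - positions[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, 1.0)  # placeholder; diagonal magnitude zeroed below
    d = np.sqrt(d2)
    np.clip(d, MIN_DISTANCE, None, out=d)
    dx3 = chem3[:, None] - chem3[None, :]
    gate = np.exp(-(dx3**2) / COHERENCE_SCALE)
    mutual = d <= coupling_radius
    if closed_mask is not None:
        open_ = ~np.asarray(closed_mask, dtype=bool)
        mutual &= open_[:, None] & open_[None, :]
    mag = repulsion_strength / (d * d) - attraction_strength * gate * mutual / d
    np.fill_diagonal(mag, 0.0)
    # force on i points from j towards i for positive magnitude (repulsion)
    return np.einsum("ij,ijk->ik", mag / d, diff)


def newtonian_acceleration(state: EnsembleState, config: EnsembleConfig) -> np.ndarray:
    """Acceleration: pair forces minus viscous drag minus the well gradient."""
    fp = config.force_params
    phi = pairwise_forces(
        state.positions,
        state.chem[:, 2],
        fp.repulsion_strength,
        fp.attraction_strength,
        state.closed_mask,
        config.coupling_radius,
    )
    return phi - fp.viscosity_coeff * state.velocities - fp.well_stiffness * state.positions


try:  # compiled hot loop; the numpy path below is the reference fallback
    from numba import njit

    @njit(cache=True)
    def _step_kernel(
        pos, vel, chem, kappa, closed, noise_v, noise_c,
        dt, r2, sigma, rho, beta, c_rep, c_att, visc, well, min_d, coh_scale,
    ):  # pragma: no cover - exercised through step/simulate
        n, d = pos.shape
        phi = np.zeros((n, d))
        csum = chem.copy()
        cnt = np.ones(n)
        for i in range(n):
            for j in range(i + 1, n):
                d2 = 0.0
                for a in range(d):
                    dd = pos[i, a] - pos[j, a]
                    d2 += dd * dd
                if d2 <= r2:
                    if not closed[j]:
                        for a in range(3):
                            csum[i, a] += chem[j, a]
                        cnt[i] += 1.0
                    if not closed[i]:
                        for a in range(3):
                            csum[j, a] += chem[i, a]
                        cnt[j] += 1.0
                dist = np.sqrt(d2)
                if dist < min_d:
                    dist = min_d
                att = 0.0
                if d2 <= r2 and not closed[i] and not closed[j]:
                    dx3 = chem[i, 2] - chem[j, 2]
                    att = c_att * np.exp(-(dx3 * dx3) / coh_scale)
                mag = (c_rep / (dist * dist) - att / dist) / dist
                for a in range(d):
                    f = mag * (pos[i, a] - pos[j, a])
                    phi[i, a] += f
                    phi[j, a] -= f
        bad = -1
        sq = np.sqrt(dt)
        for i in range(n):
            xb1 = csum[i, 0] / cnt[i]
            x1 = chem[i, 0]
            x2 = chem[i, 1]
            x3 = chem[i, 2]
            k = kappa[i]
            f0 = k * (sigma * (x2 - x1))
            f1 = k * (rho * xb1 - x2 - xb1 * x3)
            f2 = k * (xb1 * x2 - beta * x3)
            for a in range(d):
                oldp = pos[i, a]
                pos[i, a] += vel[i, a] * dt
                vel[i, a] += (phi[i, a] - visc * vel[i, a] - well * oldp) * dt
                vel[i, a] += sq * noise_v[i, a]
                if not np.isfinite(vel[i, a]):
                    bad = i if bad < 0 else bad
            chem[i, 0] += f0 * dt + sq * noise_c[i, 0]
            chem[i, 1] += f1 * dt + sq * noise_c[i, 1]
            chem[i, 2] += f2 * dt + sq * noise_c[i, 2]
            for a in range(3):
                if not np.isfinite(chem[i, a]):
                    bad = i if bad < 0 else bad
        return bad

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def step(
    state: EnsembleState, config: EnsembleConfig, rng: np.random.Generator
) -> EnsembleState:
    """One Euler–Maruyama step; adjacency is recomputed from the new geometry."""
    new = state.copy()
    _step_inplace(new, config, rng)
    return new


def _step_inplace(state: EnsembleState, config: EnsembleConfig, rng: np.random.Generator) -> None:
    """One Euler–Maruyama step (compiled kernel when numba is available)."""
    dt = config.dt
    if _HAVE_NUMBA:
        if config.noise_sd > 0.0:
            noise_v = config.noise_sd * rng.standard_normal(state.velocities.shape)
            noise_c = config.noise_sd * rng.standard_normal(state.chem.shape)
        else:
            noise_v = np.zeros_like(state.velocities)
            noise_c = np.zeros_like(state.chem)
        fp = config.force_params
        sigma, rho, beta = config.lorenz_params
        bad = _step_kernel(
            state.positions, state.velocities, state.chem, state.kappa,
            state.closed_mask, noise_v, noise_c,
            dt, config.coupling_radius**2, sigma, rho, beta,
            fp.repulsion_strength, fp.attraction_strength,
            fp.viscosity_coeff, fp.well_stiffness, MIN_DISTANCE, COHERENCE_SCALE,
        )
        state.time += dt
        if bad >= 0:
            raise IntegrationBlowUpError(state.time, int(bad))
        return
    _step_numpy(state, config, rng)


def _step_numpy(state: EnsembleState, config: EnsembleConfig, rng: np.random.Generator) -> None:
    """Reference numpy step sharing one pairwise-geometry computation."""
    dt = config.dt
    pos, vel, chem = state.positions, state.velocities, state.chem
    sigma, rho, beta = config.lorenz_params
    fp = config.force_params

    diff = pos[:, None, :] - pos[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    # adjacency of electrochemical influence (column j zeroed when j closed)
    A = d2 <= config.coupling_radius**2
    np.fill_diagonal(A, False)
    A[:, state.closed_mask] = False
    Af = A.astype(np.float64)

    # local in-neighbour averages (self included) and Lorenz-form flow
    counts = 1.0 + Af.sum(axis=1)
    xb1 = (chem[:, 0] + Af @ chem[:, 0]) / counts
    x1, x2, x3 = chem[:, 0], chem[:, 1], chem[:, 2]
    flow = np.empty_like(chem)
    flow[:, 0] = sigma * (x2 - x1)
    flow[:, 1] = rho * xb1 - x2 - xb1 * x3
    flow[:, 2] = xb1 * x2 - beta * x3
    flow *= state.kappa[:, None]

    # pair forces: inverse-square repulsion, coherence-gated attraction
    np.fill_diagonal(d2, 1.0)
    d = np.sqrt(d2)
    np.clip(d, MIN_DISTANCE, None, out=d)
    dx3 = x3[:, None] - x3[None, :]
    gate = np.exp(dx3 * dx3 / -COHERENCE_SCALE)
    open_ = ~state.closed_mask
    mutual = (d <= config.coupling_radius) & open_[:, None] & open_[None, :]
    mag = fp.repulsion_strength / (d * d) - fp.attraction_strength * gate * mutual / d
    np.fill_diagonal(mag, 0.0)
    phi = np.einsum("ij,ijk->ik", mag / d, diff)
    accel = phi - fp.viscosity_coeff * vel - fp.well_stiffness * pos

    pos += vel * dt
    vel += accel * dt
    chem += flow * dt
    sq = config.noise_sd * np.sqrt(dt)
    if sq > 0.0:
        vel += sq * rng.standard_normal(vel.shape)
        chem += sq * rng.standard_normal(chem.shape)
    state.time += dt
    if not (np.isfinite(chem).all() and np.isfinite(vel).all()):
        bad = ~(np.isfinite(chem).all(axis=1) & np.isfinite(vel).all(axis=1))
        raise IntegrationBlowUpError(state.time, int(np.flatnonzero(bad)[0]))


def simulate(
    config: EnsembleConfig,
    initial_state: EnsembleState | None = None,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Integrate the soup and return saved frames every ``save_interval``.

    The trajectory always includes the initial frame, so a run of duration T
    yields T / save_interval + 1 frames.  With no explicit initial state or
    generator, both are derived from ``config.seed``, making runs
    bit-reproducible.  A warning is logged whenever the minimum pairwise
    distance in a saved frame drops below 10 * MIN_DISTANCE (near-collision:
    the inverse-square law will eject the pair).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if initial_state is None:
        state = init_ensemble(config, rng)
    else:
        state = initial_state.copy()
    if duration is None:
        duration = config.duration

    steps_per_save = config.steps_per_save
    n_saves = round(duration / config.save_interval)
    frames = n_saves + 1

    n, d = state.n, state.positions.shape[1]
    times = np.empty(frames)
    positions = np.empty((frames, n, d))
    velocities = np.empty((frames, n, d))
    chem = np.empty((frames, n, 3))

    def record(f: int) -> None:
        times[f] = state.time
        positions[f] = state.positions
        velocities[f] = state.velocities
        chem[f] = state.chem

    record(0)
    for f in range(1, frames):
        for _ in range(steps_per_save):
            _step_inplace(state, config, rng)
        record(f)
        if n > 1:
            diff = state.positions[:, None, :] - state.positions[None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(d2, np.inf)
            dmin = np.sqrt(d2.min())
            if dmin < 10 * MIN_DISTANCE:
                logger.warning("near-collision at t=%.1f s (min distance %.2e)", state.time, dmin)
        if f % max(1, frames // 8) == 0:
            logger.info("simulated %.0f / %.0f s", state.time, duration)

    return Trajectory(
        config=replace(config, duration=float(duration)),
        times=times,
        positions=positions,
        velocities=velocities,
        chem=chem,
        kappa=state.kappa.copy(),
        closed_mask=state.closed_mask.copy(),
    )
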