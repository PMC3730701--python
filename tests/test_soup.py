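"""Simulator unit and property tests with independent dynamical oracles."""

import numpy as np
import pytest

import ergosoup as es
from ergosoup.soup import MIN_DISTANCE, init_ensemble, local_averages, step


def lorenz_rhs(x, sigma=10.0, rho=32.0, beta=8.0 / 3.0):
    """Independent textbook Lorenz right-hand side (the oracle)."""
    return np.array(
        [
            sigma * (x[1] - x[0]),
            rho * x[0] - x[1] - x[0] * x[2],
            x[0] * x[1] - beta * x[2],
        ]
    )


def quiet_config(**kw):
    defaults = dict(n_subsystems=4, duration=1.0, seed=0, noise_sd=0.0)
    defaults.update(kw)
    return es.EnsembleConfig(**defaults)


class TestInitEnsemble:
    def test_closed_count_is_rounded_third(self):
        cfg = es.EnsembleConfig(n_subsystems=128)
        state = init_ensemble(cfg)
        assert state.closed_mask.sum() == 43  # round(128/3)

    def test_seeded_determinism(self):
        cfg = es.EnsembleConfig(n_subsystems=16, seed=5)
        a, b = init_ensemble(cfg), init_ensemble(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.chem, b.chem)
        assert np.array_equal(a.kappa, b.kappa)
        assert np.array_equal(a.closed_mask, b.closed_mask)

    def test_single_subsystem(self):
        state = init_ensemble(es.EnsembleConfig(n_subsystems=1))
        assert state.positions.shape == (1, 2)
        assert state.closed_mask.sum() in (0, 1)

    def test_kappa_in_unit_interval_mostly_fast(self):
        state = init_ensemble(es.EnsembleConfig(n_subsystems=2000, seed=1))
        assert (state.kappa > 0).all() and (state.kappa <= 1).all()
        # heavy mass near one, thin slow tail
        assert (state.kappa > 0.8).mean() > 0.5
        assert (state.kappa < 0.4).mean() < 0.05


class TestContactNeighbors:
    def test_out_of_range(self):
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        assert not es.contact_neighbors(pos, 1.0).any()

    def test_symmetric_contact(self):
        pos = np.array([[0.0, 0.0], [0.5, 0.0]])
        A = es.contact_neighbors(pos, 1.0)
        assert A[0, 1] == 1 and A[1, 0] == 1 and A[0, 0] == 0

    def test_closed_column_zeroed_row_kept(self):
        pos = np.array([[0.0, 0.0], [0.5, 0.0]])
        closed = np.array([False, True])
        A = es.contact_neighbors(pos, 1.0, closed)
        assert A[0, 1] == 0  # no influence from the closed subsystem
        assert A[1, 0] == 1  # the closed subsystem still senses


class TestLocalAverage:
    def test_isolated_is_self(self):
        chem = np.arange(9.0).reshape(3, 3)
        A = np.zeros((3, 3), dtype=np.int8)
        assert np.array_equal(es.local_average(chem, A, 1), chem[1])

    def test_pair_mean(self):
        chem = np.array([[1.0, 0.0, 2.0], [3.0, 4.0, 0.0], [9.0, 9.0, 9.0]])
        A = np.zeros((3, 3), dtype=np.int8)
        A[0, 1] = 1  # 1 influences 0
        assert np.allclose(es.local_average(chem, A, 0), (chem[0] + chem[1]) / 2)

    def test_closed_neighbor_does_not_enter(self):
        rng = np.random.default_rng(0)
        pos = rng.standard_normal((5, 2)) * 0.3
        chem = rng.standard_normal((5, 3))
        closed = np.array([False, False, True, False, False])
        A = es.contact_neighbors(pos, 1.0, closed)
        before = es.local_average(chem, A, 0)
        chem2 = chem.copy()
        chem2[2] += 100.0  # perturb the closed subsystem's states
        after = es.local_average(chem2, A, 0)
        assert np.array_equal(before, after)


class TestElectrochemicalFlow:
    def test_origin_is_fixed_point(self):
        rng = np.random.default_rng(1)
        state = init_ensemble(es.EnsembleConfig(n_subsystems=6, seed=1))
        state.chem[:] = 0.0
        A = (rng.random((6, 6)) < 0.5).astype(np.int8)
        np.fill_diagonal(A, 0)
        assert np.allclose(es.electrochemical_flow(state, A), 0.0)

    def test_uncoupled_equals_textbook_lorenz(self):
        state = init_ensemble(es.EnsembleConfig(n_subsystems=1, seed=2))
        state.kappa[:] = 1.0
        A = np.zeros((1, 1), dtype=np.int8)
        flow = es.electrochemical_flow(state, A)
        assert np.allclose(flow[0], lorenz_rhs(state.chem[0]), rtol=1e-12)

    def test_kappa_scales_flow(self):
        state = init_ensemble(es.EnsembleConfig(n_subsystems=3, seed=3))
        A = np.zeros((3, 3), dtype=np.int8)
        f1 = es.electrochemical_flow(state, A)
        state.kappa *= 2.0
        f2 = es.electrochemical_flow(state, A)
        assert np.allclose(f2, 2 * f1)


class TestNewtonianAcceleration:
    def test_single_subsystem_at_rest(self):
        cfg = quiet_config(n_subsystems=1)
        state = init_ensemble(cfg)
        state.positions[:] = 0.0
        state.velocities[:] = 0.0
        assert np.allclose(es.newtonian_acceleration(state, cfg), 0.0)

    def test_newtons_third_law_pairwise(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pos = rng.standard_normal((2, 2))
            chem3 = rng.standard_normal(2) * 5
            closed = rng.random(2) < 0.5
            phi = es.pairwise_forces(pos, chem3, 1.0, 2.0, closed, 1.0)
            assert np.allclose(phi[0], -phi[1], atol=1e-12)

    def test_inverse_square_scaling(self):
        pos1 = np.array([[0.0, 0.0], [1.0, 0.0]])
        pos2 = np.array([[0.0, 0.0], [0.5, 0.0]])
        chem3 = np.zeros(2)
        # attraction off: isolate the repulsive term
        f1 = es.pairwise_forces(pos1, chem3, 1.0, 0.0)
        f2 = es.pairwise_forces(pos2, chem3, 1.0, 0.0)
        assert np.linalg.norm(f2[0]) == pytest.approx(4 * np.linalg.norm(f1[0]), rel=1e-12)

    def test_coherent_pair_attracts_incoherent_repels(self):
        pos = np.array([[0.0, 0.0], [0.8, 0.0]])
        coherent = es.pairwise_forces(pos, np.array([5.0, 5.0]), 0.3, 2.0,
                                      np.array([False, False]), 1.0)
        incoherent = es.pairwise_forces(pos, np.array([5.0, 25.0]), 0.3, 2.0,
                                        np.array([False, False]), 1.0)
        assert coherent[0, 0] > 0  # pulled towards the partner at +x
        assert incoherent[0, 0] < 0  # pushed away

    def test_closed_pair_has_no_attraction(self):
        pos = np.array([[0.0, 0.0], [0.8, 0.0]])
        chem3 = np.array([5.0, 5.0])
        closed = np.array([True, False])
        f = es.pairwise_forces(pos, chem3, 0.3, 2.0, closed, 1.0)
        pure_rep = es.pairwise_forces(pos, chem3, 0.3, 0.0)
        assert np.allclose(f, pure_rep)

    def test_coincident_positions_clamped(self):
        pos = np.zeros((2, 2))
        f = es.pairwise_forces(pos, np.zeros(2), 1.0, 0.0)
        assert np.isfinite(f).all()
        assert np.abs(f).max() <= 1.0 / MIN_DISTANCE**2


class TestStep:
    def test_null_dynamics(self):
        cfg = quiet_config(
            n_subsystems=1,
            force_params=es.ForceParams(0.0, 0.0, 0.0, 0.0),
        )
        state = init_ensemble(cfg)
        state.velocities[:] = 0.0
        state.chem[:] = 0.0
        rng = np.random.default_rng(0)
        new = step(state, cfg, rng)
        assert np.array_equal(new.positions, state.positions)
        assert np.array_equal(new.chem, state.chem)
        assert new.time == pytest.approx(cfg.dt)

    def test_single_subsystem_tracks_lorenz_oracle(self):
        """Noise-free chem trajectory matches an independent Euler integration."""
        cfg = quiet_config(n_subsystems=1)
        state = init_ensemble(cfg)
        state.kappa[:] = 1.0
        x = state.chem[0].copy()
        rng = np.random.default_rng(0)
        n_steps = 512
        for _ in range(n_steps):
            x = x + cfg.dt * lorenz_rhs(x)
            state = step(state, cfg, rng)
        assert np.allclose(state.chem[0], x, rtol=1e-9, atol=1e-9)

    def test_energy_dissipation(self):
        """Kinetic + well + repulsion-pair energy is non-increasing without noise."""
        fp = es.ForceParams(
            repulsion_strength=0.5, attraction_strength=0.0,
            viscosity_coeff=1.0, well_stiffness=0.25,
        )
        cfg = quiet_config(n_subsystems=8, force_params=fp)
        state = init_ensemble(cfg)
        state.positions *= 2.0  # avoid starting deep in the repulsive core
        rng = np.random.default_rng(0)

        def energy(s):
            kin = 0.5 * (s.velocities**2).sum()
            well = 0.5 * fp.well_stiffness * (s.positions**2).sum()
            D = np.linalg.norm(s.positions[:, None] - s.positions[None, :], axis=2)
            iu = np.triu_indices_from(D, k=1)
            pair = (fp.repulsion_strength / D[iu]).sum()
            return kin + well + pair

        energies = [energy(state)]
        for _ in range(20):
            for _ in range(256):
                state = step(state, cfg, rng)
            energies.append(energy(state))
        diffs = np.diff(energies)
        assert (diffs <= 1e-6).all()

    def test_momentum_conservation(self):
        """Total momentum is conserved without well, viscosity, or noise."""
        fp = es.ForceParams(
            repulsion_strength=1.0, attraction_strength=2.0,
            viscosity_coeff=0.0, well_stiffness=0.0,
        )
        cfg = quiet_config(n_subsystems=6, force_params=fp)
        state = init_ensemble(cfg)
        p0 = state.velocities.sum(axis=0)
        rng = np.random.default_rng(0)
        for _ in range(10 * 512):
            state = step(state, cfg, rng)
        assert np.allclose(state.velocities.sum(axis=0), p0, atol=1e-8)

    def test_uncoupled_limit_independent_lorenz(self):
        """With a vanishing coupling radius each chem trajectory is pure Lorenz."""
        cfg = quiet_config(n_subsystems=3, coupling_radius=1e-9)
        state = init_ensemble(cfg)
        refs = [c.copy() for c in state.chem]
        kappas = state.kappa.copy()
        rng = np.random.default_rng(0)
        for _ in range(256):
            refs = [x + cfg.dt * kap * lorenz_rhs(x) for x, kap in zip(refs, kappas)]
            state = step(state, cfg, rng)
        assert np.allclose(state.chem, np.array(refs), rtol=1e-9, atol=1e-9)


class TestSimulate:
    def test_zero_duration_single_frame(self):
        traj = es.simulate(quiet_config(duration=0.0))
        assert traj.n_frames == 1
        assert traj.times[0] == 0.0

    def test_frame_count_and_spacing(self):
        traj = es.simulate(quiet_config(n_subsystems=4, duration=8.0))
        assert traj.n_frames == 9
        assert np.allclose(np.diff(traj.times), 1.0)

    def test_determinism(self):
        cfg = es.EnsembleConfig(n_subsystems=8, duration=4.0, seed=7)
        t1, t2 = es.simulate(cfg), es.simulate(cfg)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.chem, t2.chem)
        assert np.array_equal(t1.velocities, t2.velocities)
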