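"""Contact potential, neighbor enumeration, Metropolis dynamics."""

import numpy as np
import pytest
from scipy import stats

import pepmc
from pepmc.energetics import (PotentialParams, metropolis_sweep,
                              neighbor_offsets, pair_potential,
                              per_node_energies, run_simulation,
                              total_energy, total_energy_oracle)
from pepmc.interactions import InteractionMatrix, parse_sequence
from pepmc.lattice import SimulationConfig, initialize_system


class TestPairPotential:
    def test_zero_beyond_cutoff(self):
        for eps in (-149.0, -6.0, 43.0):
            assert pair_potential(eps, 3.0) == 0.0
            assert pair_potential(eps, 2.9) == 0.0  # sqrt(8) ~ 2.828

    def test_attractive_pair_at_contact(self):
        # depth-normalized 12-6 form evaluated independently:
        # 4*|eps|*((1/2)^12 - (1/2)^6) for eps = -6 at r = 2
        expected = 4 * 6 * (2.0**-12 - 2.0**-6)
        assert pair_potential(-6.0, 2.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.369140625)

    def test_repulsive_pair_at_contact(self):
        expected = 4 * 67 * (2.0**-12 + 2.0**-6)
        assert pair_potential(+67.0, 2.0) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(+4.2529296875)

    def test_well_depth_is_eps(self):
        # minimum of the attractive branch sits at 2^(1/6) sigma with depth |eps|
        r_min = 2.0 ** (1 / 6)
        assert pair_potential(-6.0, r_min) == pytest.approx(-6.0)

    def test_repulsive_for_positive_eps_everywhere(self):
        for r in np.linspace(0.5, 2.8, 40):
            assert pair_potential(+10.0, r) > 0

    def test_zero_distance_raises(self):
        with pytest.raises(ValueError):
            pair_potential(-6.0, 0.0)


class TestNeighborOffsets:
    def test_enumeration(self):
        offs = neighbor_offsets()
        assert len(offs) == 92  # |v|^2 in {1,2,3,4,5,6,8}: 6+12+8+6+24+24+12
        sq = np.sum(offs * offs, axis=1)
        assert set(sq.tolist()) == {1, 2, 3, 4, 5, 6, 8}

    def test_membership_and_negation_closure(self):
        s = set(map(tuple, neighbor_offsets()))
        assert (2, 2, 0) in s
        assert (3, 0, 0) not in s   # |v|^2 = 9 > 8
        assert {tuple(-np.array(v)) for v in s} == s


def _two_node_state(matrix, r_vec, letters="AA", L=16):
    """A hand-built two-node system at a chosen separation."""
    seq = parse_sequence(letters)
    cfg = SimulationConfig(L=L, C_p=2 * 8 / L**3 * 1.01, T=1.0, seed=0)
    state = initialize_system(cfg, seq)
    state.positions[0] = (0, 0, 0)
    state.positions[1] = r_vec
    state.occupancy[:] = -1
    idx = state.site_indices()
    state.occupancy[idx[0]] = 0
    state.occupancy[idx[1]] = 1
    return state, cfg


class TestLocalEnergy:
    def test_isolated_node_zero(self, matrix):
        state, _ = _two_node_state(matrix, (0, 0, 4))  # beyond cutoff
        params = PotentialParams(matrix=matrix)
        e = per_node_energies(state, params)
        assert e[0] == 0.0 and e[1] == 0.0

    def test_two_attractive_nodes_at_distance_two(self, matrix):
        state, _ = _two_node_state(matrix, (0, 0, 2))
        params = PotentialParams(matrix=matrix)
        e = per_node_energies(state, params)
        expected = pair_potential(matrix.epsilon("A", "A"), 2.0)
        assert e[0] == pytest.approx(expected)
        assert e[1] == pytest.approx(expected)
        assert total_energy(state, params) == pytest.approx(expected)

    def test_like_charge_pair_positive(self, matrix):
        state, _ = _two_node_state(matrix, (0, 0, 2), letters="KK")
        params = PotentialParams(matrix=matrix)
        assert total_energy(state, params) > 0

    def test_matches_oracle_on_random_states(self, matrix, p1, rng):
        params = PotentialParams(matrix=matrix)
        for seed in (1, 2, 3):
            cfg = SimulationConfig(L=12, C_p=0.15, T=1.0, seed=seed)
            state = initialize_system(cfg, p1)
            assert total_energy(state, params) == pytest.approx(
                total_energy_oracle(state, params), rel=1e-10, abs=1e-12)


class TestMetropolis:
    def test_attempts_per_mcs_equals_residue_count(self, matrix, p1):
        cfg = SimulationConfig(L=16, C_p=0.1, T=1.0, seed=1)
        state = initialize_system(cfg, p1)
        params = PotentialParams(matrix=matrix)
        metropolis_sweep(state, params, T=1.0, seed=5, n_sweeps=7)
        assert state.attempts == 7 * state.n_residues

    def test_energy_bookkeeping_after_long_run(self, matrix, p1):
        cfg = SimulationConfig(L=16, C_p=0.1, T=0.7, seed=4)
        state = initialize_system(cfg, p1)
        params = PotentialParams(matrix=matrix)
        state.cached_energy = total_energy(state, params)
        metropolis_sweep(state, params, T=0.7, seed=9, n_sweeps=1000)
        oracle = total_energy_oracle(state, params)
        assert state.cached_energy == pytest.approx(oracle, rel=1e-8)
        assert pepmc.verify_state(state).ok

    def test_energy_decreases_at_very_low_temperature(self, matrix, p1):
        cfg = SimulationConfig(L=16, C_p=0.1, T=1e-6, seed=4)
        state = initialize_system(cfg, p1)
        params = PotentialParams(matrix=matrix)
        e0 = total_energy(state, params)
        state.cached_energy = e0
        metropolis_sweep(state, params, T=1e-6, seed=10, n_sweeps=200)
        assert state.cached_energy <= e0 + 1e-9

    def test_infinite_temperature_matches_athermal(self, matrix, p1):
        """At T -> inf acceptance is set by the constraints alone.

        The hot interacting system and the potential-free system follow the
        same accept-everything-allowed Markov chain, so their mean
        acceptance rates agree within run-to-run fluctuations (replicate
        means compared at 3 pooled standard errors).
        """
        zero = InteractionMatrix(np.zeros((20, 20)))
        rates = {"hot": [], "athermal": []}
        for key, mat, T in (("hot", matrix, 1e9), ("athermal", zero, 1.0)):
            for seed in range(5):
                cfg = SimulationConfig(L=16, C_p=0.1, T=T, seed=21 + seed)
                state = initialize_system(cfg, p1)
                params = PotentialParams(matrix=mat)
                acc = metropolis_sweep(state, params, T=T, seed=33 + seed,
                                       n_sweeps=300)
                rates[key].append(acc / state.attempts)
        hot, ath = np.array(rates["hot"]), np.array(rates["athermal"])
        se = np.sqrt(hot.var(ddof=1) / 5 + ath.var(ddof=1) / 5)
        assert abs(hot.mean() - ath.mean()) < 3 * se + 1e-3

    def test_dimer_samples_exact_boltzmann(self, matrix):
        """A single bonded dimer is exactly enumerable.

        The only energy is the bond itself; states group by squared bond
        length |v|^2 in {4, 5, 6, 9, 10} with degeneracies {6, 24, 24, 30,
        24} (classic bond set) and Boltzmann weight exp(-u(|v|)/T).  The
        sampled class frequencies must match the exact distribution.
        """
        T = 0.3
        seq = parse_sequence("AA")
        cfg = SimulationConfig(L=8, C_p=16 / 512 * 1.01, T=T, seed=6)
        state = initialize_system(cfg, seq)
        assert state.n_chains == 1
        params = PotentialParams(matrix=matrix)
        state.cached_energy = total_energy(state, params)

        eps = matrix.epsilon("A", "A")
        classes = {4: 6, 5: 24, 6: 24, 9: 30, 10: 24}
        energy = {sq: pair_potential(eps, np.sqrt(sq)) for sq in classes}
        weights = {sq: g * np.exp(-energy[sq] / T)
                   for sq, g in classes.items()}
        Z = sum(weights.values())

        counts = {sq: 0 for sq in classes}
        n_samples = 6000
        for k in range(n_samples):
            metropolis_sweep(state, params, T=T, seed=1000 + k, n_sweeps=5)
            v = state.positions[1] - state.positions[0]
            counts[int(v @ v)] += 1

        observed = np.array([counts[sq] for sq in sorted(classes)])
        expected = np.array([n_samples * weights[sq] / Z
                             for sq in sorted(classes)])
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 1e-3, (observed, expected)


class TestRunSimulation:
    def test_zero_mcs_gives_single_checkpoint(self, matrix, p1):
        cfg = SimulationConfig(L=16, C_p=0.05, n_mcs=0, seed=1)
        traj = run_simulation(cfg, p1, matrix)
        assert len(traj.times) == 1 and traj.times[0] == 0

    def test_deterministic_from_seed(self, matrix, p1):
        cfg = SimulationConfig(L=16, C_p=0.1, T=0.8, n_mcs=200, seed=77)
        t1 = run_simulation(cfg, p1, matrix)
        t2 = run_simulation(cfg, p1, matrix)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.hops, t2.hops)
        assert np.array_equal(t1.energy, t2.energy)

    def test_checkpoint_schedule_monotone_and_counters(self, small_traj):
        assert np.all(np.diff(small_traj.times) > 0)
        assert np.all(np.diff(small_traj.hops, axis=0) >= 0)

    def test_cached_energy_tracks_oracle_at_checkpoints(self, small_traj,
                                                        matrix):
        # per-node attribution double-counts pairs: sum = 2 * total
        assert small_traj.node_energy[-1].sum() == pytest.approx(
            2 * small_traj.energy[-1], rel=1e-8)

    def test_roundtrip_save_load(self, small_traj, tmp_path):
        path = tmp_path / "t.npz"
        small_traj.save(path)
        back = pepmc.Trajectory.load(path)
        assert np.array_equal(back.positions, small_traj.positions)
        assert back.config == small_traj.config
        assert str(back.sequence) == str(small_traj.sequence)
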