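"""Coarse-grained contact potential and Metropolis Monte Carlo driver.

Residue nodes interact through a generalized Lennard-Jones potential

    u(r) = 4 [ |eps| (sigma/r)^12 + eps (sigma/r)^6 ],    r <= r_c = sqrt(8),

with sigma = 1 lattice constant.  An attractive pair (eps < 0) sees the
familiar 12-6 well whose depth is exactly |eps| (the standard
depth-normalizing prefactor 4), while a like-charge pair (eps > 0) is
purely repulsive.  The matrix entries are therefore literal well depths,
which puts the assembly/dispersion crossover of the packaged simulated
matrix in the reduced-temperature range T ~ 0.5-1.0.  The potential is truncated, not shifted, at
the cutoff.  Temperatures are reduced: the Boltzmann constant is absorbed
and T carries the units of the interaction-matrix entries.

Time is counted in Monte Carlo steps (MCS); one MCS attempts one move per
residue in the box.  Each attempt picks a random chain, then a random
residue of that chain, then a random unit-vector target site, and accepts
with the Metropolis probability min(1, exp(-dE/T)) unless excluded volume or
the bond-length constraints forbid the move outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np

from . import _kernels
from .interactions import InteractionMatrix, PeptideSequence
from .lattice import (SimulationConfig, SystemState, bond_lookup,
                      initialize_system, move_vectors)

SIGMA = 1.0
R_CUT_SQ = 8


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the contact potential: sigma, cutoff, and the matrix."""

    matrix: InteractionMatrix
    sigma: float = SIGMA
    r_cut: float = np.sqrt(R_CUT_SQ)

    def __post_init__(self):
        if self.sigma <= 0 or self.r_cut <= self.sigma:
            raise ValueError("require 0 < sigma < r_cut")


def pair_potential(eps: float, r: float, sigma: float = SIGMA,
                   r_cut: float = float(np.sqrt(R_CUT_SQ))) -> float:
    """Generalized LJ pair energy at separation ``r`` for well depth ``eps``.

    ``eps`` is the signed well depth: the 4-prefactor makes the minimum of
    an attractive pair exactly -|eps| (at r = 2^(1/6) sigma).  Zero beyond
    the cutoff (truncated, not shifted); raises for r = 0 (excluded volume
    must forbid coincident nodes).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r > r_cut:
        return 0.0
    s6 = (sigma / r) ** 6
    return 4.0 * (abs(eps) * s6 * s6 + eps * s6)


def neighbor_offsets() -> np.ndarray:
    """All integer vectors with 0 < |v|^2 <= 8, in fixed lexicographic order.

    These span the interaction ball of the cutoff r_c = sqrt(8); there are
    92 of them (squared lengths 1, 2, 3, 4, 5, 6 and 8).
    """
    rng = range(-2, 3)
    vecs = [v for v in product(rng, rng, rng)
            if 0 < sum(x * x for x in v) <= R_CUT_SQ]
    return np.array(sorted(vecs), dtype=np.int64)


def pair_energy_table(matrix: InteractionMatrix, sigma: float = SIGMA) -> np.ndarray:
    """(20, 20, 9) lookup of pair energies by type pair and squared distance."""
    U = np.zeros((20, 20, R_CUT_SQ + 1))
    eps = matrix.values
    for rsq in range(1, R_CUT_SQ + 1):
        s6 = (sigma * sigma / rsq) ** 3
        U[:, :, rsq] = 4.0 * (np.abs(eps) * s6 * s6 + eps * s6)
    return U


def _kernel_args(state: SystemState, params: PotentialParams):
    cfg = state.config
    periodic = cfg.boundary == "periodic"
    neigh, rsqk = _neighbor_table(state.L, periodic)
    return dict(
        U=pair_energy_table(params.matrix, params.sigma),
        neigh=neigh,
        rsqk=rsqk,
        bond_ok=bond_lookup(cfg.bond_set_mode),
        moves=move_vectors(cfg.move_set),
        include_bonded=cfg.include_bonded_energy,
        periodic=periodic,
        cube=cfg.occupancy_mode == "cube",
    )


def local_energy(state: SystemState, params: PotentialParams, node: int,
                 at: tuple[int, int, int] | None = None) -> float:
    """Interaction energy of one node, optionally evaluated at a trial site."""
    ka = _kernel_args(state, params)
    L = state.L
    x, y, z = state.positions[node] if at is None else at
    site = (int(x) % L) * L * L + (int(y) % L) * L + (int(z) % L)
    return float(_kernels.node_energy(
        state.occupancy, state.types, ka["U"], ka["neigh"], ka["rsqk"],
        site, node, state.chain_length, ka["include_bonded"]))


def per_node_energies(state: SystemState, params: PotentialParams) -> np.ndarray:
    """Interaction energy attributed to each node (pairs counted twice)."""
    ka = _kernel_args(state, params)
    return _kernels.all_node_energies(
        state.site_indices(), state.occupancy, state.types, ka["U"],
        ka["neigh"], ka["rsqk"], state.chain_length, ka["include_bonded"])


def total_energy(state: SystemState, params: PotentialParams) -> float:
    return 0.5 * float(per_node_energies(state, params).sum())


def total_energy_oracle(state: SystemState, params: PotentialParams) -> float:
    """Reference O(N^2) total energy with explicit minimum-image distances.

    Deliberately independent of the jitted kernels and of the occupancy
    index; used to validate the incremental bookkeeping.
    """
    pos = np.mod(state.positions, state.L).astype(float)
    eps = params.matrix.values
    types = state.types
    L = state.L
    cfg = state.config
    n = state.chain_length
    E = 0.0
    N = len(pos)
    for i in range(N):
        for j in range(i + 1, N):
            if not cfg.include_bonded_energy and j == i + 1 \
                    and i // n == j // n:
                continue
            d = pos[j] - pos[i]
            if cfg.boundary == "periodic":
                d -= L * np.round(d / L)
            r = float(np.sqrt(d @ d))
            if 0 < r * r <= R_CUT_SQ + 1e-12:
                E += pair_potential(eps[types[i], types[j]], r,
                                    params.sigma, params.r_cut)
    return E


@lru_cache(maxsize=8)
def _neighbor_table(L: int, periodic: bool):
    """Precomputed neighbor-site indices for every site and cutoff offset.

    ``neigh[site, k]`` is the flat index of the site reached by offset k
    (wrapped when periodic, -1 when a closed boundary is crossed) and
    ``rsqk[k]`` the squared offset length.
    """
    offs = neighbor_offsets()
    x, y, z = np.indices((L, L, L)).reshape(3, -1)
    neigh = np.empty((L**3, len(offs)), dtype=np.int32)
    for k, (ox, oy, oz) in enumerate(offs):
        sx, sy, sz = x + ox, y + oy, z + oz
        idx = (sx % L) * L * L + (sy % L) * L + (sz % L)
        if not periodic:
            bad = ((sx < 0) | (sx >= L) | (sy < 0) | (sy >= L)
                   | (sz < 0) | (sz >= L))
            idx = np.where(bad, -1, idx)
        neigh[:, k] = idx
    rsqk = np.sum(offs * offs, axis=1)
    return neigh, rsqk


def _move_offset_columns(moves: np.ndarray) -> np.ndarray:
    offs = neighbor_offsets()
    lookup = {tuple(v): k for k, v in enumerate(offs)}
    return np.array([lookup[tuple(v)] for v in moves], dtype=np.int64)


def metropolis_sweep(state: SystemState, params: PotentialParams, T: float,
                     seed: int, n_sweeps: int = 1) -> int:
    """Advance the state by ``n_sweeps`` MCS in place; returns accepted moves.

    The cached total energy and per-node hop counters are updated
    incrementally.  ``seed`` seeds the kernel RNG for this segment.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    ka = _kernel_args(state, params)
    kmove = _move_offset_columns(ka["moves"])
    kcheb = np.flatnonzero(ka["rsqk"] <= 3)
    extent = 2 if ka["cube"] else 1
    closed_max = -1 if ka["periodic"] else state.L - extent
    accepted, dE = _kernels.run_sweeps(
        state.positions, state.site_indices(), state.occupancy, state.hops,
        state.types, ka["U"], ka["neigh"], ka["rsqk"], kmove, kcheb,
        ka["bond_ok"], ka["moves"], state.chain_length, float(T),
        int(n_sweeps), int(seed) % (2**32 - 1), ka["include_bonded"],
        ka["cube"], closed_max)
    state.cached_energy += dE
    state.attempts += n_sweeps * state.n_residues
    state.accepted += accepted
    return accepted


def checkpoint_schedule(n_mcs: int, per_decade: int = 30) -> np.ndarray:
    """Logarithmically spaced integer checkpoint times, including 0 and n_mcs."""
    if n_mcs <= 0:
        return np.array([0])
    decades = np.log10(max(n_mcs, 10))
    pts = np.unique(np.round(
        np.logspace(0, np.log10(n_mcs), int(per_decade * decades) + 1)
    ).astype(np.int64))
    return np.unique(np.concatenate([[0], pts[pts <= n_mcs], [n_mcs]]))


@dataclass
class Trajectory:
    """Time-ordered record of a run at logarithmically spaced checkpoints.

    Positions are unwrapped so displacements and gyration radii can be
    computed directly; wrap with ``% L`` for structural observables.
    """

    times: np.ndarray                 # (n_cp,) MCS
    positions: np.ndarray             # (n_cp, N, 3) unwrapped int
    node_energy: np.ndarray           # (n_cp, N)
    hops: np.ndarray                  # (n_cp, N) cumulative successful moves
    energy: np.ndarray                # (n_cp,) cached total energy
    config: SimulationConfig
    sequence: PeptideSequence
    acceptance_rate: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def chain_length(self) -> int:
        return len(self.sequence)

    @property
    def n_chains(self) -> int:
        return self.positions.shape[1] // self.chain_length

    def chain_coords(self) -> np.ndarray:
        """(n_cp, n_chains, chain_length, 3) unwrapped coordinates."""
        n_cp, N, _ = self.positions.shape
        return self.positions.reshape(n_cp, self.n_chains, self.chain_length, 3)

    def coms(self) -> np.ndarray:
        """(n_cp, n_chains, 3) chain centre-of-mass positions, unwrapped."""
        return self.chain_coords().mean(axis=2)

    def save(self, path) -> None:
        import json
        from dataclasses import asdict
        np.savez_compressed(
            path, times=self.times, positions=self.positions,
            node_energy=self.node_energy, hops=self.hops, energy=self.energy,
            config=json.dumps(asdict(self.config)),
            sequence=str(self.sequence), name=self.sequence.name,
            acceptance_rate=self.acceptance_rate)

    @classmethod
    def load(cls, path) -> "Trajectory":
        import json

        from .interactions import parse_sequence
        z = np.load(path, allow_pickle=False)
        cfg = SimulationConfig(**json.loads(str(z["config"])))
        seq = parse_sequence(str(z["sequence"]), name=str(z["name"]))
        return cls(times=z["times"], positions=z["positions"],
                   node_energy=z["node_energy"], hops=z["hops"],
                   energy=z["energy"], config=cfg, sequence=seq,
                   acceptance_rate=float(z["acceptance_rate"]))


def run_simulation(config: SimulationConfig, sequence: PeptideSequence,
                   matrix: InteractionMatrix,
                   state: SystemState | None = None) -> Trajectory:
    """Initialize (unless a state is given) and run ``config.n_mcs`` sweeps.

    Fully reproducible from ``config.seed``: the initial placement and every
    kernel segment draw their seeds from one ``SeedSequence``.
    """
    ss = np.random.SeedSequence(config.seed)
    init_ss, run_ss = ss.spawn(2)
    if state is None:
        state = initialize_system(config, sequence,
                                  np.random.default_rng(init_ss))
    params = PotentialParams(matrix=matrix)
    state.cached_energy = total_energy(state, params)

    times = checkpoint_schedule(config.n_mcs, config.checkpoints_per_decade)
    n_cp, N = len(times), state.n_residues
    positions = np.empty((n_cp, N, 3), dtype=np.int64)
    node_e = np.empty((n_cp, N))
    hops = np.empty((n_cp, N), dtype=np.int64)
    energy = np.empty(n_cp)

    seg_seeds = run_ss.generate_state(n_cp, dtype=np.uint32)

    def record(k):
        positions[k] = state.positions
        node_e[k] = per_node_energies(state, params)
        hops[k] = state.hops
        energy[k] = state.cached_energy

    record(0)
    for k in range(1, n_cp):
        metropolis_sweep(state, params, config.T, int(seg_seeds[k]),
                         n_sweeps=int(times[k] - times[k - 1]))
        record(k)

    acc = state.accepted / state.attempts if state.attempts else np.nan
    return Trajectory(times=times, positions=positions, node_energy=node_e,
                      hops=hops, energy=energy, config=config,
                      sequence=sequence, acceptance_rate=acc,
                      meta={"seed": config.seed,
                            "matrix_provenance": matrix.provenance,
                            "final_state": state})
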