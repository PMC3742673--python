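"""Cubic-lattice geometry, bond-fluctuation constraints, and system setup.

Chains live on a simple cubic lattice of edge ``L``.  Consecutive residues
are joined by bond vectors of length between 2 and sqrt(10) lattice
constants.  Two bond sets are offered:

* ``classic`` — the standard 3-D bond-fluctuation vector classes
  {(2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0), (3,1,0)} plus all sign and
  permutation images (108 vectors).  This set excludes (2,2,0) and, with
  cube occupancy, guarantees chains cannot cross.
* ``literal_range`` — every integer vector with 4 <= |v|^2 <= 10
  (120 vectors; adds the 12 images of (2,2,0)).

Excluded volume has two conventions:

* ``cube`` (default) — each node occupies the 2x2x2 cube of sites anchored
  at its corner coordinate, the Carmesin–Kremer convention of the
  bond-fluctuation method.  Equivalently, corner coordinates of distinct
  nodes must differ by a Chebyshev distance of at least 2, which is how it
  is enforced; the nearest possible pair separation is 2 lattice constants.
  The volume fraction counts occupied sites: C_p = 8 N_residues / L^3.
* ``site`` — one node per lattice site; nonbonded pairs may then approach
  to distance 1.  C_p = N_residues / L^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations, product

import numpy as np

from .interactions import PeptideSequence

_CLASSIC_CLASSES = [(2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0), (3, 1, 0)]

#: Sites claimed per node along each axis, by occupancy mode.
_NODE_EXTENT = {"site": 1, "cube": 2}


def _expand_classes(classes) -> np.ndarray:
    vecs = set()
    for c in classes:
        for perm in permutations(c):
            for signs in product((1, -1), repeat=3):
                vecs.add(tuple(s * p for s, p in zip(signs, perm)))
    return np.array(sorted(vecs), dtype=np.int64)


def allowed_bond_vectors(mode: str = "classic") -> np.ndarray:
    """All allowed bond vectors for the given bond-set mode, shape (n, 3).

    ``classic`` yields 108 vectors, ``literal_range`` yields the 120 integer
    vectors with squared length in [4, 10].
    """
    if mode == "classic":
        return _expand_classes(_CLASSIC_CLASSES)
    if mode == "literal_range":
        rng = range(-3, 4)
        vecs = [v for v in product(rng, rng, rng) if 4 <= sum(x * x for x in v) <= 10]
        return np.array(sorted(vecs), dtype=np.int64)
    raise ValueError(f"unknown bond_set_mode {mode!r}")


def bond_lookup(mode: str = "classic") -> np.ndarray:
    """Boolean membership table for bond vectors, indexed by component + 4.

    Shape (9, 9, 9) so that displacements with components in [-4, 4] can be
    tested without branching; anything outside is not a bond.
    """
    table = np.zeros((9, 9, 9), dtype=np.bool_)
    for v in allowed_bond_vectors(mode):
        table[v[0] + 4, v[1] + 4, v[2] + 4] = True
    return table


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one lattice Monte Carlo run.

    ``T`` is the reduced temperature, in the same units as the interaction
    matrix entries (Boltzmann constant absorbed).  ``n_mcs`` counts Monte
    Carlo steps, one attempted move per residue each.  ``C_p`` is the
    peptide volume fraction under the convention of ``occupancy_mode``
    (see the module docstring).
    """

    L: int = 64
    C_p: float = 0.1
    T: float = 1.0
    n_mcs: int = 10_000
    seed: int = 0
    occupancy_mode: str = "cube"
    bond_set_mode: str = "classic"
    boundary: str = "periodic"
    move_set: str = "unit6"          # or "unit26"
    include_bonded_energy: bool = True
    checkpoints_per_decade: int = 30

    def __post_init__(self):
        if self.L < 8:
            raise ValueError("lattice edge L must be >= 8")
        if self.occupancy_mode not in _NODE_EXTENT:
            raise ValueError(f"unknown occupancy_mode {self.occupancy_mode!r}")
        if not 0 < self.C_p < 1:
            raise ValueError(f"C_p must lie in (0, 1), got {self.C_p}")
        if self.T <= 0:
            raise ValueError("reduced temperature T must be positive")
        if self.n_mcs < 0:
            raise ValueError("n_mcs must be non-negative")
        if self.bond_set_mode not in ("classic", "literal_range"):
            raise ValueError(f"unknown bond_set_mode {self.bond_set_mode!r}")
        if self.boundary not in ("periodic", "closed"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.move_set not in ("unit6", "unit26"):
            raise ValueError(f"unknown move_set {self.move_set!r}")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    @property
    def sites_per_node(self) -> int:
        return _NODE_EXTENT[self.occupancy_mode] ** 3

    def n_chains(self, chain_length: int) -> int:
        """Chain count under the concentration convention of the mode.

        N_c = floor(C_p * L^3 / (sites_per_node * chain_length)); floor so
        the realized volume fraction never exceeds the requested one.
        """
        return int(self.C_p * self.L**3) // (self.sites_per_node * chain_length)


def move_vectors(move_set: str) -> np.ndarray:
    if move_set == "unit6":
        return np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                         (0, 0, 1), (0, 0, -1)], dtype=np.int64)
    if move_set == "unit26":
        vs = [v for v in product((-1, 0, 1), repeat=3) if v != (0, 0, 0)]
        return np.array(vs, dtype=np.int64)
    raise ValueError(f"unknown move_set {move_set!r}")


@dataclass
class SystemState:
    """Full microstate of the lattice system.

    ``positions`` are unwrapped integer corner coordinates (node, xyz); the
    wrapped coordinate is ``positions % L``.  ``occupancy`` is a flat L^3
    array mapping the corner site index ``x*L*L + y*L + z`` to the occupying
    node id (or -1); in cube mode the excluded 2x2x2 footprint is implied by
    the corner (minimum corner Chebyshev distance 2).
    """

    positions: np.ndarray
    L: int
    chain_length: int
    types: np.ndarray
    occupancy: np.ndarray
    config: SimulationConfig
    sequence: PeptideSequence
    hops: np.ndarray = None
    cached_energy: float = 0.0
    attempts: int = 0
    accepted: int = 0

    def __post_init__(self):
        if self.hops is None:
            self.hops = np.zeros(len(self.positions), dtype=np.int64)

    @property
    def n_chains(self) -> int:
        return len(self.positions) // self.chain_length

    @property
    def n_residues(self) -> int:
        return len(self.positions)

    @property
    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.L)

    def site_indices(self) -> np.ndarray:
        w = self.wrapped
        return ((w[:, 0] * self.L + w[:, 1]) * self.L + w[:, 2]).astype(np.int64)

    def chain_positions(self) -> np.ndarray:
        """Unwrapped positions reshaped to (n_chains, chain_length, 3)."""
        return self.positions.reshape(self.n_chains, self.chain_length, 3)


_CHEB1 = np.array([v for v in product((-1, 0, 1), repeat=3) if v != (0, 0, 0)],
                  dtype=np.int64)


def _site_free(occ, L, p, mode, allow=-1):
    """Can a node corner sit at p without violating excluded volume?"""
    s = np.mod(p, L)
    if occ[(s[0] * L + s[1]) * L + s[2]] not in (-1, allow):
        return False
    if mode == "cube":
        for off in _CHEB1:
            t = np.mod(p + off, L)
            v = occ[(t[0] * L + t[1]) * L + t[2]]
            if v != -1 and v != allow:
                return False
    return True


class PlacementError(RuntimeError):
    pass


def initialize_system(config: SimulationConfig, sequence: PeptideSequence,
                      rng: np.random.Generator | None = None) -> SystemState:
    """Place N_c chains as excluded-volume random walks over the bond set.

    Each chain is grown site by site; a chain that dead-ends is discarded
    and regrown.  After a bounded number of failures a
    :class:`PlacementError` suggests lowering C_p or enlarging L.
    Deterministic for a given generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, mode = config.L, config.occupancy_mode
    n = len(sequence)
    n_chains = config.n_chains(n)
    if n_chains < 1:
        raise PlacementError("C_p * L^3 is too small to hold a single chain")
    bonds = allowed_bond_vectors(config.bond_set_mode)
    occ = np.full(L**3, -1, dtype=np.int32)
    positions = np.empty((n_chains * n, 3), dtype=np.int64)
    closed = config.boundary == "closed"
    hi = L - _NODE_EXTENT[mode] + 1  # exclusive corner bound in a closed box

    def claim(p, node):
        s = np.mod(p, L)
        occ[(s[0] * L + s[1]) * L + s[2]] = node

    max_restarts = 200 * n_chains + 1000
    restarts = 0
    c = 0
    while c < n_chains:
        start = rng.integers(0, hi if closed else L, size=3)
        node0 = c * n
        if not _site_free(occ, L, start, mode):
            restarts += 1
            if restarts > max_restarts:
                raise PlacementError(
                    "could not place chains; lower C_p or increase L")
            continue
        chain = [start]
        claim(start, node0)
        ok = True
        for k in range(1, n):
            placed = False
            for bi in rng.permutation(len(bonds)):
                cand = chain[-1] + bonds[bi]
                if closed and not np.all((cand >= 0) & (cand < hi)):
                    continue
                if _site_free(occ, L, cand, mode):
                    claim(cand, node0 + k)
                    chain.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            for p in chain:
                claim(p, -1)
            restarts += 1
            if restarts > max_restarts:
                raise PlacementError(
                    "could not place chains; lower C_p or increase L")
            continue
        positions[node0:node0 + n] = np.array(chain)
        c += 1

    types = np.tile(sequence.type_indices, n_chains)
    return SystemState(positions=positions, L=L, chain_length=n, types=types,
                       occupancy=occ, config=config, sequence=sequence)


@dataclass
class StateReport:
    ok: bool
    message: str = "ok"


def verify_state(state: SystemState) -> StateReport:
    """Check every structural invariant of a state; report first violation.

    Verifies bond-set membership of all consecutive displacements, excluded
    volume (including the cube-mode Chebyshev separation), and exact
    agreement between the occupancy index and the wrapped coordinates.
    Energy bookkeeping is checked separately against
    :func:`pepmc.energetics.total_energy_oracle`.
    """
    cfg = state.config
    L = state.L
    table = bond_lookup(cfg.bond_set_mode)
    chains = state.chain_positions()
    for ci in range(state.n_chains):
        d = np.diff(chains[ci], axis=0)
        for k, v in enumerate(d):
            if np.any(np.abs(v) > 4) or not table[v[0] + 4, v[1] + 4, v[2] + 4]:
                return StateReport(
                    False, f"chain {ci} bond {k}->{k+1} has invalid vector "
                           f"{tuple(int(x) for x in v)}")
    expect = np.full(L**3, -1, dtype=np.int32)
    w = state.wrapped
    idx = (w[:, 0] * L + w[:, 1]) * L + w[:, 2]
    for node, s in enumerate(idx):
        if expect[s] != -1:
            return StateReport(
                False, f"excluded volume violated: nodes {expect[s]} and "
                       f"{node} share a site")
        expect[s] = node
    if cfg.occupancy_mode == "cube":
        for node, p in enumerate(w):
            for off in _CHEB1:
                t = np.mod(p + off, L)
                other = expect[(t[0] * L + t[1]) * L + t[2]]
                if other != -1 and other != node:
                    return StateReport(
                        False, f"cube overlap: nodes {node} and {other} are "
                               "within Chebyshev distance 1")
    if not np.array_equal(expect, state.occupancy):
        bad = int(np.flatnonzero(expect != state.occupancy)[0])
        return StateReport(False, f"occupancy index inconsistent at site {bad}")
    return StateReport(True)
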