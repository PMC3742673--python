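"""Jit-compiled inner loops of the Metropolis dynamics.

All kernels operate on plain arrays so that :mod:`pepmc.energetics` can keep
the object-level bookkeeping in Python.  Conventions:

* ``pos`` holds unwrapped integer coordinates; ``occ`` maps the wrapped site
  index x*L*L + y*L + z of a node's *corner* to the node id (or -1).  In
  cube occupancy mode a node extends one site beyond its corner along each
  axis, which is enforced as a minimum corner-to-corner Chebyshev distance
  of 2 rather than by marking all eight sites.
* ``U`` is a (20, 20, 9) table of pair energies by residue-type pair and
  squared separation (index 1..8); separations beyond the cutoff
  r_c^2 = 8 never appear because the offset list only spans the cutoff ball.
* ``neigh[site, k]`` is the flat site index reached from ``site`` by the
  k-th cutoff-ball offset (-1 across a closed boundary); ``rsqk[k]`` is the
  squared offset length; ``kcheb`` lists the 26 columns with Chebyshev
  length 1 (used for the cube-mode overlap test); ``kmove[m]`` maps the
  m-th move vector to its offset column.
* ``bond_ok`` is the (9, 9, 9) bond-membership table indexed by
  component + 4.
"""

import numba as nb
import numpy as np


@nb.njit(cache=True, inline="always")
def _energy_at_site(site, i, ti, occ, types, U, neigh, rsqk,
                    chain_len, include_bonded):
    c0 = (i // chain_len) * chain_len
    e = 0.0
    for k in range(neigh.shape[1]):
        s = neigh[site, k]
        if s < 0:
            continue
        j = occ[s]
        if j < 0 or j == i:
            continue
        if not include_bonded:
            if (j == i - 1 and j >= c0) or (j == i + 1 and j < c0 + chain_len):
                continue
        e += U[ti, types[j], rsqk[k]]
    return e


@nb.njit(cache=True)
def node_energy(occ, types, U, neigh, rsqk, site, i,
                chain_len, include_bonded):
    """Interaction energy of node ``i`` evaluated at the given site index."""
    return _energy_at_site(site, i, types[i], occ, types, U, neigh, rsqk,
                           chain_len, include_bonded)


@nb.njit(cache=True)
def all_node_energies(cur_site, occ, types, U, neigh, rsqk,
                      chain_len, include_bonded):
    N = cur_site.shape[0]
    out = np.empty(N)
    for i in range(N):
        out[i] = _energy_at_site(cur_site[i], i, types[i], occ, types, U,
                                 neigh, rsqk, chain_len, include_bonded)
    return out


@nb.njit(cache=True)
def run_sweeps(pos, cur_site, occ, hops, types, U, neigh, rsqk, kmove, kcheb,
               bond_ok, moves, chain_len, T, n_sweeps, seed,
               include_bonded, cube, closed_max):
    """Run ``n_sweeps`` Monte Carlo steps of single-site Metropolis moves.

    One sweep makes N attempts (N = residue count): pick a random
    (chain, residue) pair and a random move vector, reject outright on
    excluded-volume or bond violations, otherwise accept with
    min(1, exp(-dE/T)).  ``closed_max`` is -1 for periodic boundaries, else
    the largest allowed corner coordinate.  Returns
    (accepted_moves, total_energy_change); ``pos``, ``cur_site``, ``occ``
    and ``hops`` are updated in place.
    """
    np.random.seed(seed)
    N = pos.shape[0]
    n_moves = moves.shape[0]
    accepted = 0
    dE_sum = 0.0
    for _ in range(n_sweeps):
        for _ in range(N):
            r = np.random.randint(N * n_moves)
            i = r // n_moves
            mv = r - i * n_moves
            old = cur_site[i]
            tgt = neigh[old, kmove[mv]]
            if tgt < 0:
                continue
            nx = pos[i, 0] + moves[mv, 0]
            ny = pos[i, 1] + moves[mv, 1]
            nz = pos[i, 2] + moves[mv, 2]
            if closed_max >= 0:
                if (nx < 0 or nx > closed_max or ny < 0 or ny > closed_max
                        or nz < 0 or nz > closed_max):
                    continue
            # excluded volume
            if occ[tgt] >= 0:
                continue
            if cube:
                blocked = False
                for kk in range(kcheb.shape[0]):
                    s = neigh[tgt, kcheb[kk]]
                    if s >= 0:
                        j = occ[s]
                        if j >= 0 and j != i:
                            blocked = True
                            break
                if blocked:
                    continue
            # bond constraints with chain neighbours
            m = i % chain_len
            if m > 0:
                bx = pos[i - 1, 0] - nx
                by = pos[i - 1, 1] - ny
                bz = pos[i - 1, 2] - nz
                if (bx < -4 or bx > 4 or by < -4 or by > 4 or bz < -4
                        or bz > 4 or not bond_ok[bx + 4, by + 4, bz + 4]):
                    continue
            if m < chain_len - 1:
                bx = pos[i + 1, 0] - nx
                by = pos[i + 1, 1] - ny
                bz = pos[i + 1, 2] - nz
                if (bx < -4 or bx > 4 or by < -4 or by > 4 or bz < -4
                        or bz > 4 or not bond_ok[bx + 4, by + 4, bz + 4]):
                    continue
            ti = types[i]
            e_old = _energy_at_site(old, i, ti, occ, types, U, neigh, rsqk,
                                    chain_len, include_bonded)
            e_new = _energy_at_site(tgt, i, ti, occ, types, U, neigh, rsqk,
                                    chain_len, include_bonded)
            dE = e_new - e_old
            if dE > 0.0 and np.random.random() >= np.exp(-dE / T):
                continue
            occ[old] = -1
            occ[tgt] = i
            cur_site[i] = tgt
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz
            hops[i] += 1
            accepted += 1
            dE_sum += dE
    return accepted, dE_sum
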