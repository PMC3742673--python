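"""Switched nonbonded pair energy between two atom groups.

This is the energy function used to score residue-residue encounters in
all-atom detail: a 12-6 van der Waals term plus a Coulomb term, both
modulated by the X-PLOR switching function so the interaction goes smoothly
to zero between the switching distance R_on and the cutoff R_C,

    E = sum_{i in group1, j in group2} SW(R_ij) *
        [ eps_ij ((Rmin_ij/R_ij)^12 - 2 (Rmin_ij/R_ij)^6) + C q_i q_j / R_ij ]

with SW(R) = 1 for R <= R_on, 0 for R >= R_C and

    SW(R) = (R_C^2 - R^2)^2 (R_C^2 + 2 R^2 - 3 R_on^2) / (R_C^2 - R_on^2)^3

in between.  Units: nm for distances, elementary charges, kcal/mol for
energies; the Coulomb constant is 332.0636 kcal mol^-1 A e^-2 expressed in
nm.  Per-atom vdW parameters (well depth eps_i in kcal/mol, Rmin_i/2 in nm)
are combined pairwise as eps_ij = sqrt(eps_i eps_j),
Rmin_ij = Rmin_i/2 + Rmin_j/2, the convention of the AMBER/CHARMM family.

Reducing a stored two-group trajectory to its minimum pair energy gives the
scalar contact strength used to parameterize the coarse-grained model.
Defaults: R_on = 1.0 nm, R_C = 1.2 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Coulomb constant in kcal/mol * nm / e^2 (332.0636 kcal/mol * Angstrom / e^2).
COULOMB_NM = 33.20636


@dataclass(frozen=True)
class SwitchingParams:
    """Switching distance, cutoff and Coulomb constant of the nonbonded model."""

    r_on: float = 1.0       # nm
    r_cut: float = 1.2      # nm
    coulomb: float = COULOMB_NM

    def __post_init__(self):
        if not 0 < self.r_on < self.r_cut:
            raise ValueError("require 0 < R_on < R_C")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: position (nm), partial charge (e), vdW eps (kcal/mol), Rmin/2 (nm)."""

    position: tuple[float, float, float]
    charge: float = 0.0
    eps: float = 0.0
    rmin_half: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite atom coordinates")
        if self.eps < 0 or self.rmin_half < 0:
            raise ValueError("vdW parameters must be non-negative")


def switching_function(r: float | np.ndarray, params: SwitchingParams
                       ) -> float | np.ndarray:
    """X-PLOR switching factor in [0, 1]; 1 below R_on, 0 beyond R_C."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be non-negative")
    r2 = r * r
    ron2, rc2 = params.r_on**2, params.r_cut**2
    sw = ((rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ron2)) / (rc2 - ron2) ** 3
    out = np.where(r2 <= ron2, 1.0, np.where(r2 >= rc2, 0.0, sw))
    return float(out) if out.ndim == 0 else out


def _group_arrays(group):
    pos = np.array([a.position for a in group], dtype=float)
    q = np.array([a.charge for a in group])
    eps = np.array([a.eps for a in group])
    rh = np.array([a.rmin_half for a in group])
    return pos, q, eps, rh


def pair_interaction_energy(group_i, group_j,
                            params: SwitchingParams = SwitchingParams()
                            ) -> float:
    """Switched vdW + Coulomb energy between two disjoint atom groups, kcal/mol."""
    pi, qi, ei, ri = _group_arrays(group_i)
    pj, qj, ej, rj = _group_arrays(group_j)
    d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=2)
    if np.any(d == 0):
        raise ValueError("coincident atoms across groups")
    within = d < params.r_cut
    if not np.any(within):
        return 0.0
    eps_ij = np.sqrt(ei[:, None] * ej[None, :])
    rmin_ij = ri[:, None] + rj[None, :]
    with np.errstate(divide="ignore"):
        s6 = np.where(d > 0, (rmin_ij / d) ** 6, 0.0)
    vdw = eps_ij * (s6 * s6 - 2 * s6)
    coul = params.coulomb * qi[:, None] * qj[None, :] / d
    sw = switching_function(d, params)
    return float(np.sum(np.where(within, sw * (vdw + coul), 0.0)))


def minimum_trajectory_energy(frames, params: SwitchingParams = SwitchingParams()
                              ) -> float:
    """Minimum over frames of the two-group pair energy.

    ``frames`` is an iterable of (group_i, group_j) atom-record pairs; this
    is the reduction that turns a sampled encounter trajectory into a single
    contact energy.
    """
    energies = [pair_interaction_energy(gi, gj, params) for gi, gj in frames]
    if not energies:
        raise ValueError("no frames given")
    return min(energies)


def read_atoms_csv(path: str | Path) -> list[AtomRecord]:
    """Read atom records from CSV with columns x,y,z,charge,eps,rmin_half.

    Coordinates in nm, charges in e, eps in kcal/mol, rmin_half in nm.  An
    optional leading id/name column is ignored.
    """
    df = pd.read_csv(path)
    need = ["x", "y", "z", "charge", "eps", "rmin_half"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"atom CSV is missing column(s) {missing}")
    return [AtomRecord(position=(r.x, r.y, r.z), charge=r.charge,
                       eps=r.eps, rmin_half=r.rmin_half)
            for r in df.itertuples()]
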