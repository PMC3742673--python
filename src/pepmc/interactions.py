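"""Residue-pair interaction matrices and peptide sequences.

The coarse-grained model represents each amino acid by a single node on a
cubic lattice; all atomic detail is condensed into a symmetric 20x20 table of
signed pair energies eps(a, b) that sets the well depth of the generalized
Lennard-Jones contact potential.  Two sources of such tables are supported:

* the packaged "simulated" matrix, whose magnitudes come from all-atom MD of
  capped residue pairs in vacuum (minimum pairwise interaction energy, in
  kcal/mol) with a sign convention that makes the six like-charge pairs
  (D-D, D-E, E-E, R-R, R-K, K-K) repulsive and every other pair attractive;
* any user-supplied matrix in the same CSV layout, e.g. a knowledge-based
  Miyazawa-Jernigan contact-energy table, taken with the signs as given.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

#: The twenty standard one-letter amino-acid codes, in the row order of the
#: packaged simulated matrix.
AMINO_ACIDS = tuple("AGVLIPFMWCDERKHNQSTY")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Like-charge residue pairs that are repulsive under the simulated-matrix
#: sign convention.
LIKE_CHARGE_PAIRS = frozenset(
    frozenset(p) for p in [("D", "D"), ("D", "E"), ("E", "E"),
                           ("R", "R"), ("R", "K"), ("K", "K")]
)


class MatrixFormatError(ValueError):
    """Raised when an interaction-matrix file is malformed or incomplete."""


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered amino-acid sequence; positions are 1-based."""

    residues: tuple[str, ...]
    name: str = ""

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("a peptide needs at least 2 residues")
        for pos, r in enumerate(self.residues, start=1):
            if r not in _AA_INDEX:
                raise ValueError(
                    f"invalid residue {r!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return "".join(self.residues)

    @property
    def type_indices(self) -> np.ndarray:
        """Integer residue-type index (0..19) per position."""
        return np.array([_AA_INDEX[r] for r in self.residues], dtype=np.int8)


#: The 12-mer studied throughout: HSSYWYAFNNKT.
P1 = "HSSYWYAFNNKT"


@dataclass
class InteractionMatrix:
    """Symmetric signed residue-pair energy table.

    ``values`` is a dense (20, 20) float array indexed by :data:`AMINO_ACIDS`
    order; inside the coarse-grained model the entries are used directly as
    the dimensionless well-depth coefficients of the contact potential, and
    the reduced temperature is expressed in the same units.
    """

    values: np.ndarray
    provenance: str = "custom"
    anomalies: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (20, 20):
            raise MatrixFormatError(f"expected a (20, 20) table, got {v.shape}")
        if not np.allclose(v, v.T):
            raise MatrixFormatError("interaction matrix must be symmetric")
        self.values = v

    def epsilon(self, a: str, b: str) -> float:
        """Signed pair energy; symmetric in its arguments."""
        try:
            return float(self.values[_AA_INDEX[a], _AA_INDEX[b]])
        except KeyError as exc:
            raise KeyError(f"unknown residue code {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(AMINO_ACIDS),
                            columns=list(AMINO_ACIDS))

    def write(self, path: str | Path) -> None:
        """Write the full signed 20x20 table as labeled CSV."""
        self.to_frame().to_csv(path, float_format="%.17g")


def _read_labeled_csv(source) -> pd.DataFrame:
    df = pd.read_csv(source, index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    unknown = (set(df.index) | set(df.columns)) - set(AMINO_ACIDS)
    if unknown:
        raise MatrixFormatError(f"unknown residue label(s): {sorted(unknown)}")
    for a in AMINO_ACIDS:
        if a not in df.index:
            raise MatrixFormatError(f"matrix file is missing row {a!r}")
        if a not in df.columns:
            raise MatrixFormatError(f"matrix file is missing column {a!r}")
    return df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]


def _complete_symmetric(df: pd.DataFrame) -> np.ndarray:
    """Fill a possibly lower-triangular labeled table into a symmetric array."""
    raw = df.to_numpy(dtype=float)
    out = np.full((20, 20), np.nan)
    for i in range(20):
        for j in range(20):
            x, y = raw[i, j], raw[j, i]
            if np.isnan(x) and np.isnan(y):
                continue
            if not np.isnan(x) and not np.isnan(y) and i != j and x != y:
                raise MatrixFormatError(
                    f"contradictory entries for pair "
                    f"({AMINO_ACIDS[i]},{AMINO_ACIDS[j]}): {x} vs {y}"
                )
            v = y if np.isnan(x) else x
            out[i, j] = out[j, i] = v
    missing = [
        (AMINO_ACIDS[i], AMINO_ACIDS[j])
        for i in range(20) for j in range(i, 20) if np.isnan(out[i, j])
    ]
    if missing:
        raise MatrixFormatError(f"missing pair value(s): {missing[:5]}"
                                + ("..." if len(missing) > 5 else ""))
    return out


def load_simulated_matrix() -> InteractionMatrix:
    """Load the packaged simulated (all-atom MD derived) interaction matrix.

    The data file stores the printed magnitudes verbatim; the sign convention
    (like-charge pairs repulsive, all others attractive) is applied here at
    load time.  Two entries of the published table carry an explicit minus
    sign (H-V and H-L, both -9); consistent with the stated convention they
    are read as attractive with magnitude 9, and the anomaly is recorded on
    the returned matrix and warned about once.
    """
    pkg = resources.files("pepmc.data")
    mags_text = (pkg / "simulated_pair_energy_magnitudes.csv").read_text()
    rule = json.loads((pkg / "sign_rule.json").read_text())
    positive = frozenset(frozenset(p) for p in rule["positive_pairs"])

    df = _read_labeled_csv(io.StringIO(mags_text))
    mags = _complete_symmetric(df)

    anomalies = []
    signed = np.empty_like(mags)
    for i in range(20):
        for j in range(20):
            m = mags[i, j]
            if m < 0:
                a, b = sorted((AMINO_ACIDS[i], AMINO_ACIDS[j]))
                anomalies.append(
                    f"pair ({a},{b}) printed with an "
                    f"explicit minus sign ({m:g}); using magnitude {abs(m):g} "
                    "under the standard sign convention"
                )
                m = abs(m)
            pair = frozenset((AMINO_ACIDS[i], AMINO_ACIDS[j]))
            signed[i, j] = m if pair in positive else -m
    # de-duplicate (each off-diagonal anomaly is seen twice)
    anomalies = sorted(set(anomalies))
    for msg in anomalies:
        warnings.warn(msg, stacklevel=2)
    return InteractionMatrix(signed, provenance="simulated", anomalies=anomalies)


def load_matrix_file(path: str | Path, provenance: str = "custom") -> InteractionMatrix:
    """Load a signed interaction matrix from a labeled CSV file.

    Accepts a full 20x20 table or a lower/upper-triangular one (empty cells
    filled by symmetry).  Values are taken exactly as given: no sign
    convention is applied, so e.g. Miyazawa-Jernigan contact energies should
    already be signed.
    """
    df = _read_labeled_csv(path)
    return InteractionMatrix(_complete_symmetric(df), provenance=provenance)


def parse_sequence(text: str, name: str = "") -> PeptideSequence:
    """Parse a one-letter amino-acid string or a FASTA record.

    Returns a :class:`PeptideSequence` with 1-based position semantics.
    Any character outside the 20-letter alphabet raises a ``ValueError``
    naming the offending position.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty sequence")
    if text.startswith(">"):
        rec = next(SeqIO.parse(io.StringIO(text), "fasta"))
        return parse_sequence(str(rec.seq), name=name or rec.id)
    return PeptideSequence(tuple(text.upper()), name=name)


def read_fasta(path: str | Path) -> PeptideSequence:
    """Read the first record of a FASTA file."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return parse_sequence(str(rec.seq), name=rec.id)
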