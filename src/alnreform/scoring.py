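"""Substitution-matrix management and the gap-penalty parameter machinery.

The engine scores a profile position against a sequence residue additively:
the raw residue *counts* of the position are multiplied by substitution
scores and summed, so deep, conserved columns outscore shallow ones.  For
that to favour (mis)matches over gaps, every matrix entry must be strictly
positive, which is arranged by rescaling the HOXD70 nucleotide matrix with
a multiplicative contrast coefficient and an additive bonus.

Four gap penalties are maintained: HGOP/HGEP open/extend a gap *in the
profile* (a sequence residue inserted between profile positions) and
VGOP/VGEP open/extend a gap *in the sequence* (a profile position skipped).
Terminal gaps are never penalized.  Defaults for all six free parameters
are derived from the average pairwise sequence identity (APSI) of the
starting alignment; penalties are further scaled per sequence by its length
relative to the longest sequence in the set, and gap openings are made
position-specific through the profile conservation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TextIO

import numpy as np

from .msa import ALPHABET

_IDX = {c: i for i, c in enumerate(ALPHABET)}

# HOXD70 nucleotide scores (Chiaromonte, Yap & Miller): match A/T = 91,
# match C/G = 100, transitions -31, transversions -114/-123/-125.
_HOXD70 = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=float,
)


class ScoringError(ValueError):
    """Raised when a parameter set violates the engine's constraints."""


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue-pair score table over {A, C, G, T}."""

    table: np.ndarray  # (4, 4) float

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.shape != (4, 4):
            raise ScoringError("substitution matrix must be 4x4 over ACGT")
        if not np.allclose(t, t.T):
            raise ScoringError("substitution matrix must be symmetric")
        object.__setattr__(self, "table", t)

    def score(self, a: str, b: str) -> float:
        return float(self.table[_IDX[a], _IDX[b]])


def base_hoxd() -> SubstitutionMatrix:
    """The unmodified HOXD70 nucleotide substitution matrix."""
    return SubstitutionMatrix(_HOXD70.copy())


def adjust_matrix(
    base: SubstitutionMatrix, bonus: float, coeff: float
) -> SubstitutionMatrix:
    """Rescale a matrix to the strictly positive range the engine needs.

    Every entry becomes ``entry * coeff + bonus``.  The additive bonus
    lifts all scores above zero so any (mis)match beats a gap; because a
    uniform shift understates the match/mismatch contrast, the
    multiplicative coefficient restores it (``coeff == 1`` is the identity,
    giving a pure shift).
    """
    if bonus <= 0:
        raise ScoringError("bonus must be positive")
    if coeff <= 0:
        raise ScoringError("coeff must be positive")
    table = base.table * coeff + bonus
    if np.any(table <= 0):
        raise ScoringError("bonus too small for matrix")
    return SubstitutionMatrix(table)


@dataclass(frozen=True)
class ScoringParams:
    """An adjusted matrix plus the four gap penalties.

    Penalties are stored non-positive and *added* to the score under
    maximization; "a harder penalty" means larger magnitude.  Terminal
    gaps are always free (``terminal_gaps_free`` is fixed true and kept
    only to make the policy explicit).
    """

    matrix: SubstitutionMatrix
    hgop: float
    hgep: float
    vgop: float
    vgep: float
    bonus: float
    coeff: float
    apsi_p: float = float("nan")
    terminal_gaps_free: bool = True

    def __post_init__(self) -> None:
        for name in ("hgop", "hgep", "vgop", "vgep"):
            if getattr(self, name) > 0:
                raise ScoringError(f"{name} must be <= 0")
        if abs(self.hgop) < abs(self.hgep):
            raise ScoringError("|hgop| must be >= |hgep|")
        if abs(self.vgop) < abs(self.vgep):
            raise ScoringError("|vgop| must be >= |vgep|")
        if np.any(self.matrix.table <= 0):
            raise ScoringError("matrix entries must be strictly positive")
        if not self.terminal_gaps_free:
            raise ScoringError("terminal gaps are always free in this engine")


def params_from_apsi(apsi_p: float) -> ScoringParams:
    """Default parameters as a function of starting-alignment identity.

    All six quantities vary linearly with APSI (percent, 0-100).  More
    similar families get a larger contrast coefficient and stiffer gap
    penalties (their columns deserve trust); diverged families get a larger
    flat bonus and softer penalties so residues can cheaply skip
    low-scoring positions.  Opening a gap in the profile is always costlier
    than opening one in the sequence, because the profile by construction
    already offers a position for every residue.
    """
    if not 0 <= apsi_p <= 100:
        raise ScoringError("apsi_p must be in [0, 100]")
    bonus = 250.0 - 0.5 * apsi_p
    coeff = 1.0 + apsi_p / 200.0
    matrix = adjust_matrix(base_hoxd(), bonus, coeff)
    return ScoringParams(
        matrix=matrix,
        hgop=-(100.0 + 2.0 * apsi_p),
        hgep=-(30.0 + 0.5 * apsi_p),
        vgop=-(50.0 + 1.0 * apsi_p),
        vgep=-(10.0 + 0.2 * apsi_p),
        bonus=bonus,
        coeff=coeff,
        apsi_p=float(apsi_p),
    )


def scale_gap_penalties(params: ScoringParams, seq_len: int, max_len: int) -> ScoringParams:
    """Per-sequence length scaling of all four gap penalties.

    Shorter sequences are penalized harder to avoid sparse, gap-riddled
    rows: each penalty is multiplied by ``2 - N/M`` where N is the length
    of the sequence being aligned and M the longest sequence in the set.
    The factor is 1 at N == M and approaches 2 for very short sequences.
    """
    if seq_len > max_len:
        raise ScoringError("sequence longer than stated maximum length")
    if seq_len < 1:
        raise ScoringError("sequence length must be >= 1")
    factor = 2.0 - seq_len / max_len
    return replace(
        params,
        hgop=params.hgop * factor,
        hgep=params.hgep * factor,
        vgop=params.vgop * factor,
        vgep=params.vgep * factor,
    )


def additive_score(pos, b: str, matrix: SubstitutionMatrix) -> float:
    """Count-weighted score of one profile position against residue ``b``.

    Returns sum over residues a of C_a * Sub(a, b), where C_a are the raw
    observed counts at the position.  Using counts rather than frequencies
    makes a deep conserved column score higher than a shallow one.
    """
    col = matrix.table[:, _IDX[b]]
    total = 0.0
    for a, c in pos.weights.items():
        total += c * col[_IDX[a]]
    return total


def position_gop(base_gop: float, pcr_i: float, ss_ij: float) -> float:
    """Position-specific gap opening penalty.

    The opening penalty grows linearly with the profile conservation rate
    of the position adjacent to the candidate gap, modulated by the
    substitution score of that cell: ``GOP_eff = GOP - PCR_i * SS_ij``.
    Well-supported columns thus become expensive to gap against, while the
    modulation vanishes for maximally diffuse positions.  Extensions are
    never modulated.
    """
    if not 0 < pcr_i <= 1:
        raise ScoringError("profile conservation rate must be in (0, 1]")
    return base_gop - pcr_i * ss_ij


def load_matrix(source: TextIO) -> SubstitutionMatrix:
    """Read a 4x4 whitespace-separated matrix with an A C G T header."""
    lines = [ln.split() for ln in source.read().splitlines() if ln.strip()]
    if not lines or [c.upper() for c in lines[0]] != list(ALPHABET):
        raise ScoringError("matrix file must start with an 'A C G T' header row")
    table = np.zeros((4, 4))
    if len(lines) != 5:
        raise ScoringError("matrix file must have four data rows")
    for r, row in enumerate(lines[1:]):
        if len(row) != 5 or row[0].upper() != ALPHABET[r]:
            raise ScoringError("matrix rows must be labelled A, C, G, T")
        table[r] = [float(x) for x in row[1:]]
    return SubstitutionMatrix(table)
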