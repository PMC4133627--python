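"""Count-weighted summarization profile of an alignment.

Each profile position tallies the non-gap residues of one alignment
column as raw counts (<Residue, Weight> pairs); gaps contribute nothing.
The profile is non-probabilistic on purpose: downstream scoring uses the
counts directly, so a column supported by many sequences dominates one
supported by few.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Sequence as Seq, TextIO, Tuple

import numpy as np

from .msa import ALPHABET, GAP, Alignment

logger = logging.getLogger(__name__)

_IDX = {c: i for i, c in enumerate(ALPHABET)}


class ProfileError(ValueError):
    """Raised on invalid profile construction or update requests."""


@dataclass(frozen=True)
class ProfilePosition:
    """Residue → count tally of one alignment column (gaps excluded)."""

    weights: Dict[str, int]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ProfileError("profile position has no residues")
        for r, w in self.weights.items():
            if r not in ALPHABET:
                raise ProfileError(f"non-canonical residue {r!r} in profile")
            if w < 1:
                raise ProfileError("profile weights must be >= 1")

    def total(self) -> int:
        return sum(self.weights.values())


@dataclass(frozen=True)
class Profile:
    """Ordered list of count-weighted positions."""

    positions: Tuple[ProfilePosition, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ProfileError("profile has no positions")

    def __len__(self) -> int:
        return len(self.positions)

    def counts(self) -> np.ndarray:
        """(n_positions, 4) integer count matrix in ACGT order."""
        out = np.zeros((len(self.positions), 4), dtype=float)
        for i, pos in enumerate(self.positions):
            for r, w in pos.weights.items():
                out[i, _IDX[r]] = w
        return out

    def conservation_rates(self) -> np.ndarray:
        return np.array([conservation_rate(p) for p in self.positions])

    def total_weight(self) -> int:
        return sum(p.total() for p in self.positions)


def build_profile(aln: Alignment) -> Profile:
    """Tally every column of an alignment into a profile.

    The profile has exactly one position per column; an all-gap column is
    rejected (strip void columns first).
    """
    positions = []
    for i in range(aln.n_columns):
        tally: Dict[str, int] = {}
        for _, gapped in aln.rows:
            c = gapped[i]
            if c != GAP:
                tally[c] = tally.get(c, 0) + 1
        if not tally:
            raise ProfileError(f"void column in input alignment (column {i + 1})")
        positions.append(ProfilePosition(tally))
    return Profile(tuple(positions))


def conservation_rate(pos: ProfilePosition) -> float:
    """Max residue count over total count; 1 iff single-residue position."""
    return max(pos.weights.values()) / pos.total()


def compute_apsi(aln: Alignment) -> float:
    """Percent average pairwise sequence identity of an alignment.

    Identity of a row pair = identical-residue columns / columns where both
    rows hold a residue; columns with a gap in either row are excluded from
    the denominator.  A pair with no co-ungapped column contributes 0 and
    logs a warning.
    """
    if aln.n_rows < 2:
        raise ProfileError("APSI needs at least two rows")
    idents = []
    for (ida, a), (idb, b) in combinations(aln.rows, 2):
        both = same = 0
        for x, y in zip(a, b):
            if x != GAP and y != GAP:
                both += 1
                if x == y:
                    same += 1
        if both == 0:
            logger.warning("rows %r and %r share no co-ungapped column", ida, idb)
            idents.append(0.0)
        else:
            idents.append(100.0 * same / both)
    return float(np.mean(idents))


Insertion = Tuple[int, str, str]  # (junction index, residues, source id)


def apply_insertions(prof: Profile, insertions: Seq[Insertion]) -> Profile:
    """Fine-tune a profile to host residues it could not previously align.

    Each insertion names a junction j (between positions j-1 and j; 0 and
    len(profile) are the termini) and the residues one sequence wants
    inserted there.  A junction receiving insertions from several sequences
    grows by the maximum insertion length; weights are merged per offset,
    left-anchored, each inserted residue contributing count 1.  Existing
    positions and weights are untouched.
    """
    n = len(prof.positions)
    by_junction: Dict[int, List[str]] = {}
    for j, residues, _src in insertions:
        if not 0 <= j <= n:
            raise ProfileError(f"insertion junction {j} out of range [0, {n}]")
        by_junction.setdefault(j, []).append(residues)
    if not by_junction:
        return prof

    out: List[ProfilePosition] = []
    for j in range(n + 1):
        for offset_tally in _merged_offsets(by_junction.get(j, [])):
            out.append(ProfilePosition(offset_tally))
        if j < n:
            out.append(prof.positions[j])
    return Profile(tuple(out))


def _merged_offsets(strings: List[str]) -> List[Dict[str, int]]:
    if not strings:
        return []
    width = max(len(s) for s in strings)
    tallies: List[Dict[str, int]] = [{} for _ in range(width)]
    for s in strings:
        for k, r in enumerate(s):
            tallies[k][r] = tallies[k].get(r, 0) + 1
    return tallies


def profile_to_tsv(prof: Profile, sink: TextIO) -> None:
    """Debug dump: one row per position with A/C/G/T counts and PCR."""
    sink.write("pos\tA\tC\tG\tT\tpcr\n")
    for i, pos in enumerate(prof.positions):
        counts = [pos.weights.get(r, 0) for r in ALPHABET]
        sink.write(
            f"{i}\t" + "\t".join(str(c) for c in counts)
            + f"\t{conservation_rate(pos):.4f}\n"
        )
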