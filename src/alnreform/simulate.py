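"""Synthetic sequence families with known true alignments.

Families are generated star-wise: a random ancestor is mutated
independently into each leaf by i.i.d. substitutions and
geometric-length indels.  Because every leaf descends directly from the
ancestor, homology bookkeeping is exact: each true-alignment column is
either one ancestor site (holding every leaf's residue surviving there)
or a single leaf's insertion (non-homologous, so it occupies its own
column).  A companion corrupter displaces gap blocks inside rows to mimic
the frozen-subalignment errors of progressive aligners, leaving the
underlying sequences untouched.

This deliberately ignores real evolutionary structure — no tree shape, no
transition/transversion bias, no rate heterogeneity, no secondary
structure — so tests exercise the machinery, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .msa import ALPHABET, GAP, Alignment, Sequence
from .reform import remove_void_columns


class SimulationError(ValueError):
    """Raised on invalid family specifications."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family."""

    n_sequences: int = 8
    ancestor_length: int = 100
    substitution_rate: float = 0.2
    indel_rate: float = 0.03
    mean_indel_length: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise SimulationError("need at least two sequences")
        if self.ancestor_length < 1 or self.mean_indel_length < 1:
            raise SimulationError("lengths must be >= 1")
        for r in (self.substitution_rate, self.indel_rate):
            if not 0 <= r < 1:
                raise SimulationError("rates must be in [0, 1)")


def simulate_family(spec: FamilySpec) -> Tuple[Alignment, List[Sequence]]:
    """Generate one family; returns (true alignment, ungapped sequences)."""
    rng = np.random.default_rng(spec.seed)
    A = spec.ancestor_length
    ancestor = "".join(rng.choice(list(ALPHABET), size=A))

    # per leaf: surviving residue (or None) per ancestor site, and
    # inserted residues per junction (junction j = before site j; j = A is
    # the tail)
    residues: List[Dict[int, str]] = []
    inserts: List[Dict[int, str]] = []
    for _ in range(spec.n_sequences):
        res: Dict[int, str] = {}
        ins: Dict[int, str] = {}
        site = 0
        while site < A:
            if rng.random() < spec.indel_rate:
                length = int(rng.geometric(1.0 / spec.mean_indel_length))
                if rng.random() < 0.5:
                    ins[site] = "".join(rng.choice(list(ALPHABET), size=length))
                else:
                    site += length  # deletion: skip sites
                    continue
            base = ancestor[site]
            if rng.random() < spec.substitution_rate:
                base = rng.choice([c for c in ALPHABET if c != base])
            res[site] = base
            site += 1
        if rng.random() < spec.indel_rate:
            length = int(rng.geometric(1.0 / spec.mean_indel_length))
            ins[A] = "".join(rng.choice(list(ALPHABET), size=length))
        if not res and not ins:
            res[0] = ancestor[0]  # guard: a leaf must keep something
        residues.append(res)
        inserts.append(ins)

    columns: List[str] = []
    for j in range(A + 1):
        for leaf in range(spec.n_sequences):
            for r in inserts[leaf].get(j, ""):
                col = [GAP] * spec.n_sequences
                col[leaf] = r
                columns.append("".join(col))
        if j < A:
            col = [residues[leaf].get(j, GAP) for leaf in range(spec.n_sequences)]
            columns.append("".join(col))

    rows = []
    for leaf in range(spec.n_sequences):
        gapped = "".join(col[leaf] for col in columns)
        rows.append((f"seq{leaf + 1}", gapped))
    truth = remove_void_columns(Alignment(tuple(rows)))
    seqs = [
        Sequence(sid, gapped.replace(GAP, "")) for sid, gapped in truth.rows
    ]
    return truth, seqs


def corrupt_alignment(aln: Alignment, n_moves: int, seed: int) -> Alignment:
    """Displace random gap blocks within rows.

    Each move removes one maximal gap run from a random row and reinserts
    the whole block at a random offset of that row, preserving the row's
    residues and length.  Rows without gaps are left alone.
    """
    rng = np.random.default_rng(seed)
    rows = [list(g) for _, g in aln.rows]
    ids = [sid for sid, _ in aln.rows]
    for _ in range(n_moves):
        order = rng.permutation(len(rows))
        for k in order:
            row = rows[k]
            runs = _gap_runs(row)
            if not runs:
                continue
            start, length = runs[rng.integers(len(runs))]
            rest = row[:start] + row[start + length:]
            pos = int(rng.integers(len(rest) + 1))
            rows[k] = rest[:pos] + [GAP] * length + rest[pos:]
            break
    return Alignment(
        tuple((sid, "".join(r)) for sid, r in zip(ids, rows)), aln.rna_flags
    )


def _gap_runs(row: List[str]) -> List[Tuple[int, int]]:
    runs = []
    i = 0
    while i < len(row):
        if row[i] == GAP:
            j = i
            while j < len(row) and row[j] == GAP:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs
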