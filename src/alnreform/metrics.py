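"""Alignment accuracy scoring against a reference.

Three standard benchmark measures are computed: the sum-of-pairs /
developer score f_D (correctly aligned residue pairs over reference
pairs), the modeler score f_M (same numerator over test pairs), and the
total-column score TC (reference columns whose residue content is
reproduced intact as a column of the test alignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, List, Set, Tuple

from .msa import GAP, Alignment, degap

logger = logging.getLogger(__name__)

ResiduePair = Tuple[Tuple[str, int], Tuple[str, int]]


class MetricsError(ValueError):
    """Raised when two alignments are not comparable."""


@dataclass(frozen=True)
class AccuracyReport:
    sp: float
    modeler: float
    tc: float


def residue_pairs(aln: Alignment) -> Set[ResiduePair]:
    """All aligned residue pairs of an alignment.

    A pair is ((id_a, k_a), (id_b, k_b)): two rows placing their k_a-th and
    k_b-th residues (ungapped indices) in the same column.  Pairs are
    unordered; the two endpoints are stored sorted by id.
    """
    pairs: Set[ResiduePair] = set()
    cursors = {sid: 0 for sid, _ in aln.rows}
    for col in range(aln.n_columns):
        placed = []
        for sid, g in aln.rows:
            if g[col] != GAP:
                placed.append((sid, cursors[sid]))
                cursors[sid] += 1
        for a, b in combinations(sorted(placed), 2):
            pairs.add((a, b))
    return pairs


def _column_contents(aln: Alignment) -> List[FrozenSet[Tuple[str, int]]]:
    cols: List[FrozenSet[Tuple[str, int]]] = []
    cursors = {sid: 0 for sid, _ in aln.rows}
    for col in range(aln.n_columns):
        placed = []
        for sid, g in aln.rows:
            if g[col] != GAP:
                placed.append((sid, cursors[sid]))
                cursors[sid] += 1
        cols.append(frozenset(placed))
    return cols


def score_alignment(test: Alignment, ref: Alignment) -> AccuracyReport:
    """Score a test alignment against a reference.

    Both must hold the same sequences (same ids, identical after
    degapping); row order may differ.  Reference columns and pairs define
    the denominators of TC and f_D respectively.
    """
    test_seqs = {s.id: s.residues for s in degap(test)}
    ref_seqs = {s.id: s.residues for s in degap(ref)}
    if test_seqs != ref_seqs:
        raise MetricsError("alignments not comparable (ids or sequences differ)")

    ref_pairs = residue_pairs(ref)
    test_pairs = residue_pairs(test)
    common = len(ref_pairs & test_pairs)

    if ref_pairs:
        sp = common / len(ref_pairs)
    else:
        sp = 1.0 if not test_pairs else 0.0
        logger.warning("reference alignment has no residue pairs")
    if test_pairs:
        modeler = common / len(test_pairs)
    else:
        modeler = 1.0 if not ref_pairs else 0.0
        logger.warning("test alignment has no residue pairs")

    test_cols = set(_column_contents(test))
    ref_cols = _column_contents(ref)
    tc = sum(1 for c in ref_cols if c in test_cols) / len(ref_cols)
    return AccuracyReport(sp=sp, modeler=modeler, tc=tc)
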