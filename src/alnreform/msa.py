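"""Core alignment data model and aligned-FASTA I/O.

Sequences are stored over the canonical DNA alphabet ``{A, C, G, T}``;
RNA input (``U``) is accepted and mapped to ``T`` at parse time, with a
per-record flag so output restores the original alphabet.  Gap characters
``-`` and ``.`` are accepted on input; ``-`` is always emitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, List, TextIO, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
GAP = "-"

_VALID_INPUT = set("ACGTU.-acgtu")


class MsaError(ValueError):
    """Raised on malformed alignment input or invariant violations."""


@dataclass(frozen=True)
class Sequence:
    """An ungapped nucleotide sequence.

    ``rna`` records whether the source record used U, so that writers can
    restore the original alphabet.
    """

    id: str
    residues: str
    rna: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise MsaError(f"empty sequence after degapping: {self.id!r}")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise MsaError(
                f"unsupported ambiguous or non-nucleotide character in "
                f"{self.id!r}: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped rows."""

    rows: Tuple[Tuple[str, str], ...]
    rna_flags: Tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.rows:
            raise MsaError("alignment has no rows")
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) != 1:
            raise MsaError("unequal alignment row lengths")
        if next(iter(lengths)) < 1:
            raise MsaError("alignment rows are empty")
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise MsaError("duplicate sequence ids in alignment")
        if not self.rna_flags:
            object.__setattr__(self, "rna_flags", (False,) * len(self.rows))
        if len(self.rna_flags) != len(self.rows):
            raise MsaError("rna_flags length mismatch")
        for sid, g in self.rows:
            bad = set(g) - set(ALPHABET + GAP)
            if bad:
                raise MsaError(
                    f"unsupported ambiguous or non-nucleotide character in "
                    f"{sid!r}: {sorted(bad)!r}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def column(self, i: int) -> str:
        return "".join(g[i] for _, g in self.rows)

    def __iter__(self):
        return iter(self.rows)


def _normalize(raw: str, sid: str) -> Tuple[str, bool]:
    bad = set(raw) - _VALID_INPUT
    if bad:
        raise MsaError(
            f"unsupported ambiguous or non-nucleotide character in "
            f"{sid!r}: {sorted(bad)!r}"
        )
    up = raw.upper().replace(".", GAP)
    rna = "U" in up
    return up.replace("U", "T"), rna


def read_aligned_fasta(source: TextIO | str) -> Alignment:
    """Parse an aligned FASTA stream into an :class:`Alignment`.

    Accepts ``-`` and ``.`` as gaps, upper/lower case, and RNA (U) records.
    Raises :class:`MsaError` on ragged rows, fewer than two records, or any
    ambiguity code (N, R, Y, ...), which the engine does not support.
    """
    handle = io.StringIO(source) if isinstance(source, str) else source
    rows: List[Tuple[str, str]] = []
    flags: List[bool] = []
    for rec in SeqIO.parse(handle, "fasta"):
        label = rec.description if rec.description else rec.id
        gapped, rna = _normalize(str(rec.seq), label)
        rows.append((label, gapped))
        flags.append(rna)
    if len(rows) < 2:
        raise MsaError("need at least two sequences")
    lengths = {len(g) for _, g in rows}
    if len(lengths) != 1:
        raise MsaError("unequal alignment row lengths")
    return Alignment(tuple(rows), tuple(flags))


def write_aligned_fasta(aln: Alignment, sink: TextIO) -> None:
    """Write an alignment as FASTA, wrapped at 60 columns.

    Rows flagged as RNA are written back with U in place of T.
    """
    records = []
    for (sid, gapped), rna in zip(aln.rows, aln.rna_flags):
        out = gapped.replace("T", "U") if rna else gapped
        records.append(SeqRecord(Seq(out), id=sid, description=""))
    SeqIO.write(records, sink, "fasta")


def degap(aln: Alignment) -> List[Sequence]:
    """Strip gaps from every row, preserving order.

    Raises :class:`MsaError` if any row is entirely gaps.
    """
    out = []
    for (sid, gapped), rna in zip(aln.rows, aln.rna_flags):
        residues = gapped.replace(GAP, "")
        if not residues:
            raise MsaError(f"empty sequence after degapping: {sid!r}")
        out.append(Sequence(sid, residues, rna))
    return out


def alignment_from_rows(
    rows: Iterable[Tuple[str, str]], rna_flags: Iterable[bool] | None = None
) -> Alignment:
    """Convenience constructor from (id, gapped-string) pairs."""
    rows = tuple(rows)
    flags = tuple(rna_flags) if rna_flags is not None else (False,) * len(rows)
    return Alignment(rows, flags)
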