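"""Sequence-to-profile Gotoh alignment with free terminal gaps.

A single sequence is aligned globally against the profile with affine gap
penalties under maximization.  Three DP layers are kept: M (profile
position matched to a sequence residue), SEQGAP (profile position consumed
against a gap in the sequence, penalized by VGOP/VGEP) and PROFGAP (a
sequence residue inserted between profile positions, penalized by
HGOP/HGEP).  Gap openings are position-specific: the base opening penalty
is deepened by ``PCR_i * SS_ij`` of the adjacent cell (see
:func:`alnreform.scoring.position_gop`); extensions are flat.  Terminal
gap runs — profile positions skipped before the first or after the last
consumed sequence residue, and sequence residues overhanging before the
first or after the last consumed profile position — are free.

The fill is a numba-compiled kernel; traceback walks the stored matrices
in Python with the deterministic step preference MATCH > SEQGAP > PROFGAP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Tuple, Union

import numpy as np
from numba import njit

from .msa import Sequence
from .profile import Insertion, Profile
from .scoring import ScoringParams, _IDX


class PairwiseError(ValueError):
    """Raised on invalid alignment requests or broken traces."""


class Match(NamedTuple):
    """Profile position ``i`` aligned to sequence residue ``j`` (0-based)."""

    i: int
    j: int


class SeqGap(NamedTuple):
    """Profile position ``i`` consumed against a gap in the sequence."""

    i: int


class ProfGap(NamedTuple):
    """Sequence residue ``j`` inserted at profile junction ``junction``."""

    j: int
    junction: int


Step = Union[Match, SeqGap, ProfGap]

_NEG = -1e30


@dataclass(frozen=True)
class PairwiseTrace:
    """One sequence's optimal path through the profile."""

    steps: Tuple[Step, ...]
    score: float

    def insertion_free(self) -> bool:
        return not any(isinstance(s, ProfGap) for s in self.steps)


@njit(cache=True)
def _gotoh_fill(S, pcr, hgop, hgep, vgop, vgep):  # pragma: no cover - numba
    P, N = S.shape
    M = np.full((P + 1, N + 1), _NEG)
    Ix = np.full((P + 1, N + 1), _NEG)  # PROFGAP layer (gap in profile)
    Iy = np.full((P + 1, N + 1), _NEG)  # SEQGAP layer (gap in sequence)
    M[0, 0] = 0.0
    for j in range(1, N + 1):
        Ix[0, j] = 0.0  # free leading sequence overhang
    for i in range(1, P + 1):
        Iy[i, 0] = 0.0  # free leading profile skip
    for i in range(1, P + 1):
        for j in range(1, N + 1):
            s = S[i - 1, j - 1]
            b = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > b:
                b = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > b:
                b = Iy[i - 1, j - 1]
            M[i, j] = b + s
            mod = pcr[i - 1] * s
            a = M[i - 1, j]
            if Ix[i - 1, j] > a:
                a = Ix[i - 1, j]
            open_v = a + (vgop - mod)
            ext_v = Iy[i - 1, j] + vgep
            Iy[i, j] = open_v if open_v > ext_v else ext_v
            a = M[i, j - 1]
            if Iy[i, j - 1] > a:
                a = Iy[i, j - 1]
            open_h = a + (hgop - mod)
            ext_h = Ix[i, j - 1] + hgep
            Ix[i, j] = open_h if open_h > ext_h else ext_h
    return M, Ix, Iy


def _pick_state(M, Ix, Iy, i, j) -> Tuple[str, float]:
    # step preference MATCH > SEQGAP > PROFGAP
    best = max(M[i, j], Iy[i, j], Ix[i, j])
    if M[i, j] == best:
        return "M", best
    if Iy[i, j] == best:
        return "Y", best
    return "X", best


def _endpoint(M, Ix, Iy, P, N) -> Tuple[int, int, float]:
    bi, bj = P, N
    _, bval = _pick_state(M, Ix, Iy, P, N)
    for i in range(P - 1, -1, -1):  # trailing profile skip free
        _, v = _pick_state(M, Ix, Iy, i, N)
        if v > bval:
            bi, bj, bval = i, N, v
    for j in range(N - 1, -1, -1):  # trailing sequence overhang free
        _, v = _pick_state(M, Ix, Iy, P, j)
        if v > bval:
            bi, bj, bval = P, j, v
    return bi, bj, bval


def align_to_profile(
    seq: Sequence, prof: Profile, params: ScoringParams
) -> PairwiseTrace:
    """Optimal affine free-end-gap alignment of ``seq`` against ``prof``.

    ``params`` must already be length-scaled for this sequence.  The
    returned trace consumes every profile position (by MATCH or SEQGAP)
    and every sequence residue (by MATCH or PROFGAP), in order.
    """
    if len(prof) == 0:
        raise PairwiseError("empty profile")
    counts = prof.counts()
    codes = np.array([_IDX[c] for c in seq.residues], dtype=np.int64)
    S = counts @ params.matrix.table[:, codes]
    pcr = prof.conservation_rates()
    M, Ix, Iy = _gotoh_fill(
        S, pcr, params.hgop, params.hgep, params.vgop, params.vgep
    )
    P, N = S.shape
    ei, ej, score = _endpoint(M, Ix, Iy, P, N)

    trailing: List[Step] = []
    if ej == N and ei < P:
        trailing = [SeqGap(i) for i in range(ei, P)]
    elif ei == P and ej < N:
        trailing = [ProfGap(j, P) for j in range(ej, N)]

    rev: List[Step] = []
    i, j = ei, ej
    state, _ = _pick_state(M, Ix, Iy, i, j)
    while i > 0 or j > 0:
        if state == "M":
            rev.append(Match(i - 1, j - 1))
            i, j = i - 1, j - 1
            # kernel took max over the three predecessor layers, so the
            # argmax of the stored values identifies an optimal source
            state, _ = _pick_state(M, Ix, Iy, i, j)
        elif state == "Y":
            rev.append(SeqGap(i - 1))
            if j == 0:  # free leading profile skip
                i -= 1
                state = "Y" if i > 0 else "M"
                continue
            vo = params.vgop - pcr[i - 1] * S[i - 1, j - 1]
            here = Iy[i, j]
            if here == Iy[i - 1, j] + params.vgep:
                state = "Y"
            elif here == M[i - 1, j] + vo:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:  # state == "X"
            rev.append(ProfGap(j - 1, i))
            if i == 0:  # free leading sequence overhang
                j -= 1
                state = "X" if j > 0 else "M"
                continue
            ho = params.hgop - pcr[i - 1] * S[i - 1, j - 1]
            here = Ix[i, j]
            if here == Ix[i, j - 1] + params.hgep:
                state = "X"
            elif here == M[i, j - 1] + ho:
                state = "M"
            else:
                state = "Y"
            j -= 1

    steps = tuple(reversed(rev)) + tuple(trailing)
    _check_trace(steps, P, N)
    return PairwiseTrace(steps, float(score))


def _check_trace(steps: Tuple[Step, ...], P: int, N: int) -> None:
    """Internal contract: both sides consumed exactly once, in order."""
    prof_seen = []
    seq_seen = []
    junctions = []
    for s in steps:
        if isinstance(s, Match):
            prof_seen.append(s.i)
            seq_seen.append(s.j)
        elif isinstance(s, SeqGap):
            prof_seen.append(s.i)
        else:
            seq_seen.append(s.j)
            junctions.append(s.junction)
    if prof_seen != list(range(P)):
        raise PairwiseError("trace does not cover profile positions in order")
    if seq_seen != list(range(N)):
        raise PairwiseError("trace does not cover sequence residues in order")
    if junctions != sorted(junctions):
        raise PairwiseError("trace junctions are not non-decreasing")


def extract_insertions(trace: PairwiseTrace, seq: Sequence) -> List[Insertion]:
    """Read maximal PROFGAP runs off a trace as profile insertion requests.

    Returns one (junction, residues, source-id) record per run, in junction
    order; terminal overhangs appear at junctions 0 and len(profile).
    """
    out: List[Insertion] = []
    run: List[str] = []
    run_junction = -1
    for step in trace.steps:
        if isinstance(step, ProfGap):
            if run and step.junction != run_junction:
                out.append((run_junction, "".join(run), seq.id))
                run = []
            run_junction = step.junction
            run.append(seq.residues[step.j])
        else:
            if run:
                out.append((run_junction, "".join(run), seq.id))
                run = []
    if run:
        out.append((run_junction, "".join(run), seq.id))
    return out
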