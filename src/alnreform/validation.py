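"""Exhaustive reference scorers for tiny alignment instances.

These enumerate *every* monotone sequence-profile path and score it by
first principles, sharing no code with the dynamic-programming engine.
They are exponential and only usable for instances of a handful of
positions; their purpose is to certify the engine on small cases.

Scoring rules mirrored here, stated independently:

* a MATCH of profile position i with sequence residue j earns ``S[i, j]``;
* gap steps come in maximal runs; a run's first step pays the opening
  penalty (VGOP for a skipped profile position, HGOP for an inserted
  sequence residue) deepened by ``PCR * S`` of the adjacent cell, and each
  further step pays the flat extension (VGEP / HGEP);
* a run of skipped profile positions is free when the sequence cursor sits
  at either end (no residue consumed yet, or all consumed); a run of
  inserted residues is free when the profile cursor sits at either end.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np


def brute_force_best_score(
    S: np.ndarray,
    pcr: np.ndarray,
    hgop: float,
    hgep: float,
    vgop: float,
    vgep: float,
) -> float:
    """Maximum score over all monotone paths, by explicit enumeration."""
    P, N = S.shape
    best = [-np.inf]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == P and j == N:
            if score > best[0]:
                best[0] = score
            return
        if i < P and j < N:
            rec(i + 1, j + 1, score + S[i, j], "M")
        if i < P:  # skip profile position i (gap in the sequence)
            if j == 0 or j == N:
                cost = 0.0
            elif last == "Y":
                cost = vgep
            else:
                cost = vgop - pcr[i] * S[i, j - 1]
            rec(i + 1, j, score + cost, "Y")
        if j < N:  # insert sequence residue j (gap in the profile)
            if i == 0 or i == P:
                cost = 0.0
            elif last == "X":
                cost = hgep
            else:
                cost = hgop - pcr[i - 1] * S[i - 1, j]
            rec(i, j + 1, score + cost, "X")

    rec(0, 0, 0.0, "start")
    return float(best[0])


def score_trace(
    steps,
    S: np.ndarray,
    pcr: np.ndarray,
    hgop: float,
    hgep: float,
    vgop: float,
    vgep: float,
) -> float:
    """Score an explicit step list under the same first-principles rules.

    Steps are the engine's Match/SeqGap/ProfGap records (matched on field
    layout, not on type identity, to stay independent of the engine).
    """
    P, N = S.shape
    i = j = 0
    total = 0.0
    last = "start"
    for step in steps:
        fields = step._fields if hasattr(step, "_fields") else ()
        if fields == ("i", "j"):  # Match
            total += S[step.i, step.j]
            i, j = step.i + 1, step.j + 1
            last = "M"
        elif fields == ("i",):  # SeqGap
            if j == 0 or j == N:
                pass
            elif last == "Y":
                total += vgep
            else:
                total += vgop - pcr[step.i] * S[step.i, j - 1]
            i = step.i + 1
            last = "Y"
        else:  # ProfGap
            if i == 0 or i == P:
                pass
            elif last == "X":
                total += hgep
            else:
                total += hgop - pcr[i - 1] * S[i - 1, step.j]
            j = step.j + 1
            last = "X"
    return float(total)


def random_tiny_instance(
    rng: np.random.Generator,
    max_positions: int = 5,
    max_residues: int = 5,
    max_weight: int = 4,
) -> Tuple[np.ndarray, np.ndarray, float, float, float, float]:
    """A random small (S, pcr, penalties) instance with valid parameters.

    The score matrix is strictly positive, penalties are non-positive with
    |open| >= |extend| and |HGOP| >= |VGOP|, and pcr values derive from
    random integer count columns, as in a real profile.
    """
    P = int(rng.integers(1, max_positions + 1))
    N = int(rng.integers(1, max_residues + 1))
    sub = rng.integers(1, 40, size=(4, 4)).astype(float)
    sub = (sub + sub.T) / 2.0
    counts = np.zeros((P, 4))
    for i in range(P):
        k = int(rng.integers(1, 4))
        for _ in range(k):
            counts[i, rng.integers(4)] += rng.integers(1, max_weight + 1)
    codes = rng.integers(4, size=N)
    S = counts @ sub[:, codes]
    pcr = counts.max(axis=1) / counts.sum(axis=1)
    vgop = -float(rng.integers(0, 60))
    hgop = vgop - float(rng.integers(0, 60))
    vgep = -float(rng.integers(0, int(-vgop) + 1))
    hgep = -float(rng.integers(0, int(-hgop) + 1))
    return S, pcr, hgop, hgep, vgop, vgep
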