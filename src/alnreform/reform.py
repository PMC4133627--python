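"""The meta-alignment driver.

One outer iteration: strip void columns, derive parameters from the
current alignment's APSI (unless overridden), build the profile, align
every sequence against it (growing the profile where sequences demand
insertions), merge the per-sequence traces into a new alignment, and strip
void columns again.  Iteration stops when an iteration reproduces its
input exactly or the iteration cap is reached.

Profile fine-tuning is batched: all insertions found in a full pass over
the sequences are applied to the profile at once, then the pass restarts.
This makes the result independent of sequence processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .msa import GAP, Alignment, Sequence, degap
from .pairwise import Match, PairwiseTrace, ProfGap, align_to_profile, extract_insertions
from .profile import Profile, apply_insertions, build_profile, compute_apsi
from .scoring import ScoringParams, params_from_apsi, scale_gap_penalties

logger = logging.getLogger(__name__)


class ReformError(RuntimeError):
    """Raised when the driver's contracts are violated."""


@dataclass(frozen=True)
class ReformConfig:
    """Driver knobs.

    ``max_iterations`` caps outer refinement iterations (default 5);
    ``max_finetune_rounds`` is a safeguard on profile-growth restarts
    within one pass, which a sane parameterization never approaches.
    """

    max_iterations: int = 5
    max_finetune_rounds: int = 20
    params_override: Optional[ScoringParams] = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ReformError("max_iterations must be >= 1")
        if self.max_finetune_rounds < 1:
            raise ReformError("max_finetune_rounds must be >= 1")


def sequence_alignment_pass(
    seqs: List[Sequence],
    prof: Profile,
    params: ScoringParams,
    max_finetune_rounds: int = 20,
) -> Tuple[Profile, List[PairwiseTrace]]:
    """Align every sequence against the profile, fine-tuning on insertions.

    Each sequence gets gap penalties scaled by its length relative to the
    longest sequence in the set.  If any optimal trace inserts residues the
    profile cannot host, all insertions of the pass are applied in one
    batch and the pass restarts with the enlarged profile.  Returns the
    final profile and insertion-free traces against it.
    """
    if not seqs:
        raise ReformError("no sequences to align")
    max_len = max(len(s) for s in seqs)
    for round_no in range(max_finetune_rounds):
        traces: List[PairwiseTrace] = []
        insertions = []
        offenders = []
        for seq in seqs:
            scaled = scale_gap_penalties(params, len(seq), max_len)
            trace = align_to_profile(seq, prof, scaled)
            ins = extract_insertions(trace, seq)
            if ins:
                insertions.extend(ins)
                offenders.append(seq.id)
            traces.append(trace)
        if not insertions:
            return prof, traces
        logger.debug(
            "fine-tune round %d: %d insertion(s) from %d sequence(s)",
            round_no + 1, len(insertions), len(offenders),
        )
        insertions.sort(key=lambda rec: rec[0])
        prof = apply_insertions(prof, insertions)
    raise ReformError(
        "profile fine-tuning did not settle within "
        f"{max_finetune_rounds} rounds; offending sequences: {offenders}. "
        "Gap penalties are likely too harsh relative to substitution scores."
    )


def merge_traces(
    prof: Profile, traces: List[PairwiseTrace], seqs: List[Sequence]
) -> Alignment:
    """Join insertion-free traces into one alignment over the profile.

    The output has one column per profile position; row k holds sequence
    k's residue wherever its trace matches that position, and a gap
    wherever its trace skips it.
    """
    n_cols = len(prof)
    rows = []
    for trace, seq in zip(traces, seqs):
        cells = [GAP] * n_cols
        for step in trace.steps:
            if isinstance(step, ProfGap):
                raise ReformError(
                    f"trace for {seq.id!r} contains profile insertions; "
                    "run sequence_alignment_pass first"
                )
            if isinstance(step, Match):
                cells[step.i] = seq.residues[step.j]
        rows.append((seq.id, "".join(cells)))
    return Alignment(tuple(rows), tuple(s.rna for s in seqs))


def remove_void_columns(aln: Alignment) -> Alignment:
    """Drop columns that consist entirely of gaps."""
    keep = [
        i for i in range(aln.n_columns)
        if any(g[i] != GAP for _, g in aln.rows)
    ]
    if len(keep) == aln.n_columns:
        return aln
    rows = tuple(
        (sid, "".join(g[i] for i in keep)) for sid, g in aln.rows
    )
    return Alignment(rows, aln.rna_flags)


def reform(initial: Alignment, config: ReformConfig = ReformConfig()) -> Alignment:
    """Iteratively realign every sequence against the alignment's profile.

    Returns the reformed alignment; its rows degap to exactly the input
    sequences, in order, and it contains no void columns.
    """
    current = remove_void_columns(initial)
    for iteration in range(1, config.max_iterations + 1):
        seqs = degap(current)
        if config.params_override is not None:
            params = config.params_override
        else:
            params = params_from_apsi(compute_apsi(current))
        prof = build_profile(current)
        prof, traces = sequence_alignment_pass(
            seqs, prof, params, config.max_finetune_rounds
        )
        new = remove_void_columns(merge_traces(prof, traces, seqs))
        logger.info(
            "iteration %d: APSI %.2f, profile length %d, %d column(s)",
            iteration, params.apsi_p, len(prof), new.n_columns,
        )
        if new == current:
            logger.info("converged after %d iteration(s)", iteration)
            return new
        current = new
    logger.info("stopped at iteration cap (%d)", config.max_iterations)
    return current
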