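# Methods

## Model

`alnreform` treats an existing nucleotide alignment as a hypothesis to be
revisited, not a constraint to be respected. The alignment is condensed
into a *non-probabilistic profile*: one position per column, each holding
the raw residue counts of that column. Raw counts (rather than
frequencies) are the point of the model — a column of eight concordant
cytosines and a column holding a single cytosine would look identical to
a frequency profile, but under the additive score

    S(i, b) = Σ_{a ∈ {A,C,G,T}} C_a(i) · Sub(a, b)

the deep column scores eight times higher, so realignment gravitates
toward well-supported columns. Every sequence is then aligned against the
profile independently with Gotoh's three-state affine dynamic program
(match / gap-in-sequence / gap-in-profile) under maximization, with free
terminal gaps realized by zero-cost first row/column of the gap layers
and a free exit along the last row/column. Because each sequence is
realigned against the *whole* family's evidence, an individual row's
frozen errors can be undone even though no sequence-sequence comparison
is ever repeated. The merged result — one output column per profile
position, all-gap columns dropped — is fed back in until a fixed point or
an iteration cap.

Assumptions worth stating: columns are treated independently (no
secondary-structure or neighbour coupling); the profile is built from the
current alignment including each sequence's own contribution (a position
may legitimately be supported by the very sequence being realigned); and
the starting alignment is taken to be roughly right, since it seeds both
the profile and the parameter choice.

## Parameters

All defaults derive from the APSI (average pairwise percent identity) of
the current alignment, recomputed at each outer iteration. Pairwise
identity is identical co-ungapped columns over co-ungapped columns;
columns with a gap in either row are excluded from the denominator.

The prose constraints the parameter system must satisfy are: substitution
scores strictly positive and substantially above the gap penalties;
penalties non-positive with |open| ≥ |extend| in both orientations;
opening a gap in the profile costlier than in the sequence
(|HGOP| ≥ |VGOP|); shorter sequences penalized harder; terminal gaps
free. The concrete functional forms below are this package's own
calibration, chosen once as simple linear forms satisfying all of those
constraints across the full APSI range (`a` = APSI in percent):

| quantity | form      | range (a = 0 → 100) |
|----------|-----------|----------------------|
| bonus    | 250 − a/2 | 250 → 200 |
| Coeff    | 1 + a/200 | 1.0 → 1.5 |
| HGOP     | −(100 + 2a) | −100 → −300 |
| HGEP     | −(30 + a/2) | −30 → −80 |
| VGOP     | −(50 + a)   | −50 → −150 |
| VGEP     | −(10 + a/5) | −10 → −30 |

The substitution matrix is HOXD70 rescaled as `Sub' = Sub·Coeff + bonus`.
The multiplicative Coeff restores the match/mismatch contrast that a
uniform additive bonus flattens (Coeff = 1 is a pure shift); at a = 100
the smallest entry is −125·1.5 + 200 = 12.5, so positivity holds
everywhere. Direction of the trends: similar families get more contrast
and stiffer penalties (their columns deserve trust), diverged families
get softer penalties so residues can cheaply skip low-scoring positions.

Two runtime modifiers apply on top:

* **Length scaling.** All four penalties are multiplied by `2 − N/M`
  (N = sequence length, M = longest sequence in the set): identity at
  N = M, at most ×2 for very short sequences, monotone in N. This
  discourages sparse gap-riddled placements of short sequences.
* **Position-specific openings.** `GOP_eff(i,j) = GOP − PCR_i · S(i,j)`,
  where PCR is max weight over total weight at the position and S is the
  additive cell score under the adjusted matrix. Openings against deep
  conserved columns therefore scale with the evidence for the column;
  extensions stay flat. For a gap in the sequence the modulating cell is
  the skipped position against the last consumed residue; for a gap in
  the profile it is the left-adjacent profile position against the
  inserted residue (the left-adjacent convention is a documented choice —
  nothing pins the adjacent side).

User-supplied parameters (CLI flags or a matrix file) bypass the APSI
machinery entirely; unspecified members fall back to the APSI-50
defaults.

## Numerical and procedural choices

* The DP runs in float64; the fill is a numba-compiled kernel, the
  traceback a Python walk over the stored matrices. Traceback decisions
  recompute candidate sums with the exact operations the kernel used, so
  float comparisons are exact and runs are bit-reproducible.
* Tie-breaking: the step preference is MATCH > gap-in-sequence >
  gap-in-profile (biasing against profile growth); among equal-scoring
  gap predecessors, extension is preferred over opening. Endpoint ties
  prefer the corner, then longer matched spans.
* Profile fine-tuning is *batched*: insertions from all sequences in a
  pass are applied at once (same-junction insertions merge per offset,
  left-anchored, max length wins), then the pass restarts. The result is
  independent of sequence processing order — the serial driver and any
  parallel schedule would agree. Newly created positions start with
  weight 1 per inserting sequence; existing positions are never
  re-tallied mid-pass. A safeguard (default 20 rounds per pass) raises an
  error naming the offending sequences if fine-tuning fails to settle,
  which only happens when gap penalties rival the substitution scores.
* Convergence compares each iteration's output with its input by exact
  string equality; under determinism this is equivalent to comparing two
  successive outputs, one pass cheaper. Termination is unconditionally
  bounded by max_iterations × max_finetune_rounds.
* Degenerate inputs: alignments need ≥ 2 rows; all-gap rows and all-gap
  columns at profile construction are errors (the driver strips void
  columns before building profiles); ambiguity codes are rejected
  outright rather than guessed at.
* Accuracy metrics: TC compares column *content* — the set of
  (sequence, residue-index) placements — so a reference column counts as
  recovered wherever it reappears, regardless of its column index. If
  the reference has no residue pairs at all, SP is defined as 1 when the
  test has none either, else 0 (and logged); symmetrically for the
  modeler score.

## The synthetic-data generator

Families are simulated star-wise from a random ancestor (default: 8
sequences, 100 nt ancestor, substitution rate 0.2/site, indel rate
0.03/site, geometric indel lengths with mean 2). Star topology keeps
homology bookkeeping exact: each true column is one ancestor site or one
leaf's private insertion. The corrupter displaces whole gap blocks within
rows, emulating the frozen-subalignment errors of progressive aligners
while preserving the sequences exactly.

What this does *not* emulate: tree-shaped relatedness (correlated errors
between sister taxa), transition/transversion bias, rate heterogeneity
across sites, RNA secondary structure, and real benchmark gap structure.
Passing tests therefore certify the machinery — optimality of the DP,
conservation, determinism, metric correctness, and recovery of
majority-supported columns — not performance on real curated benchmarks,
which requires external data (see `scripts/benchmark_check.py`).

## Problem sizes used by the test and acceptance runs

Exhaustive-oracle checks enumerate all alignments at ≤ 5 profile
positions × ≤ 5 residues (hundreds of instances); conservation and
invariant fuzzing uses families of 5–15 sequences × 50–200 nt (100
replicates); the recovery experiment uses 30 families of 8 × 100 nt at
substitution rate 0.3 (≈ 40–60% APSI) corrupted by 10 gap-block moves.
These sizes exercise every code path and keep the whole suite in the
tens of seconds on one CPU.

## Known limitations

* Nucleotides only; proteins and ambiguity codes are out of scope.
* The calibration table above was not fitted to any benchmark; it is a
  constraint-satisfying default, and users with tuned parameters should
  pass them explicitly.
* Quality can only be as good as the profile: if the starting alignment
  is mostly wrong, the majority signal the profile encodes is itself
  wrong, and iteration will converge to a confidently wrong fixed point.
* The aligner is O(L·N) time and memory per sequence per pass with no
  banding; very long alignments (≫ 10 kb) will be slow.
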