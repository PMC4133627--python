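#!/usr/bin/env python
"""External-data integration check (optional; requires user-supplied data).

Given a reference alignment and an initial alignment of the same sequences
produced by any aligner of your choice, this script reforms the initial
alignment and reports SP/modeler/TC before and after, plus the sign of the
SP change.  Nothing is downloaded: you must supply the files yourself
(e.g. a family from a public RNA alignment benchmark plus the output of
MAFFT or MUSCLE on its ungapped sequences).

Usage:
    python scripts/benchmark_check.py --initial init.fasta --ref ref.fasta
"""

from __future__ import annotations

import argparse

from alnreform import read_aligned_fasta, reform, score_alignment


def main(argv=None) -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--initial", required=True, help="aligner output (aligned FASTA)")
    ap.add_argument("--ref", required=True, help="reference alignment (aligned FASTA)")
    args = ap.parse_args(argv)

    with open(args.initial) as fh:
        initial = read_aligned_fasta(fh)
    with open(args.ref) as fh:
        ref = read_aligned_fasta(fh)

    before = score_alignment(initial, ref)
    after = score_alignment(reform(initial), ref)
    print("metric\tinitial\treformed\tdelta")
    for name in ("sp", "modeler", "tc"):
        b, a = getattr(before, name), getattr(after, name)
        print(f"{name}\t{b:.4f}\t{a:.4f}\t{a - b:+.4f}")
    sign = "improved" if after.sp > before.sp else (
        "unchanged" if after.sp == before.sp else "worsened")
    print(f"# SP {sign}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
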