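import numpy as np
import pytest

from alnreform import Alignment, FamilySpec, simulate_family
from alnreform.msa import ALPHABET, GAP


def random_alignment(rng: np.random.Generator, n_rows=None, n_cols=None) -> Alignment:
    """A random valid alignment: every row keeps at least one residue and
    no column is entirely gaps."""
    n_rows = n_rows or int(rng.integers(2, 6))
    n_cols = n_cols or int(rng.integers(2, 25))
    while True:
        rows = []
        for k in range(n_rows):
            chars = [
                ALPHABET[rng.integers(4)] if rng.random() > 0.3 else GAP
                for _ in range(n_cols)
            ]
            if all(c == GAP for c in chars):
                chars[int(rng.integers(n_cols))] = ALPHABET[rng.integers(4)]
            rows.append((f"seq{k + 1}", "".join(chars)))
        aln = Alignment(tuple(rows))
        if all(any(g[i] != GAP for _, g in rows) for i in range(n_cols)):
            return aln


@pytest.fixture
def small_family():
    return simulate_family(FamilySpec(n_sequences=5, ancestor_length=60, seed=42))
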