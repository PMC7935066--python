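"""RNA alphabet helpers shared across the package.

Sequences are handled as uppercase RNA internally; ``T`` is accepted on
input and mapped to ``U`` everywhere.
"""

from __future__ import annotations

import numpy as np

RNA_LETTERS = "ACGU"

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick pairs (canonical complementarity, U == T).
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
#: G:U wobble pairs, valid in folded RNA but weaker than WC.
GU_PAIRS = {("G", "U"), ("U", "G")}
#: All pairs allowed in secondary structure (WC + wobble).
FOLD_PAIRS = WC_PAIRS | GU_PAIRS


def normalize_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U; reject non-nucleotide letters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_LETTERS)
    if bad:
        raise ValueError(f"non-RNA letters in sequence: {sorted(bad)}")
    return s


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement in RNA space."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_gu(a: str, b: str) -> bool:
    return (a, b) in GU_PAIRS


def can_fold_pair(a: str, b: str) -> bool:
    return (a, b) in FOLD_PAIRS


def random_rna(rng: np.random.Generator, length: int) -> str:
    """Uniform random RNA sequence of the given length."""
    return "".join(rng.choice(list(RNA_LETTERS), size=length))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
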