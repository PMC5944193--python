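"""Small DNA-string utilities shared across the pipeline.

Uracil is represented as T throughout: reads are handled in DNA space, so
"monouridylation" is a single untemplated T.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable

#: Illumina TruSeq small-RNA 3' adapter, the library-prep default.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches anything.

    An ``N`` in either sequence counts as a mismatch even against another
    ``N``, which makes exact-match policies reject N-containing reads.
    """
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length sequences")
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            n += 1
    return n


def matches_exactly(a: str, b: str) -> bool:
    """Equality with N-never-matches semantics."""
    return a == b and "N" not in a


def shannon_entropy(values: Iterable[int]) -> float:
    """Shannon entropy (bits) of a discrete sample, e.g. read lengths.

    Used as a degradation indicator: random mRNA fragmentation gives a broad,
    high-entropy size distribution, while genuine small-RNA libraries peak
    sharply at miRNA sizes.
    """
    counts = Counter(values)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    ent = 0.0
    for c in counts.values():
        p = c / total
        ent -= p * math.log2(p)
    return ent
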