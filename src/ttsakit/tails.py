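"""Untemplated 3'-tail detection for small RNAs.

A read whose 3' end carries nucleotides not present in the genome at its
locus fails exact full-length alignment; it is rescued here by finding the
longest exactly matching 5' prefix and treating the unmatched suffix as an
untemplated tail. This replaces a suffix-trie tail aligner with iterative
longest-prefix matching — the output contract is the same at the reference
sizes this package targets. Uracil is written as T, so a single untemplated
uridine is the tail "T".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import Aligner, AlignmentRecord
from .stats import FisherResult, fisher_exact_2x2

TAIL_CLASSES = ("none", "monoA", "monoU", "oligoA", "oligoU", "shortA", "other")


def classify_tail(tail_seq: str) -> str:
    """Partition a tail sequence into its class.

    monoA/monoU are single untemplated A/T; shortA is 2-3 A; oligoA is >= 4
    consecutive A (the class whose excess distinguishes TTSa-RNAs from
    miRNAs); oligoU is >= 2 T; anything mixed is `other`.
    """
    if not tail_seq:
        return "none"
    n = len(tail_seq)
    if set(tail_seq) == {"A"}:
        if n == 1:
            return "monoA"
        if n <= 3:
            return "shortA"
        return "oligoA"
    if set(tail_seq) == {"T"}:
        return "monoU" if n == 1 else "oligoU"
    return "other"


@dataclass
class TailCall:
    read_id: str
    prefix_len: int
    tail_seq: str
    tail_class: str
    alignment: AlignmentRecord

    @property
    def tailed(self) -> bool:
        return bool(self.tail_seq)


@dataclass
class NoCall:
    read_id: str
    reason: str  # too_short | multimapped_prefix | unaligned


@dataclass
class TailSummary:
    counts: Counter = field(default_factory=Counter)
    n_called: int = 0
    n_nocall: int = 0
    tail_length_hist: Counter = field(default_factory=Counter)

    @property
    def fractions(self) -> dict[str, float] | None:
        if self.n_called == 0:
            return None
        return {c: self.counts.get(c, 0) / self.n_called for c in TAIL_CLASSES}

    @property
    def fraction_tailed(self) -> float | None:
        if self.n_called == 0:
            return None
        return 1.0 - self.counts.get("none", 0) / self.n_called


def call_tail(
    read,
    genome: Mapping[str, str] | Aligner,
    min_prefix: int = 18,
    require_unique: bool = True,
    allow_shorter_unique: bool = False,
) -> TailCall | NoCall:
    """Call the untemplated 3' tail of one read against the genome.

    Walks prefix lengths from the full read down to ``min_prefix`` and stops
    at the longest prefix with an exact genome match. If that prefix is
    multi-mapping, the default is a strict no-call;
    ``allow_shorter_unique`` keeps descending until a unique (shorter)
    prefix is found instead. A full-length match yields tail class
    ``none``.
    """
    aligner = genome if isinstance(genome, Aligner) else Aligner(genome, tier="genome")
    seq = (read if isinstance(read, str) else read.sequence).upper()
    read_id = "" if isinstance(read, str) else getattr(read, "read_id", "")
    if len(seq) < min_prefix:
        return NoCall(read_id, "too_short")
    for L in range(len(seq), min_prefix - 1, -1):
        hits = aligner.exact_hits(seq[:L])
        if not hits:
            continue
        if len(hits) > 1 and require_unique:
            if allow_shorter_unique:
                continue
            return NoCall(read_id, "multimapped_prefix")
        chrom, start, strand = hits[0]
        tail = seq[L:]
        alignment = AlignmentRecord(read_id=read_id, chrom=chrom, start=start,
                                    end=start + L, strand=strand, tier="genome")
        return TailCall(read_id=read_id, prefix_len=L, tail_seq=tail,
                        tail_class=classify_tail(tail), alignment=alignment)
    return NoCall(read_id, "unaligned")


def summarize_tails(calls: Sequence[TailCall | NoCall]) -> TailSummary:
    """Class counts, fraction tailed, and tail-length histogram for a read set.

    No-calls are counted but excluded from fractions (which are therefore
    undefined — ``None`` — when nothing was callable).
    """
    summary = TailSummary()
    for c in calls:
        if isinstance(c, NoCall):
            summary.n_nocall += 1
            continue
        summary.n_called += 1
        summary.counts[c.tail_class] += 1
        if c.tail_seq:
            summary.tail_length_hist[len(c.tail_seq)] += 1
    return summary


def compare_oligoA(ttsa: TailSummary, mirna: TailSummary) -> FisherResult:
    """Fisher exact test for oligoA-tail excess in TTSa-RNAs over miRNAs.

    2x2 table of (oligoA vs anything else) x (TTSa vs miRNA) over all
    called reads, tailed or not. The p-value is two-sided by summing
    hypergeometric point probabilities no larger than the observed table's.
    """
    a = ttsa.counts.get("oligoA", 0)
    c = mirna.counts.get("oligoA", 0)
    table = [[a, ttsa.n_called - a], [c, mirna.n_called - c]]
    return fisher_exact_2x2(table)
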