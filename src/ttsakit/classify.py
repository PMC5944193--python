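"""Adapter trimming, tiered read classification, and library QC.

The classification cascade mirrors the standard small-RNA triage: reads are
assigned to the first reference tier that accepts them — miRNA hairpins,
then tRNA/rRNA, then the genome — with the genome tier requiring a single
exact end-to-end alignment. Only uniquely genome-aligned reads proceed to
TTSa calling; multi-mappers and unaligned reads are kept for bookkeeping
(and the latter for untemplated-tail rescue).
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import Aligner, AlignPolicy, AlignmentRecord, EXACT_POLICY, TOLERANT_POLICY
from .errors import UsageError
from .seqs import TRUSEQ_SMALL_RNA_ADAPTER, shannon_entropy

CATEGORIES = ("mirna", "trna_rrna", "genome_unique", "genome_multi", "unaligned")

DEFAULT_POLICIES: dict[str, AlignPolicy] = {
    "mirna": TOLERANT_POLICY,
    "trna_rrna": TOLERANT_POLICY,
    "genome": EXACT_POLICY,
}


@dataclass
class RawRead:
    read_id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self):
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise UsageError(f"read {self.read_id}: quality length != sequence length")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    adapter_found: bool
    kept: bool
    qualities: list[int] | None = None


@dataclass
class ClassifiedRead:
    read: TrimmedRead
    category: str
    alignment: AlignmentRecord | None = None
    tail: object | None = None  # TailCall, attached later by the tail caller

    @property
    def read_id(self) -> str:
        return self.read.read_id

    @property
    def sequence(self) -> str:
        return self.read.sequence


@dataclass
class QCSummary:
    read_length_hist: Counter = field(default_factory=Counter)
    median_phred_by_pos: list[float] | None = None
    category_counts: dict[str, int] = field(default_factory=dict)
    aligned_denominator: int = 0
    total_kept: int = 0
    total_input: int = 0


@dataclass
class QCVerdict:
    suitable: bool
    reasons: list[str]
    size_entropy: float


def trim_adapter(
    read: RawRead,
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
    min_len: int = 18,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> TrimmedRead:
    """Remove the best 3'-anchored adapter occurrence from a read.

    Every start position is considered; the adapter may run off the read end
    (suffix/prefix overlap), as long as the matched part is at least
    ``min_overlap`` nt with mismatches <= ``max_error_rate`` of its length.
    Among valid occurrences the highest-scoring (matched length minus
    penalized mismatches) and then leftmost wins. Reads shorter than
    ``min_len`` after trimming are flagged ``kept=False`` — the pipeline
    retains only inserts longer than 17 nt by default.
    """
    if not adapter:
        raise UsageError("adapter must be non-empty")
    seq = read.sequence.upper()
    L = len(seq)
    alen = len(adapter)

    best: tuple[float, int] | None = None  # (score, start)
    # fast path: leftmost exact full-adapter occurrence is always optimal
    i = seq.find(adapter)
    if i != -1:
        best = (float(alen), i)
    else:
        for i in range(0, L - min_overlap + 1):
            m = min(alen, L - i)
            if m < min_overlap:
                break
            allowed = int(max_error_rate * m)
            mm = 0
            for a, b in zip(seq[i : i + m], adapter[:m]):
                if a != b:
                    mm += 1
                    if mm > allowed:
                        break
            if mm > allowed:
                continue
            score = m - 4.0 * mm
            if best is None or score > best[0]:
                best = (score, i)

    if best is not None:
        cut = best[1]
        trimmed, found = seq[:cut], True
    else:
        trimmed, found = seq, False
    quals = read.qualities[: len(trimmed)] if read.qualities is not None else None
    kept = len(trimmed) >= min_len and bool(set(trimmed) - {"N"})
    return TrimmedRead(read_id=read.read_id, sequence=trimmed,
                       adapter_found=found, kept=kept, qualities=quals)


def _as_aligner(ref, tier: str) -> Aligner:
    if isinstance(ref, Aligner):
        return ref
    return Aligner(ref, tier=tier)


def classify_hierarchical(
    reads: Sequence[TrimmedRead],
    refs: Mapping[str, Mapping[str, str] | Aligner],
    policies: Mapping[str, AlignPolicy] | None = None,
) -> tuple[list[ClassifiedRead], QCSummary]:
    """Run the four-step cascade over trimmed reads.

    ``refs`` maps tier name (``mirna``, ``trna_rrna``, ``genome``) to a
    reference sequence dict (or prebuilt :class:`Aligner`). Reads with
    ``kept=False`` are excluded from classification and from all counts.

    Returns the classified reads plus a :class:`QCSummary` whose
    ``aligned_denominator`` — reads with a valid alignment in any tier — is
    the RPM denominator used throughout.
    """
    pol = dict(DEFAULT_POLICIES)
    if policies:
        pol.update(policies)
    for tier in ("mirna", "trna_rrna", "genome"):
        if tier not in refs:
            raise UsageError(f"missing reference for tier {tier!r}")
    mirna = _as_aligner(refs["mirna"], "mirna")
    trna = _as_aligner(refs["trna_rrna"], "trna_rrna")
    genome = _as_aligner(refs["genome"], "genome")

    out: list[ClassifiedRead] = []
    counts = Counter()
    qc = QCSummary(total_input=len(reads))
    for tr in reads:
        if not tr.kept:
            continue
        qc.total_kept += 1
        qc.read_length_hist[len(tr.sequence)] += 1
        hit = mirna.align(tr.sequence, pol["mirna"], read_id=tr.read_id,
                          first_only=True)
        if hit:
            out.append(ClassifiedRead(tr, "mirna", hit[0]))
            counts["mirna"] += 1
            continue
        hit = trna.align(tr.sequence, pol["trna_rrna"], read_id=tr.read_id,
                         first_only=True)
        if hit:
            out.append(ClassifiedRead(tr, "trna_rrna", hit[0]))
            counts["trna_rrna"] += 1
            continue
        hits = genome.align(tr.sequence, pol["genome"], read_id=tr.read_id)
        if len(hits) == 1:
            out.append(ClassifiedRead(tr, "genome_unique", hits[0]))
            counts["genome_unique"] += 1
        elif len(hits) > 1:
            out.append(ClassifiedRead(tr, "genome_multi", None))
            counts["genome_multi"] += 1
        else:
            out.append(ClassifiedRead(tr, "unaligned", None))
            counts["unaligned"] += 1

    qc.category_counts = {c: counts.get(c, 0) for c in CATEGORIES}
    qc.aligned_denominator = (
        counts["mirna"] + counts["trna_rrna"] + counts["genome_unique"]
    )
    qc.median_phred_by_pos = _median_phred([r for r in reads if r.kept])
    return out, qc


TIER_ORDER = {"mirna": 0, "trna_rrna": 1, "genome": 2}


def classify_from_alignments(
    reads: Sequence[TrimmedRead],
    alignments: Mapping[str, Sequence[AlignmentRecord]],
) -> tuple[list[ClassifiedRead], QCSummary]:
    """Classify from precomputed, tier-tagged alignments (SAM/BED input).

    Bypasses the built-in aligner for externally aligned libraries: each
    read takes the best (lowest) tier among its alignments; reads whose
    best tier is the genome are unique only if exactly one genome
    alignment exists. Alignments lacking a tier tag are treated as genome.
    """
    out: list[ClassifiedRead] = []
    counts = Counter()
    qc = QCSummary(total_input=len(reads))
    for tr in reads:
        if not tr.kept:
            continue
        qc.total_kept += 1
        qc.read_length_hist[len(tr.sequence)] += 1
        alns = list(alignments.get(tr.read_id, ()))
        if not alns:
            out.append(ClassifiedRead(tr, "unaligned", None))
            counts["unaligned"] += 1
            continue
        best = min(TIER_ORDER.get(a.tier or "genome", 2) for a in alns)
        tier_alns = sorted(
            (a for a in alns if TIER_ORDER.get(a.tier or "genome", 2) == best),
            key=AlignmentRecord.sort_key,
        )
        if best < 2:
            cat = "mirna" if best == 0 else "trna_rrna"
            out.append(ClassifiedRead(tr, cat, tier_alns[0]))
            counts[cat] += 1
        elif len(tier_alns) == 1:
            out.append(ClassifiedRead(tr, "genome_unique", tier_alns[0]))
            counts["genome_unique"] += 1
        else:
            out.append(ClassifiedRead(tr, "genome_multi", None))
            counts["genome_multi"] += 1
    qc.category_counts = {c: counts.get(c, 0) for c in CATEGORIES}
    qc.aligned_denominator = (
        counts["mirna"] + counts["trna_rrna"] + counts["genome_unique"]
    )
    qc.median_phred_by_pos = _median_phred([r for r in reads if r.kept])
    return out, qc


def _median_phred(reads: Sequence) -> list[float] | None:
    with_q = [r for r in reads if getattr(r, "qualities", None) is not None]
    if not with_q:
        return None
    max_len = max(len(r.qualities) for r in with_q)
    medians = []
    for pos in range(max_len):
        vals = [r.qualities[pos] for r in with_q if len(r.qualities) > pos]
        medians.append(float(statistics.median(vals)) if vals else float("nan"))
    return medians


def qc_dataset(reads: Sequence, min_len: int = 18,
               phred_floor: float = 2.0, phred_from_pos: int = 16) -> tuple[QCSummary, QCVerdict]:
    """Library-suitability screen applied before any analysis.

    A dataset is flagged ``unsuitable`` when the median Phred score has
    collapsed (<= ``phred_floor`` at every position beyond ``phred_from_pos``,
    1-based) — alignment beyond the quality cliff is meaningless — or when
    every read is shorter than ``min_len``, in which case multi-mapping
    prevents specific TTSa identification. The size-distribution entropy is
    reported as an advisory mRNA-degradation indicator; the verdict does not
    act on it.
    """
    lengths = [len(r.sequence) for r in reads]
    qc = QCSummary(read_length_hist=Counter(lengths), total_input=len(reads),
                   total_kept=len(reads))
    qc.median_phred_by_pos = _median_phred(reads)

    reasons = []
    if lengths and all(l < min_len for l in lengths):
        reasons.append("all_reads_short")
    med = qc.median_phred_by_pos
    if med is not None and len(med) > phred_from_pos:
        tail = med[phred_from_pos:]
        if tail and all(m <= phred_floor for m in tail):
            reasons.append("phred_collapse")
    entropy = shannon_entropy(lengths)
    return qc, QCVerdict(suitable=not reasons, reasons=reasons, size_entropy=entropy)
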