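"""Ungapped short-read alignment at desk scale.

Emulates the bowtie1 contract the pipeline was built around: a mismatch
budget inside the 5'-most ``seed_len`` nucleotides of the read plus an
overall budget, full read length aligned end to end, no gaps. The
quality-weighted budget of ``-n`` mode is replaced by a plain mismatch
count. ``N`` never matches any base (including ``N``), so exact policies
reject N-containing reads outright.

Candidates are generated by the pigeonhole principle: with at most *s* seed
mismatches, splitting the seed into *s + 1* chunks guarantees one chunk
matches the reference exactly, so exact occurrences of each chunk (both
strands) enumerate every possible alignment start. Each candidate is then
verified against both budgets. This is exhaustive, so uniqueness (`-m 1`)
can be decided by counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .errors import UsageError
from .seqs import revcomp

__all__ = [
    "AlignPolicy",
    "AlignmentRecord",
    "Aligner",
    "align_reads",
    "TOLERANT_POLICY",
    "EXACT_POLICY",
]


@dataclass(frozen=True)
class AlignPolicy:
    """Alignment acceptance rules (bowtie1 ``-n``/``-l`` analogue)."""

    seed_len: int = 18
    max_seed_mismatches: int = 0
    max_total_mismatches: int = 0
    report_all: bool = True

    def __post_init__(self):
        if self.max_seed_mismatches > self.max_total_mismatches:
            raise UsageError("seed mismatch budget cannot exceed total budget")


#: miRNA-hairpin and tRNA/rRNA tier default (``-n 2 -l 18``).
TOLERANT_POLICY = AlignPolicy(seed_len=18, max_seed_mismatches=2, max_total_mismatches=2)
#: genome tier default (``-n 0 -l 18``, exact end-to-end).
EXACT_POLICY = AlignPolicy(seed_len=18, max_seed_mismatches=0, max_total_mismatches=0)


@dataclass
class AlignmentRecord:
    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    #: (read position, reference base, read base); bases in read orientation,
    #: i.e. the reference base is complemented for minus-strand alignments.
    mismatch_positions: list[tuple[int, str, str]] = field(default_factory=list)
    tier: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (self.chrom, self.start, self.strand)


def _find_all(text: str, pattern: str) -> Iterator[int]:
    if "N" in pattern:  # N never matches, so an N-containing chunk has no exact hits
        return
    i = text.find(pattern)
    while i != -1:
        yield i
        i = text.find(pattern, i + 1)


def _chunks(lo: int, hi: int, n: int) -> list[tuple[int, int]]:
    """Split [lo, hi) into n near-equal contiguous pieces."""
    span = hi - lo
    out = []
    for k in range(n):
        a = lo + (span * k) // n
        b = lo + (span * (k + 1)) // n
        if b > a:
            out.append((a, b))
    return out


class Aligner:
    """Aligns reads against a set of named reference sequences."""

    #: k-mer length of the exact-match anchor index
    INDEX_K = 18

    def __init__(self, references: Mapping[str, str], tier: str | None = None):
        if not references or all(len(s) == 0 for s in references.values()):
            raise UsageError("reference set is empty")
        self.refs = {name: seq.upper() for name, seq in references.items()}
        self.tier = tier
        self._index: dict[str, list[tuple[str, int]]] | None = None

    def _anchor_index(self) -> dict[str, list[tuple[str, int]]]:
        """Lazy (chrom, pos) index of every INDEX_K-mer in the references.

        Exact full-length matching anchors on the read's first INDEX_K
        nucleotides, turning each lookup into O(occurrences) instead of a
        reference scan — the genome tier and the tail caller's prefix
        descent hit this path for every read.
        """
        if self._index is None:
            k = self.INDEX_K
            index: dict[str, list[tuple[str, int]]] = {}
            for chrom in sorted(self.refs):
                ref = self.refs[chrom]
                for p in range(len(ref) - k + 1):
                    index.setdefault(ref[p : p + k], []).append((chrom, p))
            self._index = index
        return self._index

    # -- candidate generation -------------------------------------------------

    def _candidates(self, oriented: str, seed_lo: int, seed_hi: int, n_chunks: int,
                    ref: str) -> set[int]:
        """Possible alignment starts of `oriented` on `ref` (forward sense)."""
        L = len(oriented)
        starts: set[int] = set()
        for a, b in _chunks(seed_lo, seed_hi, n_chunks):
            for occ in _find_all(ref, oriented[a:b]):
                p = occ - a
                if 0 <= p <= len(ref) - L:
                    starts.add(p)
        return starts

    @staticmethod
    def _verify(oriented: str, ref: str, p: int, seed_lo: int, seed_hi: int,
                policy: AlignPolicy) -> list[int] | None:
        """Mismatch offsets (in `oriented` coordinates) or None if rejected."""
        mm: list[int] = []
        seed_mm = 0
        for i, base in enumerate(oriented):
            r = ref[p + i]
            if base != r or base == "N" or r == "N":
                mm.append(i)
                if len(mm) > policy.max_total_mismatches:
                    return None
                if seed_lo <= i < seed_hi:
                    seed_mm += 1
                    if seed_mm > policy.max_seed_mismatches:
                        return None
        return mm

    # -- public API -----------------------------------------------------------

    def align(self, seq: str, policy: AlignPolicy = EXACT_POLICY,
              read_id: str = "", first_only: bool = False) -> list[AlignmentRecord]:
        """All valid alignments of `seq`, deterministically ordered.

        With ``first_only`` the search stops at the first verified hit
        (sufficient when a tier only gates read progression).
        """
        seq = seq.upper()
        L = len(seq)
        if (policy.max_total_mismatches == 0 and L >= self.INDEX_K):
            # exact end-to-end policy: resolve via the anchor index
            records = [
                self._record(read_id, chrom, p, strand, seq,
                             seq if strand == "+" else revcomp(seq),
                             self.refs[chrom], [])
                for chrom, p, strand in self.exact_hits(seq)
            ]
            return records[:1] if (first_only and records) else records
        n_chunks = policy.max_seed_mismatches + 1
        records: list[AlignmentRecord] = []
        for chrom in sorted(self.refs):
            ref = self.refs[chrom]
            if L > len(ref):
                continue
            seed = min(policy.seed_len, L)
            for strand, oriented in (("+", seq), ("-", revcomp(seq))):
                # the read's 5' seed sits at the start of `oriented` on '+',
                # at its end on '-'
                if strand == "+":
                    seed_lo, seed_hi = 0, seed
                else:
                    seed_lo, seed_hi = L - seed, L
                for p in sorted(self._candidates(oriented, seed_lo, seed_hi,
                                                 n_chunks, ref)):
                    mm = self._verify(oriented, ref, p, seed_lo, seed_hi, policy)
                    if mm is None:
                        continue
                    records.append(self._record(read_id, chrom, p, strand, seq,
                                                oriented, ref, mm))
                    if first_only:
                        return records
        records.sort(key=AlignmentRecord.sort_key)
        return records

    def _record(self, read_id, chrom, p, strand, seq, oriented, ref, mm_offsets):
        L = len(seq)
        positions = []
        for i in mm_offsets:
            if strand == "+":
                read_pos = i
                ref_base = ref[p + i]
            else:
                read_pos = L - 1 - i
                ref_base = revcomp(ref[p + i])
            positions.append((read_pos, ref_base, seq[read_pos]))
        positions.sort()
        return AlignmentRecord(
            read_id=read_id, chrom=chrom, start=p, end=p + L, strand=strand,
            mismatches=len(positions), mismatch_positions=positions, tier=self.tier,
        )

    def has_hit(self, seq: str, policy: AlignPolicy) -> bool:
        return bool(self.align(seq, policy, first_only=True))

    def exact_hits(self, seq: str) -> list[tuple[str, int, str]]:
        """(chrom, start, strand) of every exact full-length occurrence."""
        seq = seq.upper()
        if "N" in seq:
            return []
        L = len(seq)
        rc = revcomp(seq)
        hits = []
        k = self.INDEX_K
        if L >= k:
            index = self._anchor_index()
            for chrom, p in index.get(seq[:k], ()):
                ref = self.refs[chrom]
                if p + L <= len(ref) and ref[p : p + L] == seq:
                    hits.append((chrom, p, "+"))
            # the read's first k nt sit at the *end* of the reverse complement
            for chrom, q in index.get(rc[L - k :], ()):
                p = q - (L - k)
                ref = self.refs[chrom]
                if 0 <= p and p + L <= len(ref) and ref[p : p + L] == rc:
                    hits.append((chrom, p, "-"))
        else:
            for chrom in sorted(self.refs):
                ref = self.refs[chrom]
                for p in _find_all(ref, seq):
                    hits.append((chrom, p, "+"))
                for p in _find_all(ref, rc):
                    hits.append((chrom, p, "-"))
        hits.sort()
        return hits


def align_reads(reads: Sequence, reference: Mapping[str, str] | Aligner,
                policy: AlignPolicy = EXACT_POLICY) -> list[list[AlignmentRecord]]:
    """Align a batch of reads; returns one (possibly empty) record list per read.

    ``reads`` may be strings or any objects with ``sequence``/``read_id``.
    """
    aligner = reference if isinstance(reference, Aligner) else Aligner(reference)
    out = []
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        rid = "" if isinstance(r, str) else getattr(r, "read_id", "")
        out.append(aligner.align(seq, policy, read_id=rid))
    return out
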