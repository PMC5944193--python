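"""TTSa-RNA calling, quantification, and coverage metaprofiles.

A TTSa-RNA is a uniquely genome-aligned small RNA whose alignment overlaps,
by at least 1 nt, the 5-nt window centered on an annotated 1-nt polyA site,
on the sense strand of the site, within the configured size range. Reads
rescued by the tail caller participate through their templated prefix
alignment (the untemplated tail has no genomic 3' end).

Two proximity rules coexist deliberately: site *assignment* of a called
read uses 3'-end distance (the defining feature of the class), while
coverage metaprofiles attribute each read to the closest site by read
midpoint, each read counting toward a single site only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .align import AlignmentRecord
from .annotation import GeneIndex, GeneModel, PolyASite, TTSWindow, assign_gene, _normalize_exclusions
from .classify import ClassifiedRead, QCSummary
from .errors import UsageError
from .tails import TailCall

DEFAULT_SIZE_RANGE = (18, None)      # cell-line / IP mode: no explicit maximum
PRIMARY_TISSUE_SIZE_RANGE = (18, 26)  # primary-sample mode


@dataclass
class TTSaRecord:
    read_id: str
    alignment: AlignmentRecord
    site_id: str
    sense: bool
    dist3p: int
    length: int
    tail: TailCall | None = None


@dataclass
class SampleQuant:
    sample_id: str
    ttsa_count: int
    aligned_denominator: int
    rpm: float
    per_site: pd.DataFrame
    per_gene: pd.DataFrame | None = None


@dataclass
class CoverageProfile:
    offsets: np.ndarray
    sense: np.ndarray
    antisense: np.ndarray
    n_reads: int = 0
    mismatch_spectrum: dict[str, int] = field(default_factory=dict)

    @property
    def total_mass(self) -> int:
        return int(self.sense.sum() + self.antisense.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "sense_cov": self.sense,
                             "antisense_cov": self.antisense})


def _read_3p(aln: AlignmentRecord) -> int:
    """Genomic coordinate of the templated 3' end."""
    return aln.end - 1 if aln.strand == "+" else aln.start


def _signed_dist3p(aln: AlignmentRecord, site: PolyASite) -> int:
    """Signed 3'-end offset; positive = downstream of the site (site strand)."""
    r3 = _read_3p(aln)
    return r3 - site.position if site.strand == "+" else site.position - r3


def call_ttsa(
    classified: Sequence[ClassifiedRead],
    windows: Sequence[TTSWindow],
    sites: Sequence[PolyASite],
    size_range: tuple[int, int | None] = DEFAULT_SIZE_RANGE,
    sense_only: bool = True,
    tails: Mapping[str, TailCall] | None = None,
) -> list[TTSaRecord]:
    """Call TTSa-RNAs from classified reads.

    Uniquely genome-aligned reads qualify directly; unaligned reads with a
    unique tail call qualify through their prefix alignment. A read
    overlapping several windows is assigned the site whose position is
    nearest its templated 3' end (ties: smaller genomic coordinate, then
    site id). ``size_range`` bounds the full read length, tail included.
    """
    lo, hi = size_range
    if hi is not None and lo > hi:
        raise UsageError(f"inverted size range {size_range}")
    site_by_id = {s.site_id: s for s in sites}
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w)
    tails = tails or {}

    records: list[TTSaRecord] = []
    for cr in classified:
        tail = tails.get(cr.read_id)
        if cr.category == "genome_unique":
            aln = cr.alignment
        elif cr.category == "unaligned" and isinstance(tail, TailCall):
            aln = tail.alignment
        else:
            continue
        length = len(cr.sequence)
        if length < lo or (hi is not None and length > hi):
            continue
        tree = trees.get(aln.chrom)
        if tree is None:
            continue
        cands = []
        r3 = _read_3p(aln)
        for iv in tree.overlap(aln.start, aln.end):
            w: TTSWindow = iv.data
            if sense_only and w.strand != aln.strand:
                continue
            site = site_by_id.get(w.site_id)
            if site is None:
                continue
            cands.append((abs(r3 - site.position), site.position, site.site_id, site))
        if not cands:
            continue
        cands.sort(key=lambda t: t[:3])
        site = cands[0][3]
        records.append(
            TTSaRecord(
                read_id=cr.read_id,
                alignment=aln,
                site_id=site.site_id,
                sense=aln.strand == site.strand,
                dist3p=_signed_dist3p(aln, site),
                length=length,
                tail=tail if isinstance(tail, TailCall) else None,
            )
        )
    return records


def quantify(
    records: Sequence[TTSaRecord],
    qc: QCSummary,
    genes: Sequence[GeneModel] | GeneIndex | None = None,
    sample_id: str = "sample",
) -> SampleQuant:
    """Per-sample TTSa abundance in RPM, with per-site and per-gene tables.

    RPM divides the TTSa read count by the number of reads that aligned in
    any tier (the ``aligned_denominator`` of the QC summary) times 1e6.
    A read overlapping several genes counts once per gene.
    """
    denom = qc.aligned_denominator
    if denom <= 0:
        raise UsageError("aligned denominator is zero; cannot compute RPM")
    scale = 1e6 / denom
    site_counts = pd.Series([r.site_id for r in records], dtype=object).value_counts()
    per_site = pd.DataFrame({"count": site_counts, "rpm": site_counts * scale})
    per_site.index.name = "site_id"

    per_gene = None
    if genes is not None:
        index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
        rows: dict[str, int] = {}
        for r in records:
            for gid, _sense in assign_gene(r.alignment.chrom, r.alignment.start,
                                           r.alignment.end, r.alignment.strand, index):
                rows[gid] = rows.get(gid, 0) + 1
        gene_counts = pd.Series(rows, dtype=np.int64).sort_index()
        per_gene = pd.DataFrame({"count": gene_counts, "rpm": gene_counts * scale})
        per_gene.index.name = "gene_id"

    return SampleQuant(
        sample_id=sample_id,
        ttsa_count=len(records),
        aligned_denominator=denom,
        rpm=len(records) * scale,
        per_site=per_site,
        per_gene=per_gene,
    )


def proximity_stats(records: Sequence[TTSaRecord], max_dist: int = 2) -> dict:
    """3'-end proximity, size, and orientation summaries of called records.

    Returns the fraction of records whose |dist3p| <= ``max_dist``, the
    dist3p and size histograms, and the sense-strand fraction. Empty input
    gives None fractions and empty histograms.
    """
    if not records:
        return {"n": 0, "fraction_within": None, "sense_fraction": None,
                "dist3p_hist": pd.Series(dtype=np.int64),
                "size_hist": pd.Series(dtype=np.int64)}
    dists = np.array([r.dist3p for r in records])
    sizes = np.array([r.length for r in records])
    sense = np.array([r.sense for r in records])
    return {
        "n": len(records),
        "fraction_within": float(np.mean(np.abs(dists) <= max_dist)),
        "sense_fraction": float(np.mean(sense)),
        "dist3p_hist": pd.Series(dists).value_counts().sort_index(),
        "size_hist": pd.Series(sizes).value_counts().sort_index(),
    }


def _closest_site(positions: np.ndarray, mid: float) -> int:
    """Index of the closest position; ties go to the smaller coordinate."""
    i = int(np.searchsorted(positions, mid))
    if i == 0:
        return 0
    if i == len(positions):
        return len(positions) - 1
    left, right = positions[i - 1], positions[i]
    return i - 1 if (mid - left) <= (right - mid) else i


def coverage_profile(
    reads: Iterable,
    sites: Sequence[PolyASite],
    window_nt: int = 1000,
    closest_only: bool = True,
    exclude: Iterable = (),
    parclip_mode: bool = False,
) -> CoverageProfile:
    """Cumulative read coverage around polyA sites, oriented by site strand.

    Each read adds +1 to every offset its alignment covers inside the
    ``window_nt`` window of its single closest site (distance measured from
    the read midpoint; ties to the smaller coordinate), split into
    sense/antisense by strand match. Sites in ``exclude`` (ids or
    (chrom, position)) are dropped before attribution — the escape hatch for
    sites sitting next to unrelated high-output loci that would otherwise
    dominate the profile.

    ``parclip_mode`` restricts input to reads whose alignment carries
    exactly one mismatch (the crosslinking signature) and tallies the
    mismatch-type spectrum, where T>C transitions are expected to dominate.
    """
    half = window_nt // 2
    offsets = np.arange(-half, window_nt - half)
    sense_cov = np.zeros(window_nt, dtype=np.int64)
    anti_cov = np.zeros(window_nt, dtype=np.int64)
    spectrum: dict[str, int] = {}

    excl_ids, excl_coords = _normalize_exclusions(exclude)
    kept_sites = [s for s in sites
                  if s.site_id not in excl_ids and (s.chrom, s.position) not in excl_coords]
    by_chrom: dict[str, list[PolyASite]] = {}
    for s in kept_sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    pos_arrays = {}
    for chrom, ss in by_chrom.items():
        ss.sort(key=lambda s: s.position)
        pos_arrays[chrom] = np.array([s.position for s in ss])

    n_reads = 0
    for r in reads:
        aln: AlignmentRecord | None
        if isinstance(r, AlignmentRecord):
            aln = r
        elif isinstance(r, ClassifiedRead):
            if r.category != "genome_unique":
                continue
            aln = r.alignment
        else:
            aln = getattr(r, "alignment", None)
        if aln is None:
            continue
        if parclip_mode:
            if aln.mismatches != 1:
                continue
            ref_b, read_b = aln.mismatch_positions[0][1], aln.mismatch_positions[0][2]
            key = f"{ref_b}>{read_b}"
            spectrum[key] = spectrum.get(key, 0) + 1
        chrom_sites = by_chrom.get(aln.chrom)
        if not chrom_sites:
            continue
        mid = (aln.start + aln.end - 1) / 2.0
        if closest_only:
            targets = [chrom_sites[_closest_site(pos_arrays[aln.chrom], mid)]]
        else:
            targets = [s for s in chrom_sites
                       if aln.start < s.position + half and aln.end > s.position - half]
        contributed = False
        for site in targets:
            if site.strand == "+":
                lo = aln.start - site.position
                hi = aln.end - site.position  # exclusive
            else:
                lo = site.position - (aln.end - 1)
                hi = site.position - aln.start + 1
            lo_c, hi_c = max(lo, -half), min(hi, window_nt - half)
            if lo_c >= hi_c:
                continue
            target = sense_cov if aln.strand == site.strand else anti_cov
            target[lo_c + half : hi_c + half] += 1
            contributed = True
        if contributed:
            n_reads += 1

    return CoverageProfile(offsets=offsets, sense=sense_cov, antisense=anti_cov,
                           n_reads=n_reads, mismatch_spectrum=spectrum)
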