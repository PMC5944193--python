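"""Genome annotation I/O: gene models, polyA sites, and TTS windows.

All internal coordinates are 0-based half-open. GTF input (GENCODE dialect,
1-based closed) is converted on parse; BED input is taken as-is. The single
annotated polyadenylation base of a gene is the operational transcription
termination site (TTS); calling works on a 5-nt window centered on it
(position - 2 .. position + 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from .errors import ParseError, UsageError, ValidationError

logger = logging.getLogger(__name__)

GTF_SOURCE = "ttsakit"


@dataclass
class GeneModel:
    """A gene as a single stranded interval (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")


@dataclass
class PolyASite:
    """A 1-nt annotated polyadenylation position.

    ``annotated_length`` records the span of the original annotation row;
    sites longer than 1 nt are retained on parse and removed by
    :func:`filter_polya_sites`, mirroring how multi-nt entries are excluded
    from all analyses.
    """

    site_id: str
    chrom: str
    position: int
    strand: str
    gene_id: str | None = None
    annotated_length: int = 1

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"polyA site {self.site_id}: strand must be + or -")


@dataclass
class TTSWindow:
    """A 5-nt half-open window centered on a polyA site."""

    site_id: str
    chrom: str
    start: int
    end: int
    strand: str
    position: int = -1  # center (the polyA base); -1 when unknown
    clipped: bool = False


@dataclass
class GenomeAnnotation:
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)
    polya_sites: list[PolyASite] = field(default_factory=list)

    def validate(self) -> None:
        gene_ids = {g.gene_id for g in self.genes}
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.end > size:
                raise ValidationError(
                    f"gene {g.gene_id} extends past end of {g.chrom} ({g.end} > {size})"
                )
        for s in self.polya_sites:
            size = self.chrom_sizes.get(s.chrom)
            if size is not None and not (0 <= s.position < size):
                raise ValidationError(
                    f"polyA site {s.site_id} position {s.position} outside {s.chrom}"
                )
            if s.gene_id is not None and gene_ids and s.gene_id not in gene_ids:
                raise ValidationError(
                    f"polyA site {s.site_id} references unknown gene {s.gene_id}"
                )


def read_fai(path: str | Path) -> dict[str, int]:
    """Chromosome sizes from a samtools/pyfaidx .fai index."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError("expected at least 2 tab-separated fields", str(path), i)
            sizes[fields[0]] = int(fields[1])
    return sizes


def _prevalidate_gtf(path: Path) -> None:
    """Cheap structural scan so malformed rows fail with a line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", str(path), i
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError("non-integer coordinates", str(path), i) from None
            if start < 1 or end < start:
                raise ParseError(f"bad coordinate range {start}-{end}", str(path), i)
            if fields[6] not in "+-.":
                raise ParseError(f"bad strand {fields[6]!r}", str(path), i)


def parse_annotation(
    path: str | Path,
    dialect: str = "gtf",
    chrom_sizes: Mapping[str, int] | str | Path | None = None,
) -> GenomeAnnotation:
    """Parse gene and polyA-site annotation from GTF (GENCODE dialect) or BED6.

    GTF rows typed ``gene`` become :class:`GeneModel`; rows typed
    ``polyA_site`` become :class:`PolyASite` (multi-nt spans are kept with
    their ``annotated_length`` so the downstream 1-nt filter can report what
    it removed). BED6 input carries one site per row, name column = site id.

    ``chrom_sizes`` may be a mapping or a path to a FASTA ``.fai`` index;
    when given, coordinates are validated against it.
    """
    path = Path(path)
    if not path.exists():
        raise UsageError(f"annotation file not found: {path}")
    if isinstance(chrom_sizes, (str, Path)):
        chrom_sizes = read_fai(chrom_sizes)
    sizes = dict(chrom_sizes) if chrom_sizes else {}

    if dialect == "gtf":
        ann = _parse_gtf(path, sizes)
    elif dialect == "bed":
        ann = _parse_bed(path, sizes)
    else:
        raise UsageError(f"unknown annotation dialect: {dialect!r}")
    ann.validate()
    return ann


# pinned GTF attribute dialect: gffutils otherwise infers it from the first
# lines, which mis-splits multi-attribute rows when the file opens with
# single-attribute gene rows
_GTF_DIALECT = {
    "leading semicolon": False, "trailing semicolon": True,
    "quoted GFF2 values": True, "field separator": "; ",
    "semicolon in quotes": False, "keyval separator": " ",
    "multival separator": ",", "fmt": "gtf", "repeated keys": False,
    "order": ["gene_id", "site_id"],
}


def _parse_gtf(path: Path, sizes: dict[str, int]) -> GenomeAnnotation:
    _prevalidate_gtf(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            dialect=_GTF_DIALECT,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - prevalidation catches most
        raise ParseError(f"GTF parse failed: {exc}", str(path)) from exc

    genes = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = (f.attributes.get("gene_id") or [f.id])[0]
        genes.append(
            GeneModel(gene_id=gene_id, chrom=f.seqid, strand=f.strand,
                      start=f.start - 1, end=f.end)
        )
    sites = []
    n_anon = 0
    for f in db.features_of_type("polyA_site", order_by=("seqid", "start")):
        site_id = (f.attributes.get("site_id") or [""])[0]
        if not site_id:
            n_anon += 1
            site_id = f"pas_{n_anon}"
        gene_id = (f.attributes.get("gene_id") or [None])[0]
        sites.append(
            PolyASite(
                site_id=site_id,
                chrom=f.seqid,
                position=f.start - 1,  # 1-based closed -> 0-based
                strand=f.strand,
                gene_id=gene_id,
                annotated_length=f.end - f.start + 1,
            )
        )
    return GenomeAnnotation(chrom_sizes=sizes, genes=genes, polya_sites=sites)


def _parse_bed(path: Path, sizes: dict[str, int]) -> GenomeAnnotation:
    sites = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"BED6 requires 6 fields, got {len(fields)}", str(path), i
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer coordinates", str(path), i) from None
            if end_i <= start_i:
                raise ParseError(f"bad interval {start_i}-{end_i}", str(path), i)
            sites.append(
                PolyASite(
                    site_id=name,
                    chrom=chrom,
                    position=start_i,
                    strand=strand,
                    annotated_length=end_i - start_i,
                )
            )
    return GenomeAnnotation(chrom_sizes=sizes, genes=[], polya_sites=sites)


def write_annotation(ann: GenomeAnnotation, path: str | Path, dialect: str = "gtf") -> None:
    """Write annotation back out (inverse of :func:`parse_annotation`)."""
    path = Path(path)
    if dialect == "gtf":
        with open(path, "w") as fh:
            for g in sorted(ann.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(
                    f"{g.chrom}\t{GTF_SOURCE}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
                )
            for s in sorted(ann.polya_sites, key=lambda s: (s.chrom, s.position)):
                attrs = f'site_id "{s.site_id}";'
                if s.gene_id is not None:
                    attrs += f' gene_id "{s.gene_id}";'
                fh.write(
                    f"{s.chrom}\t{GTF_SOURCE}\tpolyA_site\t{s.position + 1}\t"
                    f"{s.position + s.annotated_length}\t.\t{s.strand}\t.\t{attrs}\n"
                )
    elif dialect == "bed":
        with open(path, "w") as fh:
            for s in sorted(ann.polya_sites, key=lambda s: (s.chrom, s.position)):
                fh.write(
                    f"{s.chrom}\t{s.position}\t{s.position + s.annotated_length}\t"
                    f"{s.site_id}\t0\t{s.strand}\n"
                )
    else:
        raise UsageError(f"unknown annotation dialect: {dialect!r}")


def filter_polya_sites(ann: GenomeAnnotation) -> tuple[list[PolyASite], dict]:
    """Keep only 1-nt polyA sites; report how many were removed.

    Returns ``(kept, stats)`` with ``stats`` keys ``total``, ``kept``,
    ``removed`` and ``fraction_kept`` (None for empty input).
    """
    total = len(ann.polya_sites)
    kept = [s for s in ann.polya_sites if s.annotated_length == 1]
    stats = {
        "total": total,
        "kept": len(kept),
        "removed": total - len(kept),
        "fraction_kept": (len(kept) / total) if total else None,
    }
    return kept, stats


def _normalize_exclusions(exclude: Iterable) -> tuple[set[str], set[tuple[str, int]]]:
    ids: set[str] = set()
    coords: set[tuple[str, int]] = set()
    for item in exclude or ():
        if isinstance(item, str):
            ids.add(item)
        else:
            chrom, pos = item
            coords.add((chrom, int(pos)))
    return ids, coords


def build_windows(
    sites: Sequence[PolyASite],
    half_width: int = 2,
    exclude: Iterable = (),
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TTSWindow]:
    """One ``2*half_width + 1`` nt window per non-excluded 1-nt site.

    ``exclude`` accepts site ids or ``(chrom, position)`` tuples (annotation
    releases number their sites internally, so coordinates are the portable
    spelling). Windows running past a chromosome edge are clipped and logged.
    """
    excl_ids, excl_coords = _normalize_exclusions(exclude)
    windows = []
    for s in sites:
        if s.site_id in excl_ids or (s.chrom, s.position) in excl_coords:
            continue
        start = s.position - half_width
        end = s.position + half_width + 1
        clipped = False
        if start < 0:
            start, clipped = 0, True
        size = (chrom_sizes or {}).get(s.chrom)
        if size is not None and end > size:
            end, clipped = size, True
        if clipped:
            logger.warning(
                "window for site %s clipped to [%d,%d) at %s boundary",
                s.site_id, start, end, s.chrom,
            )
        windows.append(
            TTSWindow(site_id=s.site_id, chrom=s.chrom, start=start, end=end,
                      strand=s.strand, position=s.position, clipped=clipped)
        )
    return windows


class GeneIndex:
    """Interval index over gene models for overlap queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda g: (g.start, g.gene_id))


def assign_gene(
    chrom: str,
    start: int,
    end: int,
    strand: str,
    genes: Sequence[GeneModel] | GeneIndex,
) -> list[tuple[str, bool]]:
    """All genes overlapping [start, end) by >= 1 nt, with a sense flag each.

    Overlap is strand-agnostic (a read is attributed to any overlapping
    gene); the returned flag says whether the query strand matches the
    gene's.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [(g.gene_id, g.strand == strand) for g in index.query(chrom, start, end)]
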