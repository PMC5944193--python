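"""File I/O: FASTQ/FASTA, BED, SAM, GMT, TSV tables.

Reads and tables move through the standard plain-text bioinformatics
formats; gzip is handled transparently for FASTQ by file suffix.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import AlignmentRecord
from .classify import RawRead
from .errors import ParseError, UsageError


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[RawRead]:
    reads = []
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            reads.append(RawRead(
                read_id=title.split()[0],
                sequence=seq.upper(),
                qualities=[ord(c) - 33 for c in qual],
            ))
    return reads


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else [38] * len(r.sequence)
            qual_str = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual_str}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description, >=1 gene",
                                 str(path), i)
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Cohort sample sheet TSV: sample, condition, optional pair_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "condition"):
        if col not in df.columns:
            raise ParseError(f"sample sheet lacks column {col!r}", str(path))
    return df


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """gene_id x sample expression values (TSV, first column = gene_id)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# alignments and intervals
# ---------------------------------------------------------------------------

def write_bed6(rows: Iterable[tuple], path: str | Path, extra_header: Sequence[str] = ()):
    """rows of (chrom, start, end, name, score, strand, *extras)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def windows_to_bed(windows, path: str | Path) -> None:
    write_bed6(((w.chrom, w.start, w.end, w.site_id, 0, w.strand) for w in windows), path)


def ttsa_records_to_bed(records, path: str | Path) -> None:
    """BED6 + site_id, dist3p, tail_class extra columns."""
    write_bed6(
        ((r.alignment.chrom, r.alignment.start, r.alignment.end, r.read_id,
          r.alignment.mismatches, r.alignment.strand, r.site_id, r.dist3p,
          r.tail.tail_class if r.tail else "none")
         for r in records),
        path,
    )


def read_alignments_bed(path: str | Path, tier: str | None = None) -> list[AlignmentRecord]:
    """Precomputed alignments as BED6 (+ optional 7th column = tier).

    Score column is read as the mismatch count; name column as read id.
    """
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError("BED6 needs >= 6 fields", str(path), i)
            out.append(AlignmentRecord(
                read_id=f[3], chrom=f[0], start=int(f[1]), end=int(f[2]),
                strand=f[5], mismatches=int(f[4] or 0),
                tier=f[6] if len(f) > 6 else tier,
            ))
    return out


def read_alignments_sam(path: str | Path, tier: str | None = None) -> list[AlignmentRecord]:
    """Precomputed alignments from SAM/BAM (mismatches from the NM tag)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            out.append(AlignmentRecord(
                read_id=a.query_name,
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_end,
                strand="-" if a.is_reverse else "+",
                mismatches=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                tier=tier,
            ))
    return out


def classified_to_frame(classified) -> pd.DataFrame:
    rows = []
    for cr in classified:
        aln = cr.alignment
        rows.append((cr.read_id, cr.category, len(cr.sequence),
                     aln.chrom if aln else "", aln.start if aln else -1,
                     aln.end if aln else -1, aln.strand if aln else "",
                     aln.mismatches if aln else 0))
    return pd.DataFrame(rows, columns=["read_id", "category", "length", "chrom",
                                       "start", "end", "strand", "mismatches"])


def tail_calls_to_frame(calls) -> pd.DataFrame:
    from .tails import TailCall

    rows = []
    for c in calls:
        if isinstance(c, TailCall):
            rows.append((c.read_id, c.prefix_len, c.tail_seq, c.tail_class, ""))
        else:
            rows.append((c.read_id, -1, "", "", c.reason))
    return pd.DataFrame(rows, columns=["read_id", "prefix_len", "tail_seq",
                                       "tail_class", "no_call_reason"])
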