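"""End-to-end sample processing: FASTQ to called, quantified TTSa-RNAs.

Chains the stages in their canonical order — adapter trimming, QC screen,
tiered classification, untemplated-tail rescue, TTSa calling against 1-nt
polyA-site windows, RPM quantification, and the sequence-feature summaries
(first-nt composition and G-bias test, tail summaries and oligoA
comparison, 3'-proximity stats). Each stage remains individually callable
from its own module; this is the convenience layer the CLI and batch runs
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .align import Aligner, AlignPolicy
from .annotation import GenomeAnnotation, build_windows, filter_polya_sites
from .calling import (DEFAULT_SIZE_RANGE, SampleQuant, TTSaRecord, call_ttsa,
                      proximity_stats, quantify)
from .classify import (ClassifiedRead, QCSummary, QCVerdict, RawRead,
                       classify_hierarchical, qc_dataset, trim_adapter)
from .errors import DegenerateTableError, UsageError
from .seqs import TRUSEQ_SMALL_RNA_ADAPTER
from .stats import CompositionMatrix, FisherResult, composition, g_bias_test
from .tails import (NoCall, TailCall, TailSummary, call_tail, compare_oligoA,
                    summarize_tails)


@dataclass
class PipelineConfig:
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    min_len: int = 18
    size_range: tuple[int, int | None] = DEFAULT_SIZE_RANGE
    sense_only: bool = True
    min_prefix: int = 18
    half_width: int = 2
    exclude_sites: tuple = ()
    policies: Mapping[str, AlignPolicy] | None = None


@dataclass
class SampleResult:
    sample_id: str
    qc: QCSummary
    verdict: QCVerdict
    classified: list[ClassifiedRead]
    tails: dict[str, TailCall | NoCall]
    ttsa_records: list[TTSaRecord]
    quant: SampleQuant
    ttsa_tail_summary: TailSummary
    mirna_tail_summary: TailSummary
    proximity: dict
    ttsa_composition: CompositionMatrix | None
    other_composition: CompositionMatrix | None
    g_bias: FisherResult | None
    oligoa_vs_mirna: FisherResult | None
    windows: list = field(default_factory=list)
    sites: list = field(default_factory=list)
    polya_stats: dict = field(default_factory=dict)


def run_sample(
    raw_reads: Sequence[RawRead],
    refs: Mapping[str, Mapping[str, str] | Aligner],
    annotation: GenomeAnnotation,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
) -> SampleResult:
    """Process one library end to end.

    ``refs`` maps ``mirna``/``trna_rrna``/``genome`` tiers to reference
    sequence dicts (or prebuilt aligners). Tail calls are made against the
    genome for uniquely aligned reads (trivially untailed), for unaligned
    reads (tail rescue), and for miRNA-tier reads (the tailing comparator
    population).
    """
    cfg = config or PipelineConfig()

    trimmed = [trim_adapter(r, cfg.adapter, cfg.min_len) for r in raw_reads]
    _, verdict = qc_dataset(raw_reads, min_len=cfg.min_len)
    classified, qc = classify_hierarchical(trimmed, refs, cfg.policies)

    sites, polya_stats = filter_polya_sites(annotation)
    windows = build_windows(sites, half_width=cfg.half_width,
                            exclude=cfg.exclude_sites,
                            chrom_sizes=annotation.chrom_sizes)

    genome = refs["genome"]
    genome_aligner = genome if isinstance(genome, Aligner) else Aligner(genome, tier="genome")
    tails: dict[str, TailCall | NoCall] = {}
    for cr in classified:
        if cr.category == "genome_unique":
            # a unique exact end-to-end alignment is by definition untailed
            tails[cr.read_id] = TailCall(
                read_id=cr.read_id, prefix_len=len(cr.sequence), tail_seq="",
                tail_class="none", alignment=cr.alignment,
            )
        elif cr.category in ("unaligned", "mirna"):
            tails[cr.read_id] = call_tail(cr.read, genome_aligner,
                                          min_prefix=cfg.min_prefix)

    records = call_ttsa(classified, windows, sites, size_range=cfg.size_range,
                        sense_only=cfg.sense_only, tails=tails)
    quant = quantify(records, qc, genes=annotation.genes, sample_id=sample_id)
    prox = proximity_stats(records)

    ttsa_ids = {r.read_id for r in records}
    ttsa_tail_summary = summarize_tails(
        [r.tail for r in records if r.tail is not None]
    )
    mirna_tail_summary = summarize_tails(
        [tails[cr.read_id] for cr in classified if cr.category == "mirna"]
    )

    ttsa_comp = other_comp = None
    g_bias = oligoa = None
    other_seqs = [cr.sequence for cr in classified
                  if cr.category in ("mirna", "trna_rrna", "genome_unique")
                  and cr.read_id not in ttsa_ids]
    if records:
        seq_by_id = {cr.read_id: cr.sequence for cr in classified}
        ttsa_comp = composition([seq_by_id[r.read_id] for r in records])
    if other_seqs:
        other_comp = composition(other_seqs)
    if ttsa_comp and other_comp:
        try:
            g_bias = g_bias_test(ttsa_comp.first_nt_counts, other_comp.first_nt_counts)
        except (UsageError, DegenerateTableError):
            g_bias = None
    if ttsa_tail_summary.n_called and mirna_tail_summary.n_called:
        try:
            oligoa = compare_oligoA(ttsa_tail_summary, mirna_tail_summary)
        except DegenerateTableError:
            oligoa = None

    return SampleResult(
        sample_id=sample_id, qc=qc, verdict=verdict, classified=classified,
        tails=tails, ttsa_records=records, quant=quant,
        ttsa_tail_summary=ttsa_tail_summary, mirna_tail_summary=mirna_tail_summary,
        proximity=prox, ttsa_composition=ttsa_comp, other_composition=other_comp,
        g_bias=g_bias, oligoa_vs_mirna=oligoa, windows=windows, sites=sites,
        polya_stats=polya_stats,
    )
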