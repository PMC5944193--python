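"""Synthetic genome, annotation, and small-RNA library generator.

Generates a toy reference (random genome carrying genes with 1-nt polyA
sites, miRNA hairpins, and tRNA/rRNA features, all embedded and disjoint)
and seeded FASTQ libraries whose statistical structure follows what AGO-IP
small-RNA sequencing of human cells reports: miRNA-sized hairpin reads,
TTSa reads on the sense strand with 3' ends concentrated within 2 nt of
polyA sites (~63% by default), 21-24 nt sizes, a G-depleted first position
(3.25% vs 8.10% for other aligned reads), and a 3'-tail model mixing
mono-A/mono-U with an oligoA (>= 4 A) component. Per-read ground truth is
emitted for every pipeline stage. Only 5'-monophosphate-like species are
modeled (standard small-RNA library chemistry captures nothing 5'-capped).

Two generation-time conventions keep truth identifiable:

* forcing a read's first nucleotide edits the *genome* base at the read's
  5' position (so the read still maps exactly). Reads sharing a 5' position
  therefore share a first base; truth records a ``first_slot`` key so
  recovery checks can count independent draws, not reads.
* the first base of an untemplated tail is guaranteed to differ from the
  next genomic base (editing the genome or swapping the tail A<->U when
  needed), a mild bias versus nature that makes the true tail the one the
  caller should find.

Because these edits mutate the reference, build a fresh reference per
simulated library (or cohort); determinism is (config, seed) -> bytes on a
fresh reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, PolyASite
from .classify import RawRead
from .errors import PackingError, UsageError
from .seqs import TRUSEQ_SMALL_RNA_ADAPTER, complement, revcomp

CHROM = "chrS"
CLASS_NAMES = ("mirna", "ttsa", "trna_rrna", "background", "antisense_noise")

#: First-nucleotide compositions (G-depleted for TTSa-RNAs, per AGO-IP data).
TTSA_FIRST_NT = {"A": 0.3600, "C": 0.3075, "G": 0.0325, "T": 0.3000}
OTHER_FIRST_NT = {"A": 0.3300, "C": 0.2850, "G": 0.0810, "T": 0.3040}

#: TTSa size distribution over 21-24 nt.
TTSA_SIZE_WEIGHTS = {21: 0.20, 22: 0.35, 23: 0.30, 24: 0.15}

#: Signed 3'-end offset distribution; P(|d| <= 2) = 0.63, remainder spread
#: downstream so that every generated read still overlaps the 5-nt window.
TTSA_DIST3P_WEIGHTS = {
    -2: 0.0756, -1: 0.1260, 0: 0.2268, 1: 0.1260, 2: 0.0756,
    3: 0.1110, 4: 0.0925, 5: 0.0629, 6: 0.0444, 7: 0.0333, 8: 0.0259,
}


@dataclass(frozen=True)
class TailModel:
    """Untemplated 3'-tail model: P(tailed) and class mix given tailed."""

    fraction_tailed: float = 0.23  # endogenous AGO1/2 range is ~0.20-0.27
    class_weights: Mapping[str, float] = field(default_factory=lambda: {
        "monoA": 0.35, "monoU": 0.30, "shortA": 0.15,
        "oligoA": 0.12, "oligoU": 0.05, "other": 0.03,
    })


#: miRNAs are tailed too, but with a much smaller oligoA component.
MIRNA_TAIL_MODEL = TailModel(
    fraction_tailed=0.25,
    class_weights={"monoA": 0.40, "monoU": 0.40, "shortA": 0.08,
                   "oligoA": 0.01, "oligoU": 0.06, "other": 0.05},
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate an AGO-IP nuclear library.

    The default class mixture puts TTSa reads at 1.5e-4 of the library
    (~150 RPM once normalized by aligned reads); use
    :meth:`feature_recovery` for a TTSa-enriched mixture when the point is
    recovering sequence features rather than abundance.
    """

    seed: int = 0
    genome_size: int = 250_000
    n_genes: int = 40
    n_polya_sites: int = 40
    frac_multi_nt: float = 0.002  # fraction of polyA sites annotated > 1 nt
    gene_len_range: tuple[int, int] = (300, 500)
    n_mirna_hairpins: int = 40
    hairpin_len: int = 70
    n_trna_rrna: int = 12
    trna_len_range: tuple[int, int] = (70, 120)
    reads_per_library: int = 20_000
    machine_len: int = 50
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    # AGO-IP libraries are dominated by miRNAs and structural ncRNA
    # fragments; degradation background must be sparse for the measured
    # TTS-window abundance (~150 RPM) to reflect the TTSa fraction, since
    # fragments ending near a short toy gene's 3' end are indistinguishable
    # from TTSa reads by construction.
    class_mixture: dict[str, float] = field(default_factory=lambda: {
        "mirna": 0.71385, "trna_rrna": 0.28, "ttsa": 0.00015,
        "background": 0.005, "antisense_noise": 0.001,
    })
    ttsa_first_nt: dict[str, float] = field(default_factory=lambda: dict(TTSA_FIRST_NT))
    other_first_nt: dict[str, float] = field(default_factory=lambda: dict(OTHER_FIRST_NT))
    ttsa_size_weights: dict[int, float] = field(default_factory=lambda: dict(TTSA_SIZE_WEIGHTS))
    ttsa_dist3p_weights: dict[int, float] = field(default_factory=lambda: dict(TTSA_DIST3P_WEIGHTS))
    ttsa_tail: TailModel = field(default_factory=TailModel)
    mirna_tail: TailModel = field(default_factory=lambda: MIRNA_TAIL_MODEL)
    background_len_range: tuple[int, int] = (18, 35)
    tumor_multiplier: float = 3.0
    degraded: bool = False  # emit the collapsed-quality failure mode

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise UsageError(f"class mixture sums to {total}, expected 1")
        for name, p in self.class_mixture.items():
            if name not in CLASS_NAMES:
                raise UsageError(f"unknown read class {name!r}")
            if not 0 <= p <= 1:
                raise UsageError(f"mixture fraction {name}={p} outside [0,1]")
        for comp in (self.ttsa_first_nt, self.other_first_nt):
            if abs(sum(comp.values()) - 1.0) > 1e-6:
                raise UsageError("first-nt composition must sum to 1")
        if not 0 <= self.ttsa_tail.fraction_tailed <= 1:
            raise UsageError("fraction_tailed outside [0,1]")
        if self.n_polya_sites > self.n_genes:
            raise UsageError("cannot have more polyA sites than genes")

    @classmethod
    def feature_recovery(cls, **overrides) -> "SyntheticConfig":
        """TTSa-enriched mixture for sequence-feature recovery runs."""
        mix = {"mirna": 0.25, "trna_rrna": 0.05, "ttsa": 0.50,
               "background": 0.195, "antisense_noise": 0.005}
        overrides.setdefault("class_mixture", mix)
        return cls(**overrides)

    @classmethod
    def flag_ago2(cls, **overrides) -> "SyntheticConfig":
        """FLAG-AGO2-like preset: 41% of TTSa-RNAs carry a 3' tail."""
        overrides.setdefault("ttsa_tail", TailModel(fraction_tailed=0.41))
        cfg = cls.feature_recovery(**overrides)
        return cfg


@dataclass
class _Hairpin:
    name: str
    start: int
    end: int
    mature_start: int  # 5' start of the canonical mature arm


@dataclass
class _Feature:
    name: str
    start: int
    end: int


@dataclass
class SyntheticReference:
    """Mutable reference bundle; library simulation edits ``genome`` in place."""

    config: SyntheticConfig
    genome: bytearray
    genes: list[GeneModel]
    polya_sites: list[PolyASite]
    hairpins: list[_Hairpin]
    trnas: list[_Feature]
    first_slots: dict[int, str] = field(default_factory=dict)

    @property
    def genome_str(self) -> str:
        return self.genome.decode("ascii")

    def genome_fasta(self) -> dict[str, str]:
        return {CHROM: self.genome_str}

    def mirna_fasta(self) -> dict[str, str]:
        g = self.genome_str
        return {h.name: g[h.start:h.end] for h in self.hairpins}

    def trna_rrna_fasta(self) -> dict[str, str]:
        g = self.genome_str
        return {f.name: g[f.start:f.end] for f in self.trnas}

    def annotation(self) -> GenomeAnnotation:
        return GenomeAnnotation(
            chrom_sizes={CHROM: len(self.genome)},
            genes=list(self.genes),
            polya_sites=list(self.polya_sites),
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome/tier FASTAs and the GTF; returns the path map."""
        from .io import write_fasta
        from .annotation import write_annotation

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "mirna": outdir / "mirna_hairpins.fa",
            "trna_rrna": outdir / "trna_rrna.fa",
            "annotation": outdir / "annotation.gtf",
        }
        write_fasta(self.genome_fasta(), paths["genome"])
        write_fasta(self.mirna_fasta(), paths["mirna"])
        write_fasta(self.trna_rrna_fasta(), paths["trna_rrna"])
        write_annotation(self.annotation(), paths["annotation"], dialect="gtf")
        return paths


def _sample(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights)
    p = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def make_reference(config: SyntheticConfig) -> SyntheticReference:
    """Build the genome, gene/polyA annotation, and tier features.

    All features (genes, hairpins, tRNA/rRNA) are disjoint intervals
    embedded in a random genome, so hairpin/tRNA reads also have genomic
    loci and tier precedence is what separates them. Each of the first
    ``n_polya_sites`` genes gets one polyA site at its 3' end; a
    ``frac_multi_nt`` minority is annotated with a 2-4 nt span to exercise
    the 1-nt filter. Deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    glo, ghi = config.gene_len_range
    tlo, thi = config.trna_len_range
    gene_lens = rng.integers(glo, ghi + 1, size=config.n_genes)
    trna_lens = rng.integers(tlo, thi + 1, size=config.n_trna_rrna)
    lens = (list(gene_lens) + [config.hairpin_len] * config.n_mirna_hairpins
            + list(trna_lens))
    kinds = (["gene"] * config.n_genes + ["hairpin"] * config.n_mirna_hairpins
             + ["trna"] * config.n_trna_rrna)
    total = int(sum(lens))
    if config.genome_size < 10 * total:
        raise PackingError(
            f"genome_size {config.genome_size} < 10x total feature length {total}"
        )

    order = rng.permutation(len(lens))
    margin = 30  # keep windows and read 3' jitter inside the chromosome
    free = config.genome_size - total - margin * (len(lens) + 1)
    offsets = np.sort(rng.choice(free, size=len(lens), replace=False))
    genome = bytearray(
        bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.genome_size))
    )

    genes: list[GeneModel] = []
    hairpins: list[_Hairpin] = []
    trnas: list[_Feature] = []
    cursor = 0
    for slot, idx in enumerate(order):
        start = int(offsets[slot]) + cursor + margin * (slot + 1)
        length = int(lens[idx])
        end = start + length
        cursor += length
        kind = kinds[idx]
        if kind == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gene_id=f"GENE{idx:04d}", chrom=CHROM,
                                   strand=strand, start=start, end=end))
        elif kind == "hairpin":
            hairpins.append(_Hairpin(name=f"hp-{idx}", start=start, end=end,
                                     mature_start=start + 15))
        else:
            trnas.append(_Feature(name=f"ncrna-{idx}", start=start, end=end))
    genes.sort(key=lambda g: g.start)

    sites: list[PolyASite] = []
    for i, g in enumerate(genes[: config.n_polya_sites]):
        pos = g.end - 1 if g.strand == "+" else g.start
        length = int(rng.integers(2, 5)) if rng.random() < config.frac_multi_nt else 1
        sites.append(PolyASite(site_id=f"pas_{i:05d}", chrom=CHROM, position=pos,
                               strand=g.strand, gene_id=g.gene_id,
                               annotated_length=length))

    ref = SyntheticReference(config=config, genome=genome, genes=genes,
                             polya_sites=sites, hairpins=hairpins, trnas=trnas)
    # pre-sample the first base of each possible mature-miRNA 5' start
    # (3 isomiR-like jitter offsets per hairpin) from the "other" composition
    for h in hairpins:
        for j in range(3):
            base = _sample(rng, config.other_first_nt)
            genome[h.mature_start + j] = ord(base)
    return ref


# ---------------------------------------------------------------------------
# read planning / genome editing / emission
# ---------------------------------------------------------------------------

@dataclass
class _ReadPlan:
    cls: str
    start: int
    end: int
    strand: str
    site_id: str = ""
    dist3p: float = float("nan")
    first_comp: str = ""      # "ttsa" | "other" | "" (no forcing)
    first_slot: str = ""
    tail_seq: str = ""
    tail_class: str = "none"


_TAIL_LEN = {"monoA": (1,), "monoU": (1,), "shortA": (2, 3),
             "oligoA": (4, 5, 6), "oligoU": (2, 3), "other": (1, 2, 3)}


def _make_tail(rng: np.random.Generator, model: TailModel) -> tuple[str, str]:
    if rng.random() >= model.fraction_tailed:
        return "", "none"
    cls = _sample(rng, model.class_weights)
    length = int(rng.choice(_TAIL_LEN[cls]))
    if cls in ("monoA", "shortA", "oligoA"):
        seq = "A" * length
    elif cls in ("monoU", "oligoU"):
        seq = "T" * length
    else:  # mixed tail; guarantee it is not all-A or all-T
        bases = list("ACGT")
        seq = "".join(rng.choice(bases) for _ in range(length))
        if set(seq) in ({"A"}, {"T"}):
            seq = seq[:-1] + ("C" if seq[-1] != "C" else "G")
        if length == 1 and seq in ("A", "T"):
            seq = "C"
    return seq, cls


def _swap_tail(plan: _ReadPlan, genome_next_read_orient: str) -> None:
    """A<->U swap fallback when the planned tail start is templated."""
    seq = plan.tail_seq
    if set(seq) == {"A"}:
        seq = "T" * len(seq)
    elif set(seq) == {"T"}:
        seq = "A" * len(seq)
    else:
        for b in "CGAT":
            if b != genome_next_read_orient and (b + seq[1:]) != seq:
                seq = b + seq[1:]
                break
    plan.tail_seq = seq
    from .tails import classify_tail
    plan.tail_class = classify_tail(seq)


def _plan_reads(config: SyntheticConfig, refs: SyntheticReference,
                rng: np.random.Generator, n_reads: int,
                mixture: Mapping[str, float]) -> list[_ReadPlan]:
    names = [c for c in CLASS_NAMES if mixture.get(c, 0) > 0]
    probs = np.array([mixture[c] for c in names], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(len(names), size=n_reads, p=probs)

    sites_1nt = [s for s in refs.polya_sites if s.annotated_length == 1]
    if any(names[i] in ("ttsa", "antisense_noise") for i in set(draw)) and not sites_1nt:
        raise UsageError("no 1-nt polyA sites to draw TTSa reads from")

    plans: list[_ReadPlan] = []
    for k in draw:
        cls = names[k]
        if cls == "mirna":
            h = refs.hairpins[int(rng.integers(len(refs.hairpins)))]
            j = int(_sample(rng, {0: 0.60, 1: 0.25, 2: 0.15}))
            L = int(_sample(rng, {21: 0.30, 22: 0.45, 23: 0.25}))
            start = h.mature_start + j
            tail, tcls = _make_tail(rng, config.mirna_tail)
            plans.append(_ReadPlan(cls, start, start + L, "+",
                                   first_slot=f"{h.name}:{j}",
                                   tail_seq=tail, tail_class=tcls))
        elif cls == "trna_rrna":
            f = refs.trnas[int(rng.integers(len(refs.trnas)))]
            L = int(rng.integers(18, 31))
            start = int(rng.integers(f.start, f.end - L + 1))
            plans.append(_ReadPlan(cls, start, start + L, "+",
                                   first_comp="other", first_slot=f"pos:+:{start}"))
        elif cls == "background":
            g = refs.genes[int(rng.integers(len(refs.genes)))]
            lo, hi = config.background_len_range
            L = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(g.start, g.end - L + 1))
            slot_pos = start if g.strand == "+" else start + L - 1
            plans.append(_ReadPlan(cls, start, start + L, g.strand,
                                   first_comp="other",
                                   first_slot=f"pos:{g.strand}:{slot_pos}"))
        else:  # ttsa / antisense_noise around a polyA site
            s = sites_1nt[int(rng.integers(len(sites_1nt)))]
            d = int(_sample(rng, config.ttsa_dist3p_weights))
            L = int(_sample(rng, config.ttsa_size_weights))
            if s.strand == "+":
                end3 = s.position + d
                start, end = end3 - L + 1, end3 + 1
            else:
                end3 = s.position - d
                start, end = end3, end3 + L
            if cls == "ttsa":
                tail, tcls = _make_tail(rng, config.ttsa_tail)
                slot_pos = start if s.strand == "+" else end - 1
                plans.append(_ReadPlan("ttsa", start, end, s.strand,
                                       site_id=s.site_id, dist3p=d,
                                       first_comp="ttsa",
                                       first_slot=f"pos:{s.strand}:{slot_pos}",
                                       tail_seq=tail, tail_class=tcls))
            else:
                strand = "-" if s.strand == "+" else "+"
                plans.append(_ReadPlan("antisense_noise", start, end, strand,
                                       site_id=s.site_id, dist3p=d))
    return plans


def _apply_edits(refs: SyntheticReference, plans: list[_ReadPlan],
                 rng: np.random.Generator, config: SyntheticConfig) -> None:
    genome = refs.genome
    forced = refs.first_slots
    comps = {"ttsa": config.ttsa_first_nt, "other": config.other_first_nt}
    for p in plans:
        if not p.first_comp:
            continue
        pos = p.start if p.strand == "+" else p.end - 1
        base = _sample(rng, comps[p.first_comp])  # drawn unconditionally: keeps
        if pos not in forced:                     # the stream seed-stable
            gbase = base if p.strand == "+" else complement(base)
            genome[pos] = ord(gbase)
            forced[pos] = gbase

    tail_forbidden: dict[int, set[str]] = {}
    for p in plans:
        if not p.tail_seq:
            continue
        np_pos = p.end if p.strand == "+" else p.start - 1
        if not (0 <= np_pos < len(genome)):
            continue
        forbidden = p.tail_seq[0] if p.strand == "+" else complement(p.tail_seq[0])
        seen = tail_forbidden.setdefault(np_pos, set())
        seen.add(forbidden)
        cur = chr(genome[np_pos])
        if cur != forbidden:
            continue
        free = [b for b in "ACGT" if b not in seen]
        if np_pos in forced or not free:
            next_read_orient = cur if p.strand == "+" else complement(cur)
            _swap_tail(p, next_read_orient)
        else:
            genome[np_pos] = ord(free[int(rng.integers(len(free)))])


_TRUTH_COLUMNS = ["read_id", "true_class", "chrom", "start", "end", "strand",
                  "insert_len", "site_id", "dist3p", "tail_seq", "tail_class",
                  "first_nt", "first_slot"]


def _emit(refs: SyntheticReference, plans: list[_ReadPlan],
          rng: np.random.Generator, config: SyntheticConfig,
          sample_id: str) -> tuple[list[RawRead], pd.DataFrame]:
    g = refs.genome_str
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    reads: list[RawRead] = []
    rows = []
    for i, p in enumerate(plans):
        insert = g[p.start:p.end]
        if p.strand == "-":
            insert = revcomp(insert)
        full = insert + p.tail_seq + config.adapter
        if len(full) < config.machine_len:
            pad = bytes(rng.choice(bases, size=config.machine_len - len(full)))
            full += pad.decode("ascii")
        else:
            full = full[: config.machine_len]
        if config.degraded:
            quals = [38] * min(16, len(full)) + [2] * max(0, len(full) - 16)
        else:
            quals = [38] * len(full)
        rid = f"{sample_id}_{i:06d}"
        reads.append(RawRead(read_id=rid, sequence=full, qualities=quals))
        rows.append((rid, p.cls, CHROM, p.start, p.end, p.strand,
                     len(insert) + len(p.tail_seq), p.site_id, p.dist3p,
                     p.tail_seq, p.tail_class, insert[0], p.first_slot))
    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return reads, truth


def simulate_library(
    config: SyntheticConfig,
    refs: SyntheticReference,
    seed: int | None = None,
    sample_id: str = "s1",
    n_reads: int | None = None,
    mixture: Mapping[str, float] | None = None,
) -> tuple[list[RawRead], pd.DataFrame]:
    """Simulate one small-RNA library plus its per-read ground truth.

    Mutates ``refs.genome`` (first-nucleotide and tail-untemplatedness
    edits), so classify against references extracted *after* this call.
    Returns raw reads (insert + tail + adapter, padded to machine length)
    and the truth table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plans = _plan_reads(config, refs, rng,
                        n_reads if n_reads is not None else config.reads_per_library,
                        mixture or config.class_mixture)
    _apply_edits(refs, plans, rng, config)
    return _emit(refs, plans, rng, config, sample_id)


def simulate_cohort(
    config: SyntheticConfig,
    refs: SyntheticReference | None,
    n_tumor: int,
    n_control: int,
    paired: bool = True,
    tumor_multiplier: float | None = None,
    emit: str = "counts",
    seed: int | None = None,
) -> dict:
    """Simulate a tumor/control cohort of TTSa abundances.

    Tumor samples scale the TTSa mixture fraction by ``tumor_multiplier``
    (renormalized); in paired mode tumor and control share a per-pair
    baseline rate (lognormal patient effect). Two emit modes:

    * ``"counts"`` — draw per-sample TTSa counts and RPM directly from the
      generative model without materializing reads. Fast; the table feeds
      cohort tests directly.
    * ``"fastq"`` — full per-sample read sets with truth. All samples are
      planned jointly before genome edits so every read stays exactly
      mappable against the final reference.

    Returns a dict with ``sheet`` (sample/condition/pair_id), ``table``
    (sample-level TTSa RPM) and, in fastq mode, ``samples`` mapping
    sample id to (reads, truth).
    """
    if n_control < 2 or n_tumor < 2:
        raise UsageError("need at least 2 samples per arm (a single control "
                         "sample cannot support a cohort comparison)")
    if paired and n_tumor != n_control:
        raise UsageError("paired mode requires equal arm sizes")
    mult = config.tumor_multiplier if tumor_multiplier is None else tumor_multiplier
    rng = np.random.default_rng(config.seed if seed is None else seed)

    base_ttsa = config.class_mixture["ttsa"]
    samples = []  # (sample, condition, pair_id, ttsa_rate)
    if paired:
        for i in range(n_tumor):
            patient = float(np.exp(rng.normal(0.0, 0.4)))
            samples.append((f"tumor_{i}", "tumor", f"p{i}",
                            min(base_ttsa * patient * mult, 0.9)))
            samples.append((f"control_{i}", "control", f"p{i}",
                            min(base_ttsa * patient, 0.9)))
    else:
        for i in range(n_tumor):
            patient = float(np.exp(rng.normal(0.0, 0.4)))
            samples.append((f"tumor_{i}", "tumor", None,
                            min(base_ttsa * patient * mult, 0.9)))
        for i in range(n_control):
            patient = float(np.exp(rng.normal(0.0, 0.4)))
            samples.append((f"control_{i}", "control", None,
                            min(base_ttsa * patient, 0.9)))

    sheet = pd.DataFrame(
        [(s, c, p) for s, c, p, _ in samples],
        columns=["sample", "condition", "pair_id"],
    )

    def renorm(rate: float) -> dict[str, float]:
        rest = 1.0 - base_ttsa
        scale = (1.0 - rate) / rest if rest > 0 else 0.0
        mix = {k: v * scale for k, v in config.class_mixture.items() if k != "ttsa"}
        mix["ttsa"] = rate
        return mix

    n_lib = config.reads_per_library
    if emit == "counts":
        rows = []
        for name, cond, pair, rate in samples:
            n_ttsa = int(rng.binomial(n_lib, rate))
            n_tailed = int(rng.binomial(n_ttsa, config.ttsa_tail.fraction_tailed))
            denom = n_lib - n_tailed  # tailed reads fail exact genome alignment
            rows.append((name, cond, pair, n_ttsa, denom, n_ttsa / denom * 1e6))
        table = pd.DataFrame(rows, columns=["sample", "condition", "pair_id",
                                            "ttsa_count", "aligned", "ttsa_rpm"])
        return {"sheet": sheet, "table": table, "samples": None}

    if emit != "fastq":
        raise UsageError(f"unknown emit mode {emit!r}")
    if refs is None:
        raise UsageError("fastq mode requires a reference")
    # plan all samples, run one joint edit pass, then emit per sample
    per_sample_plans = []
    for name, cond, pair, rate in samples:
        per_sample_plans.append(
            (name, _plan_reads(config, refs, rng, n_lib, renorm(rate)))
        )
    all_plans = [p for _, plans in per_sample_plans for p in plans]
    _apply_edits(refs, all_plans, rng, config)
    out = {}
    rows = []
    for name, plans in per_sample_plans:
        reads, truth = _emit(refs, plans, rng, config, name)
        out[name] = (reads, truth)
        n_ttsa = int((truth["true_class"] == "ttsa").sum())
        n_tailed = int(((truth["true_class"] == "ttsa") & (truth["tail_seq"] != "")).sum())
        denom = n_lib - n_tailed
        cond = sheet.loc[sheet["sample"] == name, "condition"].iloc[0]
        pair = sheet.loc[sheet["sample"] == name, "pair_id"].iloc[0]
        rows.append((name, cond, pair, n_ttsa, denom, n_ttsa / denom * 1e6))
    table = pd.DataFrame(rows, columns=["sample", "condition", "pair_id",
                                        "ttsa_count", "aligned", "ttsa_rpm"])
    return {"sheet": sheet, "table": table, "samples": out}
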