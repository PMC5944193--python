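# Methods

## The analysis

`ttsakit` identifies transcription termination site-associated small RNAs
(TTSa-RNAs) in small-RNA sequencing libraries. Operationally, a TTSa-RNA is
a read that (i) survives adapter trimming at ≥ 18 nt, (ii) fails to align
to miRNA hairpins or tRNA/rRNA references, (iii) aligns exactly, uniquely
and end-to-end to the genome (or, when it carries an untemplated 3' tail,
has a unique exactly matching 5' prefix), and (iv) overlaps by at least
1 nt a 5-nt window centered on an annotated 1-nt polyadenylation site, on
the site's strand, within the configured size range. The polyA position is
the operational transcription termination site (TTS).

### Tiered classification

The cascade assigns each read to the first tier that accepts it: miRNA
hairpins, then tRNA/rRNA, then the genome. The two ncRNA tiers use a
tolerant policy (up to 2 mismatches inside the 5'-most 18-nt seed and 2
overall); the genome tier demands a single exact end-to-end alignment.
Reads with several genome alignments are set aside as multi-mapping; reads
with none go to the tail caller. The RPM denominator is the number of
reads with a valid alignment in any tier.

The built-in aligner is ungapped and enumerates candidates by the
pigeonhole principle (split the seed into `s+1` chunks; a valid alignment
must match one chunk exactly), then verifies both mismatch budgets per
candidate. Exact end-to-end policies instead anchor on a cached 18-mer
index of the reference. Two deliberate simplifications relative to a
quality-aware aligner: mismatch *counts* replace quality-weighted budgets
(synthetic qualities carry no information), and `N` never matches any
base, so an `N` consumes one unit of mismatch budget and exact policies
reject N-containing reads. The aligner targets desk-scale references
(up to a few tens of Mb); for genome-scale work the pipeline accepts
precomputed, tier-tagged alignments (SAM or BED6+tier) through
`classify_from_alignments`.

### Untemplated 3' tails

Tail calling finds the longest read prefix (≥ 18 nt, configurable) with an
exact, strand-aware, unique genome match; the unmatched suffix is the
tail. This replaces a suffix-trie tail aligner with iterative
longest-prefix matching — an identical contract at these reference sizes.
Reads whose longest matching prefix is multi-mapping are not called by
default (`allow_shorter_unique=False`); the relaxed mode keeps descending
to a shorter unique prefix. Tail classes partition all non-empty tails:
monoA (`A`), monoU (`T`; uracil is written as T throughout), shortA (2–3
A), oligoA (≥ 4 A, the class enriched in TTSa-RNAs), oligoU (≥ 2 T), and
`other` for anything mixed. Uniquely genome-aligned reads are untailed by
construction and are recorded as such without re-alignment.

### Calling, quantification, coverage

A read overlapping several polyA-site windows is assigned the site whose
position is closest to the read's templated 3' end (ties: smaller genomic
coordinate, then site id) — 3'-end proximity is the defining feature of
the class. Coverage metaprofiles instead attribute each read to the
closest site by read *midpoint*, each read counting toward a single site
only, accumulating ±500 nt around the site in site-strand orientation and
split by read/site strand match. Antisense reads are excluded from TTSa
calls but retained in coverage. The signed 3'-end offset (`dist3p`) is
positive downstream of the site in the site's orientation. `parclip_mode`
restricts coverage input to alignments carrying exactly one mismatch (the
crosslinking signature) and reports the mismatch spectrum, where T>C
should dominate for genuinely crosslinked material.

RPM is `reads_of_interest / aligned_reads × 1e6` with the denominator from
the classification step. No further normalization is applied.

### Statistics

* First-position G depletion: Fisher exact test on (G vs not-G) × (TTSa vs
  other aligned reads). The test is assembled from hypergeometric log
  point probabilities, so p-values below float underflow (common at these
  library sizes) remain reportable as `log10_pvalue`. The comparator
  population defaults to all non-TTSa reads aligned in any tier.
* OligoA excess over miRNAs: the same exact test on (oligoA vs other
  outcome) × (TTSa vs miRNA) over all called reads.
* Expression correlation: genes below the first tertile of mean expression
  are dropped, then gene-sample points with TTSa RPM in the first three
  quartiles are dropped (such points carry only a handful of reads);
  Spearman rho on the rest, reported as R² = rho². Quantiles use the
  inclusive linear (type-7) convention for bit-reproducibility; at least
  3 points must survive or `InsufficientDataError` is raised.
* Cohorts: paired samples (complete `pair_id`) use the signed-rank test,
  unpaired the rank-sum test; exact null enumeration when ≤ 25
  observations with no ties/zeros, otherwise the normal approximation with
  continuity correction — the conventional `wilcox.test` contract.
  All-tied data returns p = 1 with a warning.
* Gene-set enrichment: hypergeometric upper tail against a user-supplied
  background, Benjamini–Hochberg q-values, fold enrichment
  `(k/n)/(K/N)`, reported sorted by decreasing fold enrichment with a
  top-10 convenience view at FDR < 0.01.

### Library QC

A dataset is flagged unsuitable when the median Phred score is ≤ 2 at
every position beyond 16 (quality collapse) or when every read is shorter
than 18 nt (too short for unique mapping). The Shannon entropy of the
trimmed-read size distribution is reported as an advisory degradation
indicator — random mRNA fragmentation is broad and high-entropy — but does
not flip the verdict on its own.

## Size-filter modes

Cell-line / IP mode applies only the ≥ 18 nt minimum (`size_range=(18,
None)`); primary-tissue mode uses 18–26 nt
(`PRIMARY_TISSUE_SIZE_RANGE`). A broader "< 28 nt" reading of the
primary-tissue filter exists in the field; both are exposed via
`size_range`, and the package does not guess which was intended — the
default is the stricter 18–26.

## The synthetic-data generator

The generator builds a random genome carrying disjoint genes (each with
one polyA site at its 3' end), miRNA hairpins, and tRNA/rRNA features, all
embedded so that hairpin/tRNA reads also have genomic loci and tier
precedence is what separates them. Libraries mix five read classes —
miRNA-sized hairpin reads, TTSa reads, tRNA/rRNA fragments, uniform
"degradation" background from gene bodies (18–35 nt), and antisense noise
at TTS windows — then append the TruSeq small-RNA adapter and pad reads to
50 nt machine length. Only 5'-monophosphate-like species are modeled, as
in standard small-RNA library chemistry.

Defaults are the study conditions the package is calibrated to emulate:
TTSa sizes over 21–24 nt (0.20/0.35/0.30/0.15); a signed 3'-offset
distribution with P(|dist3p| ≤ 2) = 0.63, its remainder spread over +3..+8
so every generated TTSa read still overlaps its 5-nt window; first-nt
compositions with 3.25% G for TTSa reads and 8.10% G for other aligned
reads; a tail model with 23% tailed (endogenous AGO1/2-like; the
`flag_ago2` preset raises this to 41%) mixing monoA/monoU/shortA with an
oligoA component of 12% of tails, against a miRNA tail model with a 1%
oligoA component; and a default class mixture putting TTSa reads at
1.5 × 10⁻⁴ of the library (~150 RPM, the AGO-IP regime). In the default
mixture, degradation background is 0.5% of reads: toy genes are only a few
hundred nt, so background fragments ending at a gene's 3' end are
indistinguishable from TTSa reads, and a heavier background share would be
inconsistent with the ~150 RPM abundance regime the preset emulates
(IP-selected libraries are correspondingly clean; the feature-recovery
preset keeps a 19.5% background share for tests where degradation is the
point). 0.2% of polyA
sites are annotated with a 2–4 nt span to exercise the 1-nt filter. Where
the emulated studies report only qualitative figures (exact size weights,
tail-length mix, antisense rate), the values above were fixed once as
plausible and are configuration, not estimates.

Two generation-time conventions keep truth identifiable:

* **First-nucleotide forcing edits the genome.** A read's first base is
  drawn from the configured composition and written into the genome at the
  read's 5' position (complemented on the minus strand), so the read still
  maps exactly. Reads sharing a 5' position therefore share a first base;
  the truth table records a `first_slot` key per read, and recovery checks
  compute standard errors over independent slots weighted by read count —
  the correct SE for this design — rather than over reads. miRNA
  first bases are pre-drawn per hairpin at three isomiR-like 5' offsets.
* **Tails are untemplated by construction.** The first tail base must
  differ from the next genomic base in read orientation; when it would
  not, the generator edits that genomic base (if nothing else pinned it)
  or swaps the tail A↔U as a rare fallback. This is a mild bias relative
  to nature, where a tail can begin with a templated-looking base.

Because these edits mutate the reference, tier FASTAs and the genome must
be extracted *after* simulation, and a reference object is single-use per
library (cohorts in FASTQ mode plan all samples jointly before a single
edit pass). Determinism is (config, seed) → bytes on a fresh reference.

What the generator does not emulate: real hg38 sequence composition and
repeat structure (multi-mapping is therefore much rarer than in real
data), splicing, expression-correlated read depth per gene (sites are
sampled uniformly), quality-value noise (constant Phred 38, plus a
`degraded` preset reproducing the quality-collapse failure mode), and
PCR/ligation biases. Passing recovery tests therefore demonstrates that
the pipeline's measurements are unbiased estimators of the generative
parameters at realistic mixture proportions — not that it is robust to
repeat-rich genomes or chemistry artifacts.

A note on background reads: degradation fragments drawn from gene bodies
are sense-strand and occasionally end near the gene's polyA site, so a few
percent of called TTSa records in enriched mixtures are such fragments.
This is faithful to real libraries (where the same ambiguity exists) and
is why recovery tests distinguish called-set statistics from
true-class-restricted statistics.

## Problem sizes and numerical choices

The shared test library is 120k reads over a 1 Mb genome with 200 polyA
sites; the acceptance script simulates 200k-read libraries (1 Mb genome
for sequence features; the default 250 kb reference for abundance), a
5000-site annotation for the 1-nt filter fraction, 10-pair cohorts, and a
3500-gene expression table — sizes chosen so every statistic has a few
thousand effective replicates while a run stays comfortably on one CPU.
Oracle-equivalence suites run the built-in aligner against a
numpy full scan (1000 reads × 100 kb), the tail caller against a
prefix-descent oracle (10,000 reads, tails 0–6 nt), TTSa calling against a
read × window double loop (100 instances), and every exact test against
rational-arithmetic enumeration (n ≤ 12). Null calibration of the cohort
test uses 20-pair cohorts: the exact signed-rank p-value is discrete, and
below ~16 pairs its null CDF has plateaus wide enough to fail a
continuous-uniform KS check regardless of correctness.

Tie-breaks are deterministic everywhere: alignment output is sorted by
(chrom, start, strand); site assignment by (3'-distance, coordinate, site
id); coverage attribution prefers the smaller coordinate at equidistance.
Degenerate inputs return explicit markers rather than guesses: empty
summaries report `None` fractions, zero-margin 2×2 tables raise
`DegenerateTableError`, a zero RPM denominator raises, and windows clipped
at chromosome edges are flagged and logged.

## Known limitations

* The aligner and tail caller are exact/ungapped by design; indels,
  spliced alignments, and colorspace data are out of scope.
* Bowtie-style quality-budget seeding is approximated by mismatch counts;
  on real data with poor 3' qualities the tier boundaries can differ
  slightly from a quality-aware aligner.
* The g-bias comparator population ("other aligned reads") is one of
  several defensible choices; `g_bias_test` takes raw counts, so any
  comparator can be supplied.
* GO-style enrichment is generic gene-set enrichment over a GMT file; no
  ontology-specific slicing or term relationships are implemented.
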