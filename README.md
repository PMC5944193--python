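# ttsakit

Identification and characterization of **transcription termination
site-associated small RNAs (TTSa-RNAs)** from small-RNA sequencing data.

TTSa-RNAs are a class of Argonaute-bound small RNAs, 21–24 nt long, that
arise from the sense strand of expressed genes with 3' ends clustering
within ~2 nt of the annotated polyadenylation site. They are G-depleted at
the first 5' position (a hallmark of AGO loading), frequently carry short
untemplated 3' tails with a distinctive oligoA (≥ 4 A) component, and
their abundance rises in tumor tissue relative to matched controls. This
package is for computational biologists who want to call and characterize
this class reproducibly: it implements the full analysis at desk scale —
adapter trimming, the tiered miRNA → tRNA/rRNA → unique-genome alignment
cascade, untemplated-tail calling, window-based TTSa calling with RPM
quantification, coverage metaprofiles around polyA sites (with a PAR-CLIP
single-mismatch mode), sequence-feature statistics, expression
correlation, cohort comparison, gene-set enrichment — plus a synthetic
library generator with per-read ground truth for every stage.

## The core definitions

With polyA sites restricted to 1-nt annotations, a read is a TTSa-RNA iff

* it survives adapter trimming at ≥ 18 nt and aligns to neither the miRNA
  hairpin nor the tRNA/rRNA reference tier (≤ 2 mismatches in the 18-nt 5'
  seed, ≤ 2 overall),
* it aligns to the genome exactly, uniquely, end-to-end — or its longest
  exactly matching 5' prefix (≥ 18 nt) is unique, the unmatched suffix
  being an untemplated tail,
* its alignment overlaps by ≥ 1 nt the 5-nt window centered on a polyA
  site, on the site's strand, within the size range (18 nt minimum;
  18–26 nt in primary-tissue mode).

Abundance is RPM = TTSa reads / reads aligned in any tier × 10⁶. The
first-position G test is Fisher exact on (G vs not-G) × (TTSa vs other
aligned reads); tail classes partition into monoA/monoU/shortA/
oligoA/oligoU/other; cohorts are compared by Wilcoxon tests (signed-rank
when tumor/control samples are paired); R² is the square of the Spearman
rank correlation after tertile (expression) and quartile (TTSa RPM)
filtering.

## Worked example

Simulate a TTSa-enriched library with ground truth and run the full
pipeline on it:

```python
import ttsakit as tk

cfg = tk.SyntheticConfig.feature_recovery(seed=7, reads_per_library=20_000)
refs = tk.make_reference(cfg)
reads, truth = tk.simulate_library(cfg, refs)   # edits refs.genome in place
res = tk.run_sample(
    reads,
    {"mirna": refs.mirna_fasta(), "trna_rrna": refs.trna_rrna_fasta(),
     "genome": refs.genome_fasta()},             # extract refs *after* simulating
    refs.annotation(),
)
```

which prints, for the summaries shown:

```
categories:        {'mirna': 4864, 'trna_rrna': 1006, 'genome_unique': 11765, 'genome_multi': 0, 'unaligned': 2365}
TTSa-RNAs called:  9981  (RPM 565977)
3' within 2 nt:    0.629
first-nt %G:       TTSa 3.62  vs other 9.24  (Fisher log10 p = -59.9)
fraction tailed:   0.228
oligoA vs miRNA:   odds ratio inf, p = 8.07e-47
```

Reading this: the cascade kept every read's first accepting tier
(`unaligned` is mostly tailed TTSa reads, later rescued by the tail
caller); 9,981 TTSa-RNAs were called, 62.9% of whose 3' ends sit within
2 nt of the polyA site (the generator draws 63%); the first-position G
fraction is depleted in TTSa-RNAs (3.6% vs 9.2%, configured 3.25% vs
8.10%, recovered within slot-level sampling error); 22.8% carry a 3' tail
(configured 23%), with oligoA tails essentially absent from miRNAs at
this depth (hence the infinite sample odds ratio).

The same stages are scriptable from the shell — `ttsa simulate`,
`ttsa classify`, `ttsa tails`, `ttsa call`, `ttsa coverage`,
`ttsa stats ...` — each a thin wrapper over the functions above; run
`ttsa --help`.

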