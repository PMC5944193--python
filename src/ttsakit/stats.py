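"""Sequence-feature and cohort statistics.

Covers the analyses layered on top of TTSa calling: per-position nucleotide
composition and the first-position G-depletion test, correlation of TTSa
abundance with gene expression under tertile/quartile abundance filters,
tumor-vs-control cohort comparison by Wilcoxon tests, and generic
hypergeometric gene-set enrichment with Benjamini-Hochberg control.

Exact 2x2 tests are assembled from hypergeometric log point probabilities
so that p-values far below float underflow are still meaningful in log
space (AGO-bound libraries give first-nt G tests with p << 1e-300).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateTableError, InsufficientDataError, UsageError

LOG10E = np.log10(np.e)


# ---------------------------------------------------------------------------
# exact 2x2 Fisher test (log-space)
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    pvalue: float
    log10_pvalue: float


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric point probabilities that do not exceed
    the observed table's probability (the conventional two-sided rule).
    Computed fully in log space; ``pvalue`` may underflow to 0.0 for
    extreme tables, in which case ``log10_pvalue`` carries the result.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise UsageError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise DegenerateTableError(f"degenerate_table: zero margin in {table}")
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logpmf = sps.hypergeom.logpmf(support, n, c1, r1)
    log_obs = sps.hypergeom.logpmf(a, n, c1, r1)
    keep = logpmf <= log_obs + 1e-7  # tolerate fp noise at ties
    if keep.all():
        log_p = 0.0  # whole support included: p is exactly 1
    else:
        log_p = min(float(logsumexp(logpmf[keep])), 0.0)
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return FisherResult(
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        pvalue=float(np.exp(log_p)),
        log10_pvalue=float(log_p * LOG10E),
    )


# ---------------------------------------------------------------------------
# nucleotide composition and first-position G bias
# ---------------------------------------------------------------------------

@dataclass
class CompositionMatrix:
    """Per-position base frequencies over a read set.

    ``freqs`` is positions (1-based index) x {A,C,G,T}; each row sums to 1
    over the reads long enough to cover that position (``n`` per row).
    """

    freqs: pd.DataFrame
    n: pd.Series
    first_nt: dict[str, float]
    first_nt_counts: dict[str, int]


def composition(reads: Iterable) -> CompositionMatrix:
    """Exact positional nucleotide composition of a read set."""
    seqs = [(r if isinstance(r, str) else r.sequence).upper() for r in reads]
    if not seqs:
        raise UsageError("composition() requires at least one read")
    max_len = max(len(s) for s in seqs)
    bases = "ACGT"
    counts = np.zeros((max_len, 4), dtype=np.int64)
    n = np.zeros(max_len, dtype=np.int64)
    idx = {b: i for i, b in enumerate(bases)}
    for s in seqs:
        for pos, base in enumerate(s):
            if base in idx:
                counts[pos, idx[base]] += 1
                n[pos] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / n[:, None]
    df = pd.DataFrame(freqs, index=pd.RangeIndex(1, max_len + 1, name="position"),
                      columns=list(bases))
    first_counts = {b: int(counts[0, idx[b]]) for b in bases}
    total_first = max(int(n[0]), 1)
    first = {b: first_counts[b] / total_first for b in bases}
    return CompositionMatrix(freqs=df, n=pd.Series(n, index=df.index),
                             first_nt=first, first_nt_counts=first_counts)


def g_bias_test(ttsa_first_nt: Mapping[str, int],
                other_first_nt: Mapping[str, int]) -> FisherResult:
    """Fisher exact test for first-position G depletion.

    2x2 table of (first base G vs not G) x (TTSa vs other small RNAs).
    Both groups must be non-empty; a zero margin (e.g. no G anywhere)
    raises ``DegenerateTableError``.
    """
    tg = int(ttsa_first_nt.get("G", 0))
    tn = int(sum(ttsa_first_nt.values())) - tg
    og = int(other_first_nt.get("G", 0))
    on = int(sum(other_first_nt.values())) - og
    if tg + tn == 0 or og + on == 0:
        raise UsageError("both groups must be non-empty")
    return fisher_exact_2x2([[tg, tn], [og, on]])


# ---------------------------------------------------------------------------
# expression correlation
# ---------------------------------------------------------------------------

def correlate_expression(
    expr: pd.DataFrame | pd.Series,
    ttsa_rpm: pd.DataFrame | pd.Series,
    expr_tertile_filter: bool = True,
    ttsa_quartile_filter: bool = True,
) -> dict:
    """Spearman correlation between gene expression and TTSa-RNA abundance.

    Inputs are gene x sample tables (a Series is treated as one sample).
    Filters follow the standard protocol for this comparison: genes whose
    mean expression falls below the first tertile are removed, then
    gene-sample points with TTSa RPM in the first three quartiles are
    removed (low-count points carry fewer than ~4 reads and only add rank
    noise). Quantiles use the inclusive linear (type-7) convention so
    results are bit-reproducible.

    Returns ``{"spearman_rho", "r_squared", "n"}`` with R^2 = rho^2.
    """
    if isinstance(expr, pd.Series):
        expr = expr.to_frame("s1")
    if isinstance(ttsa_rpm, pd.Series):
        ttsa_rpm = ttsa_rpm.to_frame("s1")
    genes = expr.index.intersection(ttsa_rpm.index)
    samples = expr.columns.intersection(ttsa_rpm.columns)
    expr = expr.loc[genes, samples]
    ttsa_rpm = ttsa_rpm.loc[genes, samples]

    if expr_tertile_filter and len(genes):
        gene_expr = expr.mean(axis=1)
        cut = np.percentile(gene_expr.to_numpy(float), 100 / 3)
        keep = gene_expr >= cut
        expr, ttsa_rpm = expr.loc[keep], ttsa_rpm.loc[keep]

    x = expr.to_numpy(float).ravel()
    y = ttsa_rpm.to_numpy(float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if ttsa_quartile_filter and len(y):
        q3 = np.percentile(y, 75)
        keep = y > q3
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(
            f"insufficient_data: {len(x)} gene-sample points after filtering"
        )
    rho = float(sps.spearmanr(x, y).statistic)
    return {"spearman_rho": rho, "r_squared": rho ** 2, "n": int(len(x))}


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    test: str  # "wilcoxon_signed_rank" | "wilcoxon_rank_sum"
    statistic: float
    pvalue: float
    paired: bool
    n_tumor: int
    n_control: int
    medians: dict[str, float]
    fold_change: pd.DataFrame | None = None


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def compare_cohorts(
    table: pd.DataFrame,
    site_matrix: pd.DataFrame | None = None,
    paired: bool | None = None,
    value_col: str = "ttsa_rpm",
) -> CohortResult:
    """Tumor-vs-control comparison of per-sample TTSa abundance.

    ``table`` needs columns ``sample``, ``condition`` ({tumor, control}) and
    ``value_col``; a complete ``pair_id`` column switches to the paired
    (signed-rank) test, otherwise the rank-sum test is used. Exact null
    enumeration when the sample is small (<= 25 observations, no ties or
    zero differences), normal approximation with continuity correction
    otherwise — the conventional wilcox.test contract. All-tied data yields
    p = 1 with a warning.

    ``site_matrix`` (samples x sites) adds a per-site median fold-change
    table to the result.
    """
    for col in ("sample", "condition", value_col):
        if col not in table.columns:
            raise UsageError(f"cohort table lacks required column {col!r}")
    conditions = set(table["condition"])
    if not conditions <= {"tumor", "control"}:
        raise UsageError(f"conditions must be tumor/control, got {sorted(conditions)}")
    tumor = table[table["condition"] == "tumor"]
    control = table[table["condition"] == "control"]
    if paired is None:
        paired = "pair_id" in table.columns and table["pair_id"].notna().all()

    if paired:
        if (tumor["pair_id"].duplicated().any()
                or control["pair_id"].duplicated().any()
                or set(tumor["pair_id"]) != set(control["pair_id"])):
            raise UsageError("paired test requires a tumor/control bijection via pair_id")
        merged = pd.merge(tumor, control, on="pair_id", suffixes=("_t", "_c"))
        if len(merged) < 2:
            raise UsageError("paired test requires at least 2 pairs")
        t = merged[f"{value_col}_t"].to_numpy(float)
        c = merged[f"{value_col}_c"].to_numpy(float)
        diffs = t - c
        if np.all(diffs == 0):
            warnings.warn("all paired differences are zero; p set to 1")
            stat, p = 0.0, 1.0
        else:
            nz = diffs[diffs != 0]
            exact = len(diffs) <= 25 and len(nz) == len(diffs) and not _has_ties(np.abs(nz))
            res = sps.wilcoxon(t, c, zero_method="wilcox", correction=True,
                               alternative="two-sided",
                               method="exact" if exact else "approx")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_signed_rank"
    else:
        if len(tumor) < 2 or len(control) < 2:
            raise UsageError("unpaired test requires >= 2 samples per condition")
        t = tumor[value_col].to_numpy(float)
        c = control[value_col].to_numpy(float)
        pooled = np.concatenate([t, c])
        if _has_ties(pooled) and len(np.unique(pooled)) == 1:
            warnings.warn("all values identical; p set to 1")
            stat, p = float(len(t) * len(c) / 2), 1.0
        else:
            exact = len(pooled) <= 25 and not _has_ties(pooled)
            res = sps.mannwhitneyu(t, c, alternative="two-sided", use_continuity=True,
                                   method="exact" if exact else "asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_rank_sum"

    fold = None
    if site_matrix is not None:
        mt = site_matrix.loc[tumor["sample"]].median(axis=0)
        mc = site_matrix.loc[control["sample"]].median(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = mt / mc
        fold = pd.DataFrame({"median_tumor": mt, "median_control": mc,
                             "fold_change": fc})
        fold.index.name = "site_id"

    return CohortResult(
        test=test, statistic=stat, pvalue=min(max(p, 0.0), 1.0), paired=bool(paired),
        n_tumor=len(tumor), n_control=len(control),
        medians={"tumor": float(np.median(tumor[value_col])),
                 "control": float(np.median(control[value_col]))},
        fold_change=fold,
    )


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def enrich_gene_sets(
    hits: Iterable[str],
    background: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each gene set.

    Per set with K background members: k = hits in set, n = |hits|,
    N = |background|; p is the hypergeometric upper tail P(X >= k), q the
    Benjamini-Hochberg adjusted value, and
    fold_enrichment = (k/n) / (K/N). Sets with no background members are
    dropped. The table is sorted by decreasing fold enrichment (the usual
    reporting order for the significant, FDR < ``fdr``, rows).
    """
    hit_set = set(hits)
    bg = set(background)
    if not hit_set <= bg:
        raise UsageError("hits must be a subset of background")
    if not hit_set:
        return pd.DataFrame(columns=["set", "k", "K", "n", "N", "fold_enrichment",
                                     "p", "q", "significant"])
    n, N = len(hit_set), len(bg)
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & bg
        K = len(in_bg)
        if K == 0:
            continue
        k = len(hit_set & in_bg)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((name, k, K, n, N, fold, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["set", "k", "K", "n", "N", "fold_enrichment",
                                     "p", "q", "significant"])
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "fold_enrichment", "p"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["q"] < fdr
    df = df.sort_values(["fold_enrichment", "set"], ascending=[False, True])
    return df.reset_index(drop=True)


def top_enriched(table: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The top-n significant sets by fold enrichment (the reporting view)."""
    if table.empty:
        return table
    return table[table["significant"]].head(n).reset_index(drop=True)
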