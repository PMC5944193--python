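"""Independent brute-force oracles used to validate the package.

Everything here deliberately avoids the implementation strategies of the
package: alignment is a numpy full scan over every reference position and
strand, tail calling descends prefixes using that scan, TTSa calling is a
read x window double loop, and the exact tests are rational-arithmetic
combinatorial enumerations.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_ENC_REF = np.full(256, 9, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC_REF[b] = i
_ENC_REF[ord("N")] = 4
_ENC_READ = _ENC_REF.copy()
_ENC_READ[ord("N")] = 5  # read N != ref N: N never matches anything

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _enc(seq: str, table) -> np.ndarray:
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def naive_align(seq, refs, seed_len=18, max_seed_mm=0, max_total_mm=0):
    """Every valid ungapped alignment by scanning all positions and strands.

    Returns a sorted list of (chrom, start, strand, mismatches).
    """
    out = []
    L = len(seq)
    for chrom in sorted(refs):
        ref = refs[chrom].upper()
        if L > len(ref):
            continue
        enc_ref = _enc(ref, _ENC_REF)
        windows = sliding_window_view(enc_ref, L)
        seed = min(seed_len, L)
        for strand in "+-":
            oriented = seq.upper() if strand == "+" else rc(seq.upper())
            enc_read = _enc(oriented, _ENC_READ)
            mm = windows != enc_read
            total = mm.sum(axis=1)
            if strand == "+":
                seed_mm = mm[:, :seed].sum(axis=1)
            else:  # the read's 5' seed sits at the end of the reverse complement
                seed_mm = mm[:, L - seed:].sum(axis=1)
            ok = np.flatnonzero((total <= max_total_mm) & (seed_mm <= max_seed_mm))
            out.extend((chrom, int(p), strand, int(total[p])) for p in ok)
    return sorted(out)


def naive_exact_hits(seq, refs):
    return [(c, p, s) for c, p, s, _ in naive_align(seq, refs, seed_len=len(seq))]


def naive_tail_call(seq, refs, min_prefix=18, require_unique=True,
                    allow_shorter_unique=False):
    """Prefix-descent tail calling on top of the naive scanner.

    Returns ("call", prefix_len, tail_seq, (chrom, start, strand)) or
    ("nocall", reason).
    """
    if len(seq) < min_prefix:
        return ("nocall", "too_short")
    for L in range(len(seq), min_prefix - 1, -1):
        hits = naive_exact_hits(seq[:L], refs)
        if not hits:
            continue
        if len(hits) > 1 and require_unique:
            if allow_shorter_unique:
                continue
            return ("nocall", "multimapped_prefix")
        return ("call", L, seq[L:], hits[0])
    return ("nocall", "unaligned")


def naive_call_ttsa(alignments, windows, sites, size_range=(18, None),
                    sense_only=True):
    """read x window double loop.

    ``alignments``: list of (read_id, chrom, start, end, strand, read_len).
    ``windows``: list of (site_id, chrom, start, end, strand).
    ``sites``: dict site_id -> (position, strand).
    Returns a sorted list of (read_id, site_id, dist3p, sense).
    """
    lo, hi = size_range
    out = []
    for read_id, chrom, start, end, strand, read_len in alignments:
        if read_len < lo or (hi is not None and read_len > hi):
            continue
        r3 = end - 1 if strand == "+" else start
        cands = []
        for site_id, wchrom, wstart, wend, wstrand in windows:
            if wchrom != chrom:
                continue
            if min(end, wend) - max(start, wstart) < 1:
                continue
            if sense_only and wstrand != strand:
                continue
            pos, sstrand = sites[site_id]
            cands.append((abs(r3 - pos), pos, site_id))
        if not cands:
            continue
        cands.sort()
        _, pos, site_id = cands[0]
        sstrand = sites[site_id][1]
        dist = r3 - pos if sstrand == "+" else pos - r3
        out.append((read_id, site_id, dist, strand == sstrand))
    return sorted(out)


# ---------------------------------------------------------------------------
# exact-test enumeration oracles (rational arithmetic)
# ---------------------------------------------------------------------------

def fisher_two_sided_enum(table) -> float:
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    pmf = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pmf[k] = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def hypergeom_upper_enum(k, N, K, n) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def signed_rank_two_sided_enum(diffs) -> float:
    """Exact paired Wilcoxon p over all 2^n sign assignments.

    Requires no zero differences and no tied |differences| (the regime in
    which the package promises exactness).
    """
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0) and len(np.unique(np.abs(d))) == len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = int(ranks[d > 0].sum())
    n = len(d)
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(int(sum(r for r, s in zip(ranks, signs) if s)))
    ws = np.array(ws)
    total = len(ws)
    p_low = np.count_nonzero(ws <= w_obs) / total
    p_high = np.count_nonzero(ws >= w_obs) / total
    return float(min(1.0, 2 * min(p_low, p_high)))


def rank_sum_two_sided_enum(x, y) -> float:
    """Exact rank-sum p over all label assignments (no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled)
    n1 = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1
    w_obs = int(ranks[:n1].sum())
    ws = [int(sum(ranks[list(idx)])) for idx in itertools.combinations(range(len(pooled)), n1)]
    ws = np.array(ws)
    total = len(ws)
    p_low = np.count_nonzero(ws <= w_obs) / total
    p_high = np.count_nonzero(ws >= w_obs) / total
    return float(min(1.0, 2 * min(p_low, p_high)))
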