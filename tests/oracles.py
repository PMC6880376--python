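"""Independent brute-force reference implementations used as test oracles.

Everything here is written for clarity over speed, using explicit enumeration
(pairwise loops, materialized windows, interval scans) rather than the
vectorized algebra of the package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# -- diversity ---------------------------------------------------------------

def pairwise_pi_site(alleles) -> float:
    """Mean mismatches over all haplotype pairs at one site."""
    alleles = list(alleles)
    pairs = list(itertools.combinations(range(len(alleles)), 2))
    return sum(alleles[i] != alleles[j] for i, j in pairs) / len(pairs)


def pairwise_pi_matrix(H) -> float:
    """Sum over sites of the mean pairwise difference (absolute units)."""
    H = np.asarray(H)
    n = H.shape[0]
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sum(H[i] != H[j])
            npairs += 1
    return total / npairs


# -- Tajima ------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """Independent transcription of the 1989 constants, in exact arithmetic."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {k: float(v) for k, v in
            dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2).items()}


def tajima_d_from_haplotypes(H) -> float:
    H = np.asarray(H)
    n = H.shape[0]
    c = tajima_constants(n)
    k = H.sum(axis=0)
    S = int(np.sum((k > 0) & (k < n)))
    if S == 0:
        return float("nan")
    pi = pairwise_pi_matrix(H)
    return (pi - S / c["a1"]) / math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))


# -- Weir & Cockerham --------------------------------------------------------

def wc_abc(genotype_lists) -> tuple[float, float, float]:
    """a, b, c for one site from per-population diploid dosage lists.

    Straight transcription of the 1984 definitions with explicit sums.
    """
    pops = [[g for g in pop if g >= 0] for pop in genotype_lists]
    r = len(pops)
    n_i = [len(pop) for pop in pops]
    if any(n == 0 for n in n_i):
        raise ValueError("population with no genotyped individual")
    p_i = [sum(pop) / (2 * n) for pop, n in zip(pops, n_i)]
    h_i = [sum(1 for g in pop if g == 1) / n for pop, n in zip(pops, n_i)]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


# -- LD ----------------------------------------------------------------------

def ld_counts(x, y) -> dict:
    """D, D' and r2 from an explicit 2x2 gamete contingency table."""
    x = list(x)
    y = list(y)
    n = len(x)
    f11 = sum(1 for a, b in zip(x, y) if a == 1 and b == 1) / n
    pa = sum(x) / n
    pb = sum(y) / n
    D = f11 - pa * pb
    if D > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif D < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0
    return {"D": D, "D_prime": D / dmax if D != 0 else 0.0,
            "r2": D * D / (pa * (1 - pa) * pb * (1 - pb))}


# -- EHH12 / iHH12 -----------------------------------------------------------

def ehh12_at_span(H, lo, hi) -> float:
    """EHH12 over the inclusive site span [lo, hi] by explicit tabulation."""
    H = np.asarray(H)
    n = H.shape[0]
    groups: dict[tuple, int] = {}
    for row in H[:, lo:hi + 1]:
        key = tuple(row)
        groups[key] = groups.get(key, 0) + 1
    counts = sorted(groups.values(), reverse=True)
    top = sum(counts[:2])
    rest = counts[2:]
    comb2 = lambda m: m * (m - 1) / 2
    return (comb2(top) + sum(comb2(m) for m in rest)) / comb2(n)


def ehh12_points(H, positions, core, step, cutoff, max_extend):
    """(distance, ehh12) points for one direction, explicit spans."""
    pts = [(0.0, 1.0)]
    j = core + step
    while 0 <= j < len(positions):
        d = abs(int(positions[j]) - int(positions[core]))
        if d > max_extend:
            break
        lo, hi = min(core, j), max(core, j)
        v = ehh12_at_span(H, lo, hi)
        pts.append((float(d), v))
        if v < cutoff:
            break
        j += step
    return pts


def ihh12_value(H, positions, core, cutoff=0.05, max_extend=1_000_000) -> float:
    total = 0.0
    for step in (-1, 1):
        pts = ehh12_points(H, positions, core, step, cutoff, max_extend)
        for (d0, v0), (d1, v1) in zip(pts[:-1], pts[1:]):
            if v1 >= cutoff:
                total += (v0 + v1) / 2 * (d1 - d0)
            else:
                if v0 > cutoff:
                    x = d0 + (d1 - d0) * (v0 - cutoff) / (v0 - v1)
                    total += (v0 + cutoff) / 2 * (x - d0)
                break
    return total


# -- scan primitives ---------------------------------------------------------

def nearest_rank_threshold(values, q=0.95) -> float:
    vals = sorted(v for v in values if not math.isnan(v))
    rank = math.ceil(q * len(vals))
    return vals[max(rank, 1) - 1]


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals, merging adjacency (gap 0)."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def genes_in_region(genes, chrom, start, end) -> list[str]:
    """All-pairs inclusive interval intersection."""
    hits = []
    for gid, g_chrom, g_start, g_end in genes:
        if g_chrom != chrom:
            continue
        if max(g_start, start) <= min(g_end, end):
            hits.append(gid)
    return sorted(hits)


# -- ROH ---------------------------------------------------------------------

def roh_segments(positions, genotypes, p) -> list[tuple[int, int, int]]:
    """(start, end, n_snps) by materializing every scanning window."""
    positions = list(map(int, positions))
    genotypes = list(map(int, genotypes))
    S = len(positions)
    w = p.window_snp
    windows = []
    for s in range(S - w + 1):
        span = positions[s + w - 1] - positions[s] + 1
        if span > p.window_kb * 1000:
            windows.append((s, None))
            continue
        het = sum(1 for g in genotypes[s:s + w] if g == 1)
        mis = sum(1 for g in genotypes[s:s + w] if g < 0)
        windows.append((s, het <= p.window_het and mis <= p.window_missing))
    state = []
    for i in range(S):
        containing = [hom for s, hom in windows if s <= i <= s + w - 1 and hom is not None]
        if not containing:
            state.append(False)
        else:
            state.append(sum(containing) / len(containing) >= p.hit_threshold)
    segs = []
    i = 0
    while i < S:
        if not state[i]:
            i += 1
            continue
        j = i
        while (j + 1 < S and state[j + 1]
               and positions[j + 1] - positions[j] <= p.max_gap_kb * 1000):
            j += 1
        n_snps = j - i + 1
        length = positions[j] - positions[i] + 1
        if (n_snps >= p.min_snp and length >= p.min_kb * 1000
                and length / n_snps <= p.max_kb_per_snp * 1000):
            segs.append((positions[i], positions[j], n_snps))
        i = j + 1
    return segs
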