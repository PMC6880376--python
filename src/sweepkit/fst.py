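"""Weir-Cockerham F_ST from diploid genotype data.

Implements the 1984 variance-components estimator for a biallelic site
sampled from r populations: the among-population (a), among-individuals-
within-population (b) and within-individual (c) components are computed
per site from the population sample sizes, alt-allele frequencies and
observed heterozygote proportions.  Windowed and genome-wide estimates are
"weighted" ratios of sums, theta_hat = sum(a) / sum(a + b + c) over the
contributing sites, which is the standard aggregation for resequencing
scans; an unweighted mean of per-site ratios is also reported as a
diagnostic.  Negative estimates (expected at sites/windows with no true
differentiation) are retained in tables and only clamped to zero in summary
reporting.

Missing genotypes are excluded from all counts; a site where any population
has no genotyped individual, or where the average sample size is <= 1, is
skipped as uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix
from .window_stats import window_grid, _resolve_length, _window_index

__all__ = ["FstComponents", "wc_site_components", "wc_components_table", "windowed_fst",
           "FstResult"]


@dataclass
class FstComponents:
    """Per-site Weir-Cockerham intermediates and variance components."""

    a: float
    b: float
    c: float
    r: int
    n_i: np.ndarray
    p_i: np.ndarray
    h_i: np.ndarray
    n_bar: float
    n_c: float
    p_bar: float
    s2: float
    h_bar: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return float("nan") if denom == 0 else self.a / denom


def _components_arrays(n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray):
    """Vectorized W&C components; inputs are (n_pops, n_sites) arrays."""
    r = n_i.shape[0]
    if r < 2:
        raise ValueError("at least two populations are required")
    n_i = n_i.astype(np.float64)
    valid = (n_i > 0).all(axis=0)
    n_bar = n_i.mean(axis=0)
    valid &= n_bar > 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
        a = n_bar / n_c * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2.0
    # n_c can be 0 when all samples sit in one population; mark invalid
    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, n_bar, n_c, p_bar, s2, h_bar, valid


def _pop_summaries(genotypes_by_pop: Sequence[np.ndarray]):
    """(n_i, p_i, h_i) arrays of shape (n_pops, n_sites) from dosage matrices."""
    n_list, p_list, h_list = [], [], []
    for g in genotypes_by_pop:
        g = np.asarray(g, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("expected a (n_sites, n_samples) dosage matrix")
        called = g >= 0
        n = called.sum(axis=1, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, g, 0).sum(axis=1) / np.maximum(2 * n, 1)
            h = (g == 1).sum(axis=1) / np.maximum(n, 1)
        n_list.append(n)
        p_list.append(p)
        h_list.append(h)
    return np.array(n_list, dtype=np.float64), np.array(p_list), np.array(h_list)


def wc_site_components(genotypes_by_pop: Sequence[np.ndarray]) -> FstComponents:
    """Components for a single biallelic site.

    ``genotypes_by_pop`` holds one 1-D dosage array (0/1/2, -1 missing) per
    population.  Raises if any population has no genotyped individual.
    """
    mats = [np.asarray(g, dtype=np.int8).reshape(1, -1) for g in genotypes_by_pop]
    n_i, p_i, h_i = _pop_summaries(mats)
    if np.any(n_i[:, 0] == 0):
        raise ValueError("a population has no genotyped individual at this site")
    a, b, c, n_bar, n_c, p_bar, s2, h_bar, valid = _components_arrays(n_i, p_i, h_i)
    return FstComponents(
        a=float(a[0]), b=float(b[0]), c=float(c[0]), r=len(mats),
        n_i=n_i[:, 0], p_i=p_i[:, 0], h_i=h_i[:, 0],
        n_bar=float(n_bar[0]), n_c=float(n_c[0]), p_bar=float(p_bar[0]),
        s2=float(s2[0]), h_bar=float(h_bar[0]))


def wc_components_table(matrices: Sequence[GenotypeMatrix]) -> pd.DataFrame:
    """Per-site a, b, c and theta_hat for two or more aligned matrices.

    The matrices must share the site grid (same positions).  Sites where any
    population is entirely missing, or with a + b + c = 0, have NaN theta.
    """
    first = matrices[0]
    for gm in matrices[1:]:
        if not np.array_equal(gm.positions, first.positions):
            raise ValueError("population matrices are not on a shared site grid")
    n_i, p_i, h_i = _pop_summaries([gm.genotypes for gm in matrices])
    a, b, c, *_, valid = _components_arrays(n_i, p_i, h_i)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    return pd.DataFrame({
        "chrom": first.chrom,
        "pos": first.positions,
        "a": a,
        "b": b,
        "c": c,
        "fst": theta,
        "informative": valid & (denom != 0) & ~np.isnan(denom),
    })


@dataclass
class FstResult:
    """Windowed and per-site F_ST plus genome-wide summaries."""

    windows: pd.DataFrame
    sites: pd.DataFrame
    genome_weighted: float      # raw ratio of sums over all informative sites
    genome_unweighted: float    # mean of per-site ratios

    @property
    def genome_weighted_clamped(self) -> float:
        return max(0.0, self.genome_weighted)


def windowed_fst(matrices: Sequence[GenotypeMatrix], window: int = 10_000) -> FstResult:
    """Weighted window F_ST = sum(a)/sum(a+b+c) over informative window sites.

    Accepts two (the tested pairwise design) or more population matrices on a
    shared site grid.  Windows without informative sites get NaN.
    """
    sites = wc_components_table(matrices)
    gm = matrices[0]
    length = _resolve_length(gm)
    starts, ends = window_grid(length, window)
    n_win = starts.size
    num = np.zeros(n_win)
    den = np.zeros(n_win)
    n_inf = np.zeros(n_win, dtype=np.int64)
    n_snps = np.zeros(n_win, dtype=np.int64)
    if gm.n_sites:
        idx = _window_index(gm.positions, window)
        np.add.at(n_snps, idx, 1)
        inf = sites["informative"].to_numpy()
        a = sites["a"].to_numpy()
        d = (sites["a"] + sites["b"] + sites["c"]).to_numpy()
        np.add.at(num, idx[inf], a[inf])
        np.add.at(den, idx[inf], d[inf])
        np.add.at(n_inf, idx[inf], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_fst = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    span = (ends - starts + 1).astype(np.float64)
    per_site = sites.loc[sites["informative"], "fst"]
    windows = pd.DataFrame({
        "chrom": gm.chrom,
        "start": starts,
        "end": ends,
        "n_snps": n_snps,
        "n_informative": n_inf,
        "fst": w_fst,
        "partial": span < window,
    })
    # mean-of-ratios diagnostic per window
    if gm.n_sites:
        mor = np.full(n_win, np.nan)
        sums = np.zeros(n_win)
        inf_idx = idx[inf]
        np.add.at(sums, inf_idx, sites.loc[sites["informative"], "fst"].to_numpy())
        nz = n_inf > 0
        mor[nz] = sums[nz] / n_inf[nz]
        windows["fst_unweighted"] = mor
    else:
        windows["fst_unweighted"] = np.nan
    tot_den = den.sum()
    genome_weighted = float(num.sum() / tot_den) if tot_den != 0 else float("nan")
    genome_unweighted = float(per_site.mean()) if len(per_site) else float("nan")
    return FstResult(windows, sites, genome_weighted, genome_unweighted)
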