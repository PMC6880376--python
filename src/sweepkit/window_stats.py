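"""Nucleotide diversity, Tajima's D and diversity ratios in tiled windows.

All windowed statistics use non-overlapping windows (default 10 kb) tiled
from position 1 of each chromosome.  Window pi divides the summed per-site
heterozygosity by the full window width, so monomorphic (and unsequenced)
base pairs count as invariant; this yields per-bp magnitudes on the order of
1e-3 for typical livestock resequencing panels.  The trailing partial window
is reported with its true span and a ``partial`` flag so that downstream
outlier ranking can exclude it.

Tajima's D follows the classical constants a1..e2 computed from the sample
haplotype count, with the window's pairwise-difference mean taken in absolute
(not per-bp) units.  D requires complete genotypes: missing calls must be
imputed (or the sites dropped) upstream so that the haplotype count n is
constant across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix

__all__ = [
    "TajimaCoefficients",
    "site_pi",
    "window_grid",
    "windowed_pi",
    "tajima_coefficients",
    "windowed_tajima_d",
    "pi_ratio",
]


def site_pi(alt_count, allele_total):
    """Unbiased per-site heterozygosity k(n-k)/C(n,2).

    Equals the mean number of pairwise mismatches over all C(n,2) haplotype
    pairs at a biallelic site with ``alt_count`` copies of the alternate
    allele among ``allele_total`` called alleles.  Vectorized; returns NaN
    where fewer than two alleles were called.
    """
    k = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(allele_total, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n >= 2, k * (n - k) / (n * (n - 1) / 2.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def window_grid(chrom_length: int, window: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based inclusive [start, end] bounds of windows tiled from position 1."""
    if chrom_length < 1:
        raise ValueError("chromosome length must be >= 1")
    starts = np.arange(1, chrom_length + 1, window, dtype=np.int64)
    ends = np.minimum(starts + window - 1, chrom_length)
    return starts, ends


def _resolve_length(gm: GenotypeMatrix) -> int:
    if gm.chrom_length is not None:
        return int(gm.chrom_length)
    if gm.n_sites == 0:
        raise ValueError("cannot infer chromosome length from an empty matrix")
    return int(gm.positions[-1])


def _window_index(positions: np.ndarray, window: int) -> np.ndarray:
    return (positions - 1) // window


def windowed_pi(gm: GenotypeMatrix, window: int = 10_000) -> pd.DataFrame:
    """Per-window nucleotide diversity (per bp) for one population.

    Columns: chrom, start, end, n_snps, pi, partial.  ``n_snps`` counts the
    SNP records of the matrix falling in the window (the shared dataset site
    grid); windows with no SNPs have pi = 0.
    """
    length = _resolve_length(gm)
    starts, ends = window_grid(length, window)
    n_win = starts.size
    n_snps = np.zeros(n_win, dtype=np.int64)
    pi_sum = np.zeros(n_win, dtype=np.float64)
    if gm.n_sites:
        k, n = gm.allele_counts()
        vals = site_pi(k, n)
        vals = np.where(np.isnan(vals), 0.0, vals)
        idx = _window_index(gm.positions, window)
        np.add.at(n_snps, idx, 1)
        np.add.at(pi_sum, idx, vals)
    span = (ends - starts + 1).astype(np.float64)
    return pd.DataFrame({
        "chrom": gm.chrom,
        "start": starts,
        "end": ends,
        "n_snps": n_snps,
        "pi": pi_sum / span,
        "partial": span < window,
    })


@dataclass(frozen=True)
class TajimaCoefficients:
    """The constants of the D denominator for a sample of n haplotypes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(n: int) -> TajimaCoefficients:
    """Coefficients a1..e2 for ``n`` haplotypes (n >= 3)."""
    if n < 3:
        raise ValueError("Tajima's D needs at least 3 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(S: int, pi_abs: float, coeff: TajimaCoefficients) -> float:
    """D from the segregating-site count and absolute mean pairwise difference."""
    if S == 0:
        return float("nan")
    var = coeff.e1 * S + coeff.e2 * S * (S - 1)
    return (pi_abs - S / coeff.a1) / np.sqrt(var)


def windowed_tajima_d(gm: GenotypeMatrix, window: int = 10_000) -> pd.DataFrame:
    """Per-window Tajima's D for one population (complete genotypes required).

    Sites monomorphic within this population do not count as segregating.
    Windows with S = 0 get NaN.
    """
    if np.any(gm.genotypes < 0):
        raise ValueError(
            "missing genotypes present: impute or drop incomplete sites before "
            "computing Tajima's D")
    n = 2 * gm.n_samples
    coeff = tajima_coefficients(n)
    length = _resolve_length(gm)
    starts, ends = window_grid(length, window)
    n_win = starts.size
    S = np.zeros(n_win, dtype=np.int64)
    pi_sum = np.zeros(n_win, dtype=np.float64)
    n_snps = np.zeros(n_win, dtype=np.int64)
    if gm.n_sites:
        k = gm.genotypes.sum(axis=1, dtype=np.int64)
        seg = (k > 0) & (k < n)
        idx = _window_index(gm.positions, window)
        np.add.at(n_snps, idx, 1)
        np.add.at(S, idx[seg], 1)
        np.add.at(pi_sum, idx[seg], site_pi(k[seg], np.full(seg.sum(), n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        var = coeff.e1 * S + coeff.e2 * S * (S - 1.0)
        d = np.where(S > 0, (pi_sum - S / coeff.a1) / np.sqrt(np.where(S > 0, var, 1.0)),
                     np.nan)
    span = (ends - starts + 1).astype(np.float64)
    return pd.DataFrame({
        "chrom": gm.chrom,
        "start": starts,
        "end": ends,
        "n_snps": n_snps,
        "S": S,
        "theta_w": S / coeff.a1 / span,  # Watterson estimator per bp
        "tajima_d": d,
        "partial": span < window,
    })


def pi_ratio(ref_table: pd.DataFrame, focal_table: pd.DataFrame) -> pd.DataFrame:
    """Per-window diversity ratio pi(reference) / pi(focal).

    Oriented so that a diversity loss in the focal population (a sweep)
    yields ratios > 1.  Undefined (NaN) when the focal window has pi = 0;
    ``log2_pi_ratio`` is reported for display.
    """
    for col in ("chrom", "start", "end"):
        if not ref_table[col].reset_index(drop=True).equals(
                focal_table[col].reset_index(drop=True)):
            raise ValueError("reference and focal tables are on different window grids")
    ref_pi = ref_table["pi"].to_numpy(dtype=float)
    foc_pi = focal_table["pi"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(foc_pi > 0, ref_pi / np.where(foc_pi > 0, foc_pi, 1.0), np.nan)
        log2 = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), np.nan)
    out = ref_table[["chrom", "start", "end", "n_snps"]].copy()
    if "partial" in ref_table.columns:
        out["partial"] = ref_table["partial"].to_numpy()
    out["pi_ref"] = ref_pi
    out["pi_focal"] = foc_pi
    out["pi_ratio"] = ratio
    out["log2_pi_ratio"] = log2
    return out
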