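"""Genome-wide linkage-disequilibrium decay with physical distance.

Pairs of sites separated by at most ``max_dist`` bp contribute their r^2 to a
distance bin; per-bin means trace how LD decays with distance, the standard
summary for comparing effective recombination across populations.  r^2 comes
from phased haplotypes when available, otherwise from the squared Pearson
correlation of genotype dosages (flagged in the output).  Sites are MAF
filtered (default >= 0.05) before pairing, consistent with the dataset-level
frequency filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeMatrix
from .variant_io import GenotypeMatrix

__all__ = ["decay_curve", "adjacent_pair_r2"]


def _haplotype_columns(data: HaplotypeMatrix | GenotypeMatrix,
                       maf_min: float) -> tuple[np.ndarray, np.ndarray, str]:
    """(positions, columns matrix, mode) after the MAF filter."""
    if isinstance(data, HaplotypeMatrix):
        X = data.haplotypes.astype(np.float64).T  # sites x haplotypes
        pos = data.positions
        mode = "haplotype"
    elif data.is_phased and not np.any(data.phase < 0):
        X = data.phase.astype(np.float64)
        pos = data.positions
        mode = "haplotype"
    else:
        X = np.where(data.genotypes >= 0, data.genotypes, np.nan).astype(np.float64)
        pos = data.positions
        mode = "genotype"
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=1) / (1.0 if mode == "haplotype" else 2.0)
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    return pos[keep], X[keep], mode


def _pair_r2(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared correlation of one site row against many (NaN-aware)."""
    out = np.empty(Y.shape[0])
    for k in range(Y.shape[0]):
        y = Y[k]
        ok = ~(np.isnan(x) | np.isnan(y))
        xs, ys = x[ok], y[ok]
        vx, vy = xs.var(), ys.var()
        if xs.size < 2 or vx == 0 or vy == 0:
            out[k] = np.nan
            continue
        cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
        out[k] = cov * cov / (vx * vy)
    return out


def decay_curve(data: HaplotypeMatrix | GenotypeMatrix, max_dist: int = 300_000,
                bin_size: int = 1_000, maf_min: float = 0.05) -> pd.DataFrame:
    """Mean r^2 per distance bin [k*bin, (k+1)*bin) up to ``max_dist``.

    Columns: bin_start, bin_end, mean_r2, n_pairs, mode.
    """
    pos, X, mode = _haplotype_columns(data, maf_min)
    if pos.size < 2:
        raise ValueError("need at least two polymorphic sites for LD decay")
    # a pair at exactly max_dist falls in bin max_dist // bin_size
    n_bins = max_dist // bin_size + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for i in range(pos.size - 1):
        j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
        if j_hi <= i + 1:
            continue
        r2 = _pair_r2(X[i], X[i + 1:j_hi])
        d = (pos[i + 1:j_hi] - pos[i]) // bin_size
        ok = np.isfinite(r2)
        np.add.at(sums, d[ok], r2[ok])
        np.add.at(counts, d[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_start": np.arange(n_bins) * bin_size,
        "bin_end": (np.arange(n_bins) + 1) * bin_size,
        "mean_r2": mean,
        "n_pairs": counts,
        "mode": mode,
    })


def adjacent_pair_r2(data: HaplotypeMatrix | GenotypeMatrix,
                     maf_min: float = 0.05) -> float:
    """Mean r^2 over consecutive SNP pairs (one chromosome)."""
    pos, X, _ = _haplotype_columns(data, maf_min)
    if pos.size < 2:
        raise ValueError("need at least two polymorphic sites")
    vals = np.empty(pos.size - 1)
    for i in range(pos.size - 1):
        vals[i] = _pair_r2(X[i], X[i + 1:i + 2])[0]
    return float(np.nanmean(vals))
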