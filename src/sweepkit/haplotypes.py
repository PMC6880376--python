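"""Phased-haplotype statistics: EHH12 / iHH12, pairwise LD and frequency tables.

EHH12 extends the classic extended-haplotype-homozygosity profile by pooling
the two most frequent haplotype classes: at extension x from the core site,
haplotypes are partitioned by identity over the spanned sites and

    EHH12(x) = [C(n1 + n2, 2) + sum_{k>2} C(n_k, 2)] / C(n, 2)

with n1 >= n2 the two largest class counts.  iHH12 is the trapezoidal
integral of EHH12 over physical distance, left plus right of the core,
truncated where the profile drops below a cutoff (integrated to the
interpolated cutoff crossing) or at a maximum extension.  Pooling the top
two classes makes the statistic sensitive to soft as well as hard sweeps.

Scores are standardized genome-wide (z-score, population standard deviation)
and averaged per window; no genetic map is used, distances are physical bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, PopulationMap
from .window_stats import window_grid, _resolve_length, _window_index

__all__ = [
    "HaplotypeMatrix",
    "EHHProfile",
    "LDPair",
    "ehh12_profile",
    "ihh12",
    "ihh12_scan",
    "normalize_and_window",
    "window_mean_scores",
    "normalize_scores",
    "ld_pair",
    "haplotype_frequencies",
    "allele_frequencies",
]


@dataclass
class HaplotypeMatrix:
    """Phased alleles: 2 * n_samples haplotype rows over increasing positions.

    Rows 2i and 2i+1 belong to sample i.  No missing alleles are allowed;
    phase and impute upstream.
    """

    chrom: str
    positions: np.ndarray           # int64, strictly increasing
    haplotypes: np.ndarray          # uint8 (n_haplotypes, n_sites), alleles 0/1
    samples: list[str]
    chrom_length: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype matrix must have 2 rows per sample")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("at least two haplotypes are required")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix width does not match positions")
        if np.any((self.haplotypes != 0) & (self.haplotypes != 1)):
            raise ValueError("haplotype alleles must be 0/1 with no missing values")

    @classmethod
    def from_genotype_matrix(cls, gm: GenotypeMatrix) -> "HaplotypeMatrix":
        if gm.phase is None:
            raise ValueError("genotype matrix is unphased; phase/impute upstream")
        if np.any(gm.phase < 0):
            raise ValueError("phased matrix contains missing alleles; impute upstream")
        return cls(gm.chrom, gm.positions.copy(), gm.phase.T.astype(np.uint8),
                   list(gm.samples), gm.chrom_length)

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def sample_rows(self, sample_indices: Sequence[int]) -> np.ndarray:
        rows = np.array([(2 * i, 2 * i + 1) for i in sample_indices]).reshape(-1)
        return self.haplotypes[rows]


@dataclass
class EHHProfile:
    """EHH12 values at successive extensions from a core site, per direction.

    ``left``/``right`` are (distance_bp, ehh12) arrays ordered outward from
    the core (distance 0, value 1.0 included as the first row).  The profile
    stops after the first value below ``cutoff`` (kept, for interpolation) or
    beyond ``max_extend``.
    """

    core_index: int
    core_pos: int
    left: np.ndarray
    right: np.ndarray
    cutoff: float
    max_extend: int


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def _ehh12_from_labels(labels: np.ndarray) -> float:
    counts = np.sort(np.bincount(labels))[::-1]
    n = labels.size
    top2 = counts[:2].sum()
    rest = counts[2:]
    return float((_comb2(top2) + _comb2(rest).sum()) / _comb2(n))


def ehh12_profile(hm: HaplotypeMatrix, core: int, cutoff: float = 0.05,
                  max_extend: int = 1_000_000) -> EHHProfile:
    """EHH12 profile around site index ``core``.

    Haplotype classes are refined incrementally as the span grows, one site
    at a time, separately leftward and rightward.  At the core itself the
    two allele classes are pooled, so EHH12 starts at exactly 1.
    """
    H = hm.haplotypes
    pos = hm.positions
    core_pos = int(pos[core])

    def one_direction(step: int) -> np.ndarray:
        out = [(0.0, 1.0)]
        labels = H[:, core].astype(np.int64)  # classes at the core collapse to 1.0
        j = core + step
        while 0 <= j < hm.n_sites:
            dist = abs(int(pos[j]) - core_pos)
            if dist > max_extend:
                break
            pair = labels * 2 + H[:, j]
            _, labels = np.unique(pair, return_inverse=True)
            val = _ehh12_from_labels(labels)
            out.append((float(dist), val))
            if val < cutoff:
                break
            j += step
        return np.array(out, dtype=np.float64)

    return EHHProfile(core, core_pos, one_direction(-1), one_direction(+1),
                      cutoff, max_extend)


def _area(points: np.ndarray, cutoff: float) -> float:
    """Trapezoidal area above zero, truncated at the cutoff crossing."""
    total = 0.0
    for (d0, v0), (d1, v1) in zip(points[:-1], points[1:]):
        if v1 >= cutoff:
            total += (v0 + v1) / 2.0 * (d1 - d0)
        else:
            # integrate to the interpolated crossing of the cutoff level
            if v0 <= cutoff:
                break
            frac = (v0 - cutoff) / (v0 - v1)
            total += (v0 + cutoff) / 2.0 * (d1 - d0) * frac
            break
    return total


def ihh12(profile: EHHProfile) -> float:
    """Integrated EHH12 (bp units): left area plus right area from the core."""
    return _area(profile.left, profile.cutoff) + _area(profile.right, profile.cutoff)


def ihh12_scan(hm: HaplotypeMatrix, cutoff: float = 0.05,
               max_extend: int = 1_000_000) -> pd.DataFrame:
    """Raw iHH12 score at every site of the matrix.

    Uses a compiled kernel when numba is importable (identical arithmetic to
    :func:`ehh12_profile` + :func:`ihh12`, which remain the reference path).
    """
    if _ihh12_kernel is not None:
        scores = _ihh12_kernel(np.ascontiguousarray(hm.haplotypes),
                               hm.positions.astype(np.int64),
                               float(cutoff), float(max_extend))
    else:
        scores = np.empty(hm.n_sites)
        for i in range(hm.n_sites):
            scores[i] = ihh12(ehh12_profile(hm, i, cutoff, max_extend))
    return pd.DataFrame({"chrom": hm.chrom, "pos": hm.positions, "ihh12": scores})


def _build_ihh12_kernel():
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional accelerator
        return None

    @njit(cache=True)
    def kernel(H, pos, cutoff, max_extend):  # pragma: no cover - compiled
        n, S = H.shape
        denom = n * (n - 1) / 2.0
        out = np.zeros(S)
        labels = np.empty(n, np.int64)
        counts = np.zeros(2 * n + 2, np.int64)
        relabel = np.empty(2 * n + 2, np.int64)
        for core in range(S):
            total = 0.0
            for step in (-1, 1):
                for h in range(n):
                    labels[h] = H[h, core]
                prev_d = 0.0
                prev_v = 1.0
                j = core + step
                while 0 <= j < S:
                    d = abs(pos[j] - pos[core])
                    if d > max_extend:
                        break
                    # refine classes by the allele at site j and compact labels
                    for c in range(2 * n + 2):
                        counts[c] = 0
                    for h in range(n):
                        labels[h] = labels[h] * 2 + H[h, j]
                        counts[labels[h]] += 1
                    nxt = 0
                    for c in range(2 * n + 2):
                        if counts[c] > 0:
                            relabel[c] = nxt
                            nxt += 1
                    # EHH12: pool the two largest classes
                    m1 = 0
                    m2 = 0
                    rest = 0.0
                    for c in range(2 * n + 2):
                        cc = counts[c]
                        if cc > m1:
                            m2 = m1
                            m1 = cc
                        elif cc > m2:
                            m2 = cc
                    for c in range(2 * n + 2):
                        cc = counts[c]
                        rest += cc * (cc - 1) / 2.0
                    top = m1 + m2
                    val = (top * (top - 1) / 2.0
                           + rest - m1 * (m1 - 1) / 2.0 - m2 * (m2 - 1) / 2.0) / denom
                    for h in range(n):
                        labels[h] = relabel[labels[h]]
                    dd = float(d)
                    if val >= cutoff:
                        total += (prev_v + val) / 2.0 * (dd - prev_d)
                        prev_d = dd
                        prev_v = val
                    else:
                        if prev_v > cutoff:
                            frac = (prev_v - cutoff) / (prev_v - val)
                            total += (prev_v + cutoff) / 2.0 * (dd - prev_d) * frac
                        break
                    j += step
            out[core] = total
        return out

    return kernel


_ihh12_kernel = _build_ihh12_kernel()


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Genome-wide z-score with the population (denominator n) std."""
    scores = np.asarray(scores, dtype=np.float64)
    finite = scores[np.isfinite(scores)]
    if finite.size < 2:
        raise ValueError("need at least two finite scores to normalize")
    sd = finite.std()  # ddof=0
    if sd == 0:
        raise ValueError("degenerate score set: standard deviation is zero")
    return (scores - finite.mean()) / sd


def window_mean_scores(chrom: str, pos: np.ndarray, z: np.ndarray,
                       window: int = 10_000,
                       chrom_length: int | None = None) -> pd.DataFrame:
    """Per-window arithmetic mean of (already normalized) per-site scores."""
    pos = np.asarray(pos, dtype=np.int64)
    z = np.asarray(z, dtype=np.float64)
    length = chrom_length if chrom_length is not None else int(pos.max())
    starts, ends = window_grid(length, window)
    n_win = starts.size
    sums = np.zeros(n_win)
    counts = np.zeros(n_win, dtype=np.int64)
    idx = (pos - 1) // window
    ok = np.isfinite(z)
    np.add.at(sums, idx[ok], z[ok])
    np.add.at(counts, idx[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    span = (ends - starts + 1).astype(np.float64)
    return pd.DataFrame({
        "chrom": chrom,
        "start": starts,
        "end": ends,
        "n_scored": counts,
        "ihh12": mean,
        "partial": span < window,
    })


def normalize_and_window(site_scores: pd.DataFrame, window: int = 10_000,
                         chrom_length: int | None = None) -> pd.DataFrame:
    """Z-normalize per-site iHH12 scores, then average per window.

    ``site_scores`` needs columns chrom, pos, ihh12; one chromosome per call
    (multi-chromosome data are pooled for normalization by the scan driver).
    Windows without a scored site get NaN.
    """
    chroms = site_scores["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("normalize_and_window expects a single chromosome per call")
    z = normalize_scores(site_scores["ihh12"].to_numpy())
    return window_mean_scores(str(chroms[0]),
                              site_scores["pos"].to_numpy(dtype=np.int64),
                              z, window, chrom_length)


@dataclass(frozen=True)
class LDPair:
    """Two-site gametic disequilibrium and its normalizations."""

    D: float
    D_prime: float
    r2: float
    distance: int


def ld_from_haplotype_columns(x: np.ndarray, y: np.ndarray, distance: int = 0) -> LDPair:
    """D, D' and r^2 from two phased 0/1 allele columns."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pa = x.mean()
    pb = y.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD is undefined at a monomorphic site")
    f11 = (x * y).mean()
    D = f11 - pa * pb
    qa, qb = 1 - pa, 1 - pb
    if D > 0:
        dmax = min(pa * qb, qa * pb)
    else:
        dmax = min(pa * pb, qa * qb)
    d_prime = 0.0 if D == 0 else D / dmax
    r2 = D * D / (pa * qa * pb * qb)
    return LDPair(float(D), float(d_prime), float(r2), int(distance))


def ld_pair(hm: HaplotypeMatrix, site_i: int, site_j: int) -> LDPair:
    """Gametic LD between two site indices of a phased matrix."""
    dist = abs(int(hm.positions[site_j]) - int(hm.positions[site_i]))
    return ld_from_haplotype_columns(hm.haplotypes[:, site_i], hm.haplotypes[:, site_j],
                                     dist)


def haplotype_frequencies(hm: HaplotypeMatrix, site_positions: Sequence[int],
                          popmap: PopulationMap,
                          ref: np.ndarray | None = None,
                          alt: np.ndarray | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate haplotypes over a site subset per population.

    Returns (frequency table, pairwise-LD table).  Haplotype strings use the
    ref/alt bases when given, otherwise '0'/'1' characters.  The LD table
    reports D'/r^2 for every site pair of the subset, to flag perfect-LD
    sets (D' = 1 and r^2 = 1).
    """
    site_positions = list(site_positions)
    if not site_positions:
        raise ValueError("empty site subset")
    idx = []
    for p in site_positions:
        i = int(np.searchsorted(hm.positions, p))
        if i >= hm.n_sites or hm.positions[i] != p:
            raise ValueError(f"position {p} not present in the haplotype matrix")
        idx.append(i)
    sub = hm.haplotypes[:, idx]
    sample_index = {s: i for i, s in enumerate(hm.samples)}
    rows = []
    for pop in popmap.populations:
        members = [sample_index[s] for s in popmap.samples(pop) if s in sample_index]
        if not members:
            continue
        haps = hm.sample_rows(members)[:, idx]
        strings = []
        for row in haps:
            if ref is not None and alt is not None:
                chars = [alt[idx[k]] if row[k] else ref[idx[k]] for k in range(len(idx))]
            else:
                chars = [str(int(v)) for v in row]
            strings.append("".join(chars))
        total = len(strings)
        for s, cnt in sorted(pd.Series(strings).value_counts().items(),
                             key=lambda kv: (-kv[1], kv[0])):
            rows.append({"population": pop, "haplotype": s, "count": int(cnt),
                         "frequency": cnt / total, "n_haplotypes": total})
    freq = pd.DataFrame(rows)
    ld_rows = []
    for ii in range(len(idx)):
        for jj in range(ii + 1, len(idx)):
            x, y = sub[:, ii], sub[:, jj]
            if x.min() == x.max() or y.min() == y.max():
                continue
            pair = ld_from_haplotype_columns(
                x, y, abs(int(hm.positions[idx[jj]]) - int(hm.positions[idx[ii]])))
            ld_rows.append({"pos_i": site_positions[ii], "pos_j": site_positions[jj],
                            "D": pair.D, "D_prime": pair.D_prime, "r2": pair.r2})
    return freq, pd.DataFrame(ld_rows)


def allele_frequencies(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population alt-allele frequency over non-missing alleles, per site."""
    sample_index = {s: i for i, s in enumerate(gm.samples)}
    out = pd.DataFrame({"chrom": gm.chrom, "pos": gm.positions,
                        "ref": gm.ref, "alt": gm.alt})
    for pop in popmap.populations:
        cols = [sample_index[s] for s in popmap.samples(pop) if s in sample_index]
        if not cols:
            continue
        g = gm.genotypes[:, cols]
        called = g >= 0
        n = 2 * called.sum(axis=1, dtype=np.int64)
        k = np.where(called, g, 0).sum(axis=1, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"freq_{pop}"] = np.where(n > 0, k / np.maximum(n, 1), np.nan)
        out[f"n_called_{pop}"] = n
    return out
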