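"""Runs of homozygosity: PLINK-style scanning-window detection and F_ROH.

The detector reproduces the scanning-window heuristic popularized by PLINK's
``--homozyg``: every window of ``window_snp`` consecutive SNPs (whose bp span
does not exceed ``window_kb``) is called homozygous if it contains at most
``window_het`` heterozygous and at most ``window_missing`` missing calls.  A
SNP is in the ROH state when the fraction of valid windows containing it that
are homozygous reaches ``hit_threshold``.  Maximal runs of in-state SNPs are
split at inter-SNP gaps above ``max_gap_kb`` and then filtered by minimum SNP
count, minimum length and SNP density.  Segment endpoints are the first and
last in-state SNP positions.

F_ROH is the fraction of the genome covered by (overlap-merged) ROH; the
default genome length of 2.92 Gb corresponds to the autosomal span of the
ARS1 goat assembly, the denominator used in goat inbreeding studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, PopulationMap

__all__ = ["ROHParams", "ROHSegment", "detect_roh", "detect_roh_matrix", "merge_segments",
           "f_roh", "roh_size_classes", "SIZE_CLASSES"]

GOAT_AUTOSOME_BP = 2.92e9

#: half-open [lo, hi) length classes in bp
SIZE_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("0-250kb", 0.0, 250_000.0),
    ("250-500kb", 250_000.0, 500_000.0),
    ("500-1000kb", 500_000.0, 1_000_000.0),
    (">1000kb", 1_000_000.0, float("inf")),
)


@dataclass(frozen=True)
class ROHParams:
    """Scanning-window and segment-filter settings (PLINK-compatible defaults)."""

    window_snp: int = 50
    window_kb: float = 5000.0
    window_het: int = 1
    window_missing: int = 5
    hit_threshold: float = 0.05
    min_snp: int = 10
    min_kb: float = 100.0
    max_kb_per_snp: float = 10.0
    max_gap_kb: float = 100.0

    def __post_init__(self):
        if min(self.window_snp, self.window_het + 1, self.window_missing + 1,
               self.min_snp) < 1 or min(self.window_kb, self.min_kb,
                                        self.max_kb_per_snp, self.max_gap_kb) <= 0:
            raise ValueError("ROH parameters must be positive")
        if not (0 < self.hit_threshold <= 1):
            raise ValueError("hit_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _in_state(positions: np.ndarray, genotypes: np.ndarray, p: ROHParams) -> np.ndarray:
    """Per-SNP ROH state from the fraction of homozygous containing windows."""
    S = positions.size
    state = np.zeros(S, dtype=bool)
    w = p.window_snp
    if S < w:
        return state
    het = (genotypes == 1).astype(np.int64)
    mis = (genotypes < 0).astype(np.int64)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(S - w + 1)
    span = positions[starts + w - 1] - positions[starts] + 1
    valid = span <= p.window_kb * 1000.0
    hom = valid & (het_c[starts + w] - het_c[starts] <= p.window_het) \
        & (mis_c[starts + w] - mis_c[starts] <= p.window_missing)
    # windows containing SNP i start in [i - w + 1, i] clipped to the array
    hom_c = np.concatenate([[0], np.cumsum(hom)])
    val_c = np.concatenate([[0], np.cumsum(valid)])
    i = np.arange(S)
    lo = np.clip(i - w + 1, 0, S - w)
    hi = np.clip(i, 0, S - w)
    n_hom = hom_c[hi + 1] - hom_c[lo]
    n_val = val_c[hi + 1] - val_c[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_val > 0, n_hom / np.maximum(n_val, 1), 0.0)
    return frac >= p.hit_threshold


def detect_roh(positions: np.ndarray, genotypes: np.ndarray,
               params: ROHParams | None = None, chrom: str = "chr1",
               sample: str = "sample") -> list[ROHSegment]:
    """ROH segments for one individual on one chromosome.

    ``genotypes`` is the 1-D dosage track (0/1/2, -1 missing) aligned with
    ``positions`` (1-based, strictly increasing).
    """
    p = params or ROHParams()
    positions = np.asarray(positions, dtype=np.int64)
    genotypes = np.asarray(genotypes)
    if positions.size > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("positions must be strictly increasing")
    state = _in_state(positions, genotypes, p)
    segments: list[ROHSegment] = []
    i = 0
    S = positions.size
    max_gap = p.max_gap_kb * 1000.0
    while i < S:
        if not state[i]:
            i += 1
            continue
        j = i
        while j + 1 < S and state[j + 1] and positions[j + 1] - positions[j] <= max_gap:
            j += 1
        idx = slice(i, j + 1)
        n_snps = j - i + 1
        length = int(positions[j] - positions[i] + 1)
        dens_ok = length / n_snps <= p.max_kb_per_snp * 1000.0
        if n_snps >= p.min_snp and length >= p.min_kb * 1000.0 and dens_ok:
            n_het = int(np.sum(genotypes[idx] == 1))
            segments.append(ROHSegment(sample, chrom, int(positions[i]),
                                       int(positions[j]), n_snps, n_het))
        i = j + 1
    return segments


def detect_roh_matrix(matrices: Mapping[str, GenotypeMatrix] | GenotypeMatrix,
                      params: ROHParams | None = None) -> pd.DataFrame:
    """ROH for every sample over one or more chromosome matrices."""
    if isinstance(matrices, GenotypeMatrix):
        matrices = {matrices.chrom: matrices}
    rows = []
    for chrom, gm in matrices.items():
        for i, sample in enumerate(gm.samples):
            for seg in detect_roh(gm.positions, gm.genotypes[:, i], params,
                                  chrom=chrom, sample=sample):
                rows.append({"sample": seg.sample, "chrom": seg.chrom,
                             "start": seg.start, "end": seg.end,
                             "n_snps": seg.n_snps, "n_het": seg.n_het,
                             "length": seg.length})
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                       "n_snps", "n_het", "length"])


def merge_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent segments per (sample, chrom)."""
    if segments.empty:
        return segments.copy()
    rows = []
    for (sample, chrom), grp in segments.groupby(["sample", "chrom"], sort=True):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for _, row in grp.iterrows():
            if cur_s is None:
                cur_s, cur_e = row["start"], row["end"]
            elif row["start"] <= cur_e + 1:
                cur_e = max(cur_e, row["end"])
            else:
                rows.append({"sample": sample, "chrom": chrom, "start": cur_s,
                             "end": cur_e, "length": cur_e - cur_s + 1})
                cur_s, cur_e = row["start"], row["end"]
        rows.append({"sample": sample, "chrom": chrom, "start": cur_s,
                     "end": cur_e, "length": cur_e - cur_s + 1})
    return pd.DataFrame(rows)


def f_roh(segments: pd.DataFrame, genome_length: float = GOAT_AUTOSOME_BP,
          popmap: PopulationMap | None = None
          ) -> tuple[pd.Series, pd.Series | None]:
    """Genomic inbreeding coefficient: ROH-covered fraction of the genome.

    Segments are overlap-merged per individual first.  Returns per-individual
    F_ROH and, when a population map is given, the per-population mean.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    merged = merge_segments(segments)
    if merged.empty:
        per_ind = pd.Series(dtype=float, name="f_roh")
    else:
        per_ind = (merged.groupby("sample")["length"].sum() / genome_length)
        per_ind.name = "f_roh"
    per_pop = None
    if popmap is not None:
        per_ind = per_ind.reindex(list(popmap.assignments), fill_value=0.0)
        per_ind.name = "f_roh"
        pops = pd.Series({s: popmap.assignments[s] for s in per_ind.index})
        per_pop = per_ind.groupby(pops).mean()
        per_pop = per_pop.reindex(popmap.populations)
        per_pop.name = "f_roh"
    return per_ind, per_pop


def roh_size_classes(segments: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions of segments per length class ([lo, hi) bounds)."""
    lengths = segments["length"].to_numpy(dtype=float) if len(segments) else \
        np.zeros(0)
    rows = []
    total = lengths.size
    for name, lo, hi in SIZE_CLASSES:
        cnt = int(np.sum((lengths >= lo) & (lengths < hi)))
        rows.append({"size_class": name, "count": cnt,
                     "proportion": cnt / total if total else 0.0})
    return pd.DataFrame(rows)
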