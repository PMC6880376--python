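"""Variant I/O: VCF parsing, site filters and population partitioning.

The central container is :class:`GenotypeMatrix`, a sites x samples store of
diploid alt-allele dosages (0/1/2, -1 for missing) for one chromosome, with
optional phased haplotype alleles and per-site quality annotations.  Only
biallelic SNPs are retained on read; multiallelic records and indels are
dropped and counted, matching the convention of resequencing studies that
extract biallelic SNPs before population-genetic analysis.

Two filter stages mirror a standard GATK/VCFtools workflow:

* hard filters on site annotations (QUAL < 100, QD < 2, MQ < 40, FS > 60,
  SOR > 3, MQRankSum < -12.5, ReadPosRankSum < -8; all strict), where a site
  missing an annotation passes that particular test;
* frequency filters removing sites with minor allele frequency strictly below
  ``maf_min`` or a missing-genotype fraction strictly above ``max_missing``,
  both evaluated across the union of all samples (meta-population level).

Coordinates are 1-based inclusive throughout (VCF convention); conversion to
BED-style half-open intervals happens only at export time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "VcfData",
    "HARD_FILTER_RULES",
    "read_vcf",
    "write_vcf",
    "apply_hard_filters",
    "apply_frequency_filters",
    "split_populations",
    "pool_populations",
]

#: (annotation field, comparison, threshold); a site failing ANY rule is removed.
HARD_FILTER_RULES: tuple[tuple[str, str, float], ...] = (
    ("QUAL", "<", 100.0),
    ("QD", "<", 2.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 60.0),
    ("SOR", ">", 3.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)

_INFO_FIELDS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for one chromosome: sites x samples."""

    chrom: str
    positions: np.ndarray            # int64, 1-based, strictly increasing
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray            # int8 (n_sites, n_samples); -1 = missing
    samples: list[str]
    phase: np.ndarray | None = None  # int8 (n_sites, 2*n_samples); -1 = missing
    site_info: pd.DataFrame | None = None
    chrom_length: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"positions on {self.chrom} are not strictly increasing")
        if self.genotypes.shape != (self.positions.size, len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites x samples")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_phased(self) -> bool:
        return self.phase is not None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset of sites (boolean mask or integer index, order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[index],
            samples=list(self.samples),
            phase=None if self.phase is None else self.phase[index],
            site_info=None if self.site_info is None
            else self.site_info.iloc[np.flatnonzero(index) if index.dtype == bool else index]
            .reset_index(drop=True),
            chrom_length=self.chrom_length,
        )

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        """Column-subset view over a list of sample indices (site set unchanged)."""
        indices = list(indices)
        phase = None
        if self.phase is not None:
            cols = np.array([(2 * i, 2 * i + 1) for i in indices]).reshape(-1)
            phase = self.phase[:, cols]
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            genotypes=self.genotypes[:, indices],
            samples=[self.samples[i] for i in indices],
            phase=phase,
            site_info=self.site_info,
            chrom_length=self.chrom_length,
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele total) over all samples."""
        called = self.genotypes >= 0
        k = np.where(called, self.genotypes, 0).sum(axis=1, dtype=np.int64)
        n = 2 * called.sum(axis=1, dtype=np.int64)
        return k, n

    def missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.genotypes < 0).mean(axis=1)


@dataclass
class PopulationMap:
    """sample -> population assignment with a stable population order."""

    assignments: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.populations:
            seen: list[str] = []
            for pop in self.assignments.values():
                if pop not in seen:
                    seen.append(pop)
            self.populations = seen

    @classmethod
    def from_file(cls, path: str) -> "PopulationMap":
        """Read a headerless two-column (sample TAB population) file."""
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
                sample, pop = parts
                if sample in assignments:
                    raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
                assignments[sample] = pop
        return cls(assignments)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.assignments.items():
                fh.write(f"{sample}\t{pop}\n")

    def samples(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]


@dataclass
class VcfData:
    """Per-chromosome genotype matrices plus read-time exclusion counts."""

    matrices: dict[str, GenotypeMatrix]
    n_records: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0

    @property
    def chroms(self) -> list[str]:
        return list(self.matrices)

    def __getitem__(self, chrom: str) -> GenotypeMatrix:
        return self.matrices[chrom]

    def single(self) -> GenotypeMatrix:
        """The only matrix, for single-chromosome data."""
        if len(self.matrices) != 1:
            raise ValueError(f"expected one chromosome, found {self.chroms}")
        return next(iter(self.matrices.values()))

    @property
    def samples(self) -> list[str]:
        first = next(iter(self.matrices.values()), None)
        return [] if first is None else list(first.samples)


def read_vcf(path: str, region: str | None = None) -> VcfData:
    """Read biallelic SNPs from a VCF into per-chromosome matrices.

    Multiallelic records and indels are dropped and counted.  Phase is kept
    when every non-missing genotype call is phased ("|" separator); half
    calls and non-diploid genotypes are treated as missing with a warning.
    ``region`` is a "chrom" or "chrom:start-end" string filter (1-based
    inclusive), applied while streaming.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    n_s = len(samples)
    lengths: dict[str, int] = {}
    try:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        lengths = {}

    r_chrom, r_start, r_end = None, None, None
    if region is not None:
        if ":" in region:
            r_chrom, span = region.split(":", 1)
            lo, hi = span.split("-", 1)
            r_start, r_end = int(lo), int(hi)
        else:
            r_chrom = region

    per_chrom: dict[str, dict[str, list]] = {}
    n_records = n_multi = n_indel = 0
    n_odd_ploidy = 0
    for v in vcf:
        n_records += 1
        if r_chrom is not None and v.CHROM != r_chrom:
            continue
        if r_start is not None and not (r_start <= v.POS <= r_end):
            continue
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_indel += 1
            continue
        store = per_chrom.setdefault(v.CHROM, {
            "pos": [], "ref": [], "alt": [], "gt": [], "ph": [], "phased": [],
            "info": []})
        if store["pos"] and v.POS <= store["pos"][-1]:
            raise ValueError(f"unsorted VCF: {v.CHROM}:{v.POS} after {store['pos'][-1]}")
        store["pos"].append(v.POS)
        store["ref"].append(v.REF)
        store["alt"].append(v.ALT[0])
        gt = np.full(n_s, -1, dtype=np.int8)
        ph = np.full(2 * n_s, -1, dtype=np.int8)
        all_phased = True
        for i, call in enumerate(v.genotypes):
            alleles = call[:-1]
            phased = bool(call[-1])
            if len(alleles) != 2 or alleles[0] < 0 or alleles[1] < 0:
                if len(alleles) != 2 or any(a >= 0 for a in alleles):
                    n_odd_ploidy += 1
                continue  # missing
            gt[i] = alleles[0] + alleles[1]
            ph[2 * i] = alleles[0]
            ph[2 * i + 1] = alleles[1]
            if not phased:
                all_phased = False
        store["gt"].append(gt)
        store["ph"].append(ph)
        store["phased"].append(all_phased)
        qual = v.QUAL
        info = {"QUAL": np.nan if qual is None else float(qual)}
        for f in _INFO_FIELDS:
            val = v.INFO.get(f)
            info[f] = np.nan if val is None else float(val)
        store["info"].append(info)
    if n_odd_ploidy:
        warnings.warn(f"{n_odd_ploidy} half-calls / non-diploid genotypes treated as missing")

    matrices: dict[str, GenotypeMatrix] = {}
    for chrom, store in per_chrom.items():
        n_sites = len(store["pos"])
        gt = np.array(store["gt"], dtype=np.int8) if n_sites else np.zeros((0, n_s), np.int8)
        phase = None
        if n_sites and all(store["phased"]):
            phase = np.array(store["ph"], dtype=np.int8)
        info_df = pd.DataFrame(store["info"]) if n_sites else None
        if info_df is not None and info_df.drop(columns=["QUAL"]).isna().all().all() \
                and info_df["QUAL"].isna().all():
            info_df = None
        matrices[chrom] = GenotypeMatrix(
            chrom=chrom,
            positions=np.array(store["pos"], dtype=np.int64),
            ref=np.array(store["ref"]),
            alt=np.array(store["alt"]),
            genotypes=gt,
            samples=samples,
            phase=phase,
            site_info=info_df,
            chrom_length=lengths.get(chrom),
        )
    return VcfData(matrices, n_records=n_records, n_multiallelic=n_multi, n_indel=n_indel)


def write_vcf(data: VcfData | GenotypeMatrix | Mapping[str, GenotypeMatrix],
              path: str) -> None:
    """Write matrices back to a VCF v4.2 text file (phased GT when available)."""
    if isinstance(data, GenotypeMatrix):
        matrices: Mapping[str, GenotypeMatrix] = {data.chrom: data}
    elif isinstance(data, VcfData):
        matrices = data.matrices
    else:
        matrices = data
    first = next(iter(matrices.values()))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, gm in matrices.items():
            if gm.chrom_length is not None:
                fh.write(f"##contig=<ID={chrom},length={gm.chrom_length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        has_info = any(gm.site_info is not None for gm in matrices.values())
        if has_info:
            for f in _INFO_FIELDS:
                fh.write(f"##INFO=<ID={f},Number=1,Type=Float,Description=\"{f}\">\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(first.samples) + "\n")
        for chrom, gm in matrices.items():
            info = gm.site_info
            for j in range(gm.n_sites):
                if info is not None:
                    q = info["QUAL"].iloc[j]
                    qual = "." if pd.isna(q) else f"{q:g}"
                    pairs = [f"{f}={info[f].iloc[j]:g}" for f in _INFO_FIELDS
                             if f in info.columns and not pd.isna(info[f].iloc[j])]
                    info_s = ";".join(pairs) if pairs else "."
                else:
                    qual, info_s = ".", "."
                calls = []
                for i in range(gm.n_samples):
                    g = gm.genotypes[j, i]
                    if g < 0:
                        calls.append("./.")
                    elif gm.phase is not None:
                        calls.append(f"{gm.phase[j, 2 * i]}|{gm.phase[j, 2 * i + 1]}")
                    else:
                        calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(g)])
                fh.write(f"{chrom}\t{gm.positions[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t"
                         f"{qual}\tPASS\t{info_s}\tGT\t" + "\t".join(calls) + "\n")


def hard_filter_mask(site_info: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Boolean keep-mask plus a per-site removal log for the seven hard rules.

    A site fails when any annotated value violates its rule; a missing (NaN)
    annotation passes that particular test, mirroring common GATK practice.
    """
    n = len(site_info)
    keep = np.ones(n, dtype=bool)
    reasons: list[list[str]] = [[] for _ in range(n)]
    for fieldname, op, thr in HARD_FILTER_RULES:
        if fieldname not in site_info.columns:
            continue
        vals = site_info[fieldname].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < thr) if op == "<" else (vals > thr)
        bad &= ~np.isnan(vals)
        keep &= ~bad
        for i in np.flatnonzero(bad):
            reasons[i].append(f"{fieldname}{op}{thr}")
    log = pd.DataFrame({
        "removed": ~keep,
        "reasons": [";".join(r) if r else "" for r in reasons],
    })
    return keep, log


def apply_hard_filters(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove sites failing any GATK-style hard rule; returns (matrix, log)."""
    if gm.site_info is None:
        warnings.warn("no site annotations present; hard filters are a no-op")
        log = pd.DataFrame({"chrom": [], "pos": [], "reasons": []})
        return gm, log
    keep, log = hard_filter_mask(gm.site_info)
    out_log = pd.DataFrame({
        "chrom": gm.chrom,
        "pos": gm.positions[~keep],
        "reasons": log.loc[~keep, "reasons"].to_numpy(),
    })
    return gm.take_sites(keep), out_log


def apply_frequency_filters(gm: GenotypeMatrix, maf_min: float = 0.05,
                            max_missing: float = 0.10) -> GenotypeMatrix:
    """Meta-population MAF and missingness filter (strict inequalities).

    A site is removed iff its minor allele frequency over all non-missing
    alleles is strictly below ``maf_min`` or its missing-genotype fraction is
    strictly above ``max_missing``.  All-missing sites are removed.
    """
    k, n = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    miss = gm.missing_fraction()
    keep = (n > 0) & ~(maf < maf_min) & ~(miss > max_missing)
    return gm.take_sites(keep)


def split_populations(gm: GenotypeMatrix, popmap: PopulationMap,
                      pops: Sequence[str] | None = None) -> dict[str, GenotypeMatrix]:
    """Column-subset the matrix into per-population views (site set unchanged)."""
    unknown = set(popmap.assignments) - set(gm.samples)
    if unknown:
        raise ValueError(f"popmap samples not present in the matrix: {sorted(unknown)}")
    missing = set(gm.samples) - set(popmap.assignments)
    if missing:
        raise ValueError(f"matrix samples missing from popmap: {sorted(missing)}")
    pops = list(popmap.populations if pops is None else pops)
    out: dict[str, GenotypeMatrix] = {}
    index = {s: i for i, s in enumerate(gm.samples)}
    for pop in pops:
        cols = [index[s] for s in popmap.samples(pop)]
        if not cols:
            raise ValueError(f"population {pop!r} has no samples")
        out[pop] = gm.take_samples(cols)
    return out


def pool_populations(gm: GenotypeMatrix, popmap: PopulationMap,
                     pops: Sequence[str], name: str | None = None) -> GenotypeMatrix:
    """Union of several populations' samples treated as one population."""
    index = {s: i for i, s in enumerate(gm.samples)}
    cols = [index[s] for p in pops for s in popmap.samples(p) if s in index]
    if not cols:
        raise ValueError(f"no samples found for populations {list(pops)}")
    return gm.take_samples(cols)
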