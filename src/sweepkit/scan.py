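"""Composite selective-sweep scan: thresholds, intersection, regions, genes.

The outlier procedure follows the standard resequencing-scan recipe: window
statistics (weighted F_ST, diversity ratio, window-mean normalized iHH12) are
ranked over windows holding at least ``min_snps`` SNPs; each statistic's
empirical 95th percentile (nearest-rank) defines its outlier threshold; a
window is a selection signal only when it strictly exceeds all three
thresholds.  Signal windows are merged into maximal regions over adjacent or
overlapping windows, and a gene is called under selection when its span
overlaps a region by at least one base pair.

Tajima's D is computed and reported alongside, but does not enter the
three-statistic conjunction.  Undefined statistic values never qualify as
outliers.  An ``any 2 of 3`` relaxation is available behind a switch.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import yaml

from . import variant_io, window_stats, fst as fst_mod, haplotypes as hap_mod
from .variant_io import GenotypeMatrix, PopulationMap

__all__ = [
    "GeneFeature",
    "SweepRegion",
    "filter_windows",
    "empirical_threshold",
    "outlier_intersection",
    "merge_regions",
    "read_gene_features",
    "annotate_genes",
    "run_scan",
    "load_config",
]

STAT_COLUMNS = ("fst", "pi_ratio", "ihh12")


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    stat_max: dict
    stat_mean: dict
    genes: list[str] = dataclasses.field(default_factory=list)


def filter_windows(table: pd.DataFrame, min_snps: int = 10) -> pd.DataFrame:
    """Flag windows eligible for outlier ranking (>= min_snps SNPs, full span).

    All windows are retained in the output; the boolean ``ranked`` column
    marks those that enter threshold estimation and outlier calling.
    """
    out = table.copy()
    ranked = out["n_snps"].to_numpy() >= min_snps
    if "partial" in out.columns:
        ranked &= ~out["partial"].to_numpy()
    out["ranked"] = ranked
    return out


def empirical_threshold(values, q: float = 0.95) -> float:
    """Nearest-rank (inverse ECDF) quantile of the finite values.

    An outlier is a value strictly greater than the returned threshold
    ("right 5% tail" with strict inequality).  Requires at least 20 finite
    values so the tail is populated at the default q.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 20:
        raise ValueError(f"need >= 20 finite values for a {q:.0%} threshold, "
                         f"got {vals.size}")
    vals = np.sort(vals)
    rank = int(np.ceil(q * vals.size))
    rank = min(max(rank, 1), vals.size)
    return float(vals[rank - 1])


def outlier_intersection(table: pd.DataFrame,
                         thresholds: Mapping[str, float],
                         stats: Sequence[str] = STAT_COLUMNS,
                         min_pass: int | None = None) -> pd.DataFrame:
    """Mark windows exceeding the per-statistic thresholds.

    ``min_pass`` defaults to all statistics (full conjunction); set e.g. 2
    for an any-2-of-3 rule.  Comparisons against NaN fail.  Only ``ranked``
    windows can be signals.
    """
    out = table.copy()
    n_pass = np.zeros(len(out), dtype=np.int64)
    for stat in stats:
        thr = thresholds[stat]
        vals = out[stat].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            passed = vals > thr
        passed &= np.isfinite(vals)
        out[f"outlier_{stat}"] = passed
        n_pass += passed
    need = len(stats) if min_pass is None else min_pass
    signal = n_pass >= need
    if "ranked" in out.columns:
        signal &= out["ranked"].to_numpy()
        for stat in stats:
            out[f"outlier_{stat}"] &= out["ranked"]
    out["signal"] = signal
    return out


def merge_regions(windows: pd.DataFrame,
                  stats: Sequence[str] = STAT_COLUMNS) -> list[SweepRegion]:
    """Merge signal windows sharing a boundary (or overlapping) into regions."""
    sig = windows[windows["signal"]] if "signal" in windows.columns else windows
    regions: list[SweepRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        block: list[pd.Series] = []
        for _, row in grp.iterrows():
            if block and row["start"] > block[-1]["end"] + 1:
                regions.append(_finish_region(chrom, block, stats))
                block = []
            block.append(row)
        if block:
            regions.append(_finish_region(chrom, block, stats))
    return regions


def _finish_region(chrom, block, stats) -> SweepRegion:
    df = pd.DataFrame(block)
    stat_max = {s: float(df[s].max()) for s in stats if s in df.columns}
    stat_mean = {s: float(df[s].mean()) for s in stats if s in df.columns}
    return SweepRegion(chrom=str(chrom), start=int(df["start"].min()),
                       end=int(df["end"].max()), n_windows=len(df),
                       stat_max=stat_max, stat_mean=stat_mean)


def read_gene_features(gff_path: str) -> list[GeneFeature]:
    """Gene features from a GFF3 file (gffutils, in-memory database)."""
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneFeature(gene_id, feat.seqid, feat.start, feat.end,
                                 feat.strand or "+"))
    return genes


def annotate_genes(regions: Sequence[SweepRegion],
                   genes: Sequence[GeneFeature] | str) -> list[SweepRegion]:
    """Assign genes overlapping each region by >= 1 bp (1-based inclusive)."""
    if isinstance(genes, str):
        genes = read_gene_features(genes)
    for region in regions:
        hits = [g.gene_id for g in genes
                if g.chrom == region.chrom
                and g.start <= region.end and g.end >= region.start]
        region.genes = sorted(set(hits))
    return regions


def gene_set_overlap(sets: Mapping[str, set]) -> dict:
    """Venn-style counts for gene sets from different comparisons."""
    names = list(sets)
    out = {name: len(sets[name]) for name in names}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            out[f"{a}&{b}"] = len(sets[a] & sets[b])
            out[f"{a}-{b}"] = len(sets[a] - sets[b])
            out[f"{b}-{a}"] = len(sets[b] - sets[a])
    return out


# ---------------------------------------------------------------------------
# pipeline driver

DEFAULT_CONFIG = {
    "window": 10_000,
    "quantile": 0.95,
    "min_snps": 10,
    "maf_min": 0.05,
    "max_missing": 0.10,
    "hard_filters": False,
    "ehh_cutoff": 0.05,
    "max_extend": 1_000_000,
    "min_pass": None,            # None = all three statistics
    "tajima_d": True,
}


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    merged = dict(DEFAULT_CONFIG)
    merged.update(cfg or {})
    return merged


def _chromosome_statistics(gm: GenotypeMatrix, popmap: PopulationMap, focal: str,
                           reference: Sequence[str], cfg: Mapping
                           ) -> tuple[pd.DataFrame, pd.DataFrame, "fst_mod.FstResult"]:
    """Per-window statistics and raw per-SNP iHH12 for one chromosome."""
    window = int(cfg["window"])
    focal_gm = variant_io.pool_populations(gm, popmap, [focal])
    ref_gm = variant_io.pool_populations(gm, popmap, list(reference))

    pi_f = window_stats.windowed_pi(focal_gm, window)
    pi_r = window_stats.windowed_pi(ref_gm, window)
    table = window_stats.pi_ratio(pi_r, pi_f)
    fst_res = fst_mod.windowed_fst([focal_gm, ref_gm], window)
    table["fst"] = fst_res.windows["fst"].to_numpy()
    if cfg["tajima_d"]:
        td = window_stats.windowed_tajima_d(focal_gm, window)
        table["tajima_d"] = td["tajima_d"].to_numpy()
    hm = hap_mod.HaplotypeMatrix.from_genotype_matrix(focal_gm)
    raw = hap_mod.ihh12_scan(hm, cutoff=float(cfg["ehh_cutoff"]),
                             max_extend=int(cfg["max_extend"]))
    return table, raw, fst_res


def _assemble(tables: dict, raw_scores: dict, lengths: dict, cfg: Mapping
              ) -> tuple[pd.DataFrame, dict]:
    """Pool chromosomes: genome-wide iHH12 normalization and thresholds."""
    window = int(cfg["window"])
    pooled = pd.concat(list(raw_scores.values()), ignore_index=True)
    z_all = hap_mod.normalize_scores(pooled["ihh12"].to_numpy())
    offset = 0
    parts = []
    for chrom, raw in raw_scores.items():
        z = z_all[offset:offset + len(raw)]
        offset += len(raw)
        ihh = hap_mod.window_mean_scores(chrom, raw["pos"].to_numpy(), z,
                                         window, lengths.get(chrom))
        tab = tables[chrom].copy()
        tab["ihh12"] = ihh["ihh12"].to_numpy()
        tab["n_scored"] = ihh["n_scored"].to_numpy()
        parts.append(tab)
    table = pd.concat(parts, ignore_index=True)
    table = filter_windows(table, int(cfg["min_snps"]))
    thresholds = {
        stat: empirical_threshold(table.loc[table["ranked"], stat],
                                  float(cfg["quantile"]))
        for stat in STAT_COLUMNS
    }
    table = outlier_intersection(table, thresholds, STAT_COLUMNS, cfg["min_pass"])
    return table, thresholds


def scan_tables(gm: GenotypeMatrix, popmap: PopulationMap, focal: str,
                reference: Sequence[str], config: Mapping | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """Window table with all statistics plus thresholds, for one chromosome.

    ``reference`` may name several populations; their samples are pooled and
    treated as a single reference population for diversity and F_ST.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    stats, raw, fst_res = _chromosome_statistics(gm, popmap, focal, reference, cfg)
    table, thresholds = _assemble({gm.chrom: stats}, {gm.chrom: raw},
                                  {gm.chrom: gm.chrom_length}, cfg)
    meta = {
        "thresholds": thresholds,
        "genome_weighted_fst": fst_res.genome_weighted,
        "genome_weighted_fst_clamped": fst_res.genome_weighted_clamped,
        "n_ranked_windows": int(table["ranked"].sum()),
        "n_signal_windows": int(table["signal"].sum()),
    }
    return table, meta


def run_scan(config: Mapping, out_dir: str) -> dict:
    """Full pipeline: VCF -> filters -> statistics -> outliers -> genes.

    ``config`` needs at least vcf, popmap, focal and reference keys; see
    ``DEFAULT_CONFIG`` for tunables.  Writes window tables, thresholds,
    signal windows, merged regions (TSV + BED), gene assignments and a JSON
    manifest to ``out_dir``; rerunning with the same config reproduces the
    files byte for byte.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    os.makedirs(out_dir, exist_ok=True)
    data = variant_io.read_vcf(cfg["vcf"])
    popmap = PopulationMap.from_file(cfg["popmap"])
    focal = cfg["focal"]
    reference = cfg["reference"]
    if isinstance(reference, str):
        reference = [reference]

    # per-chromosome statistics; normalization and thresholds are genome-wide
    stats_by_chrom: dict[str, pd.DataFrame] = {}
    raw_by_chrom: dict[str, pd.DataFrame] = {}
    lengths: dict[str, int | None] = {}
    fst_summaries = {}
    for chrom in data.chroms:
        gm = data[chrom]
        if cfg["hard_filters"]:
            gm, _ = variant_io.apply_hard_filters(gm)
        gm = variant_io.apply_frequency_filters(gm, float(cfg["maf_min"]),
                                                float(cfg["max_missing"]))
        stats, raw, fst_res = _chromosome_statistics(gm, popmap, focal,
                                                     reference, cfg)
        stats_by_chrom[chrom] = stats
        raw_by_chrom[chrom] = raw
        lengths[chrom] = gm.chrom_length
        fst_summaries[chrom] = {
            "genome_weighted_fst": fst_res.genome_weighted,
            "genome_weighted_fst_clamped": fst_res.genome_weighted_clamped,
        }
    table, thresholds = _assemble(stats_by_chrom, raw_by_chrom, lengths, cfg)
    metas = {
        "thresholds": thresholds,
        "per_chromosome_fst": fst_summaries,
        "n_ranked_windows": int(table["ranked"].sum()),
        "n_signal_windows": int(table["signal"].sum()),
    }

    regions = merge_regions(table)
    genes: list[GeneFeature] = []
    if cfg.get("gff"):
        genes = read_gene_features(cfg["gff"])
        annotate_genes(regions, genes)

    _write_tsv(table, os.path.join(out_dir, "windows.tsv"))
    _write_tsv(table[table["signal"]], os.path.join(out_dir, "signal_windows.tsv"))
    region_df = pd.DataFrame([
        {"chrom": r.chrom, "start": r.start, "end": r.end,
         "n_windows": r.n_windows,
         **{f"max_{s}": r.stat_max.get(s, np.nan) for s in STAT_COLUMNS},
         "genes": ",".join(r.genes)}
        for r in regions])
    _write_tsv(region_df, os.path.join(out_dir, "regions.tsv"))
    with open(os.path.join(out_dir, "regions.bed"), "w") as fh:
        for r in regions:  # BED is 0-based half-open
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\n")
    manifest = {
        "config": {k: v for k, v in sorted(cfg.items())},
        **metas,
        "n_regions": len(regions),
        "n_genes": len(sorted({g for r in regions for g in r.genes})),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return {"windows": table, "regions": regions, "manifest": manifest}


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
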