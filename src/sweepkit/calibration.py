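"""Designed simulation experiments: neutral calibration and sweep recovery.

These drivers define the package's reference simulation studies — the
conditions under which the statistics are validated — and are shared by the
test suite and the reproduction script.  Two experiments are provided:

Neutral calibration
    Two populations split symmetrically from a common ancestor, no selection.
    Checks that genome-mean diversity matches the mutation-drift expectation
    pi = 4*N*mu, that the realized Weir-Cockerham F_ST tracks the pure-drift
    prediction 1 - (1 - 1/(2N))^t for a pairwise separation of t generations,
    and that windowed Tajima's D centres on zero.

Sweep recovery
    An additive beneficial mutation (default s = 0.1) enters the focal
    population at the split and is sampled right around its completion time,
    against a reference population that stays close to the ancestor (a wild
    outgroup proxy).  Replicates qualify when the beneficial allele reaches
    the target frequency; each qualifying replicate runs the full composite
    scan and reports whether a merged three-statistic outlier region contains
    the selected site.  Matched neutral runs (same demography, no sweep)
    measure the conjunction's false-positive rate against each single
    statistic's tail.

Problem sizes (population sizes, chromosome length, replicate counts) are
chosen so one replicate takes seconds on one core; see the methods note for
the reasoning behind each default.
"""

from __future__ import annotations

import dataclasses
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scan as scan_mod
from . import variant_io, window_stats, fst as fst_mod
from .simulate import SimParams, SweepSettings, simulate, write_fixture
from .variant_io import PopulationMap

__all__ = [
    "NEUTRAL_CALIBRATION",
    "SWEEP_RECOVERY",
    "neutral_calibration",
    "sweep_recovery",
    "drift_fst_expectation",
]

#: conditions of the neutral two-population calibration
NEUTRAL_CALIBRATION = dict(
    n_anc=50, pop_size=50, split_gens=20, n_sample=20, seq_len=200_000,
    mu=7.5e-6, rec=7.5e-6, burn_in=500,
)

#: conditions of the sweep-recovery experiment (focal vs outgroup reference)
SWEEP_RECOVERY = dict(
    n_anc=100, focal_size=250, ref_size=100, focal_gens=95, ref_gens=10,
    n_sample=20, seq_len=1_000_000, mu=3.75e-6, rec=1e-6, burn_in=600,
    s=0.1, min_freq=0.95, max_extend=100_000,
)


def drift_fst_expectation(n_diploid: int, t_split: int) -> float:
    """Pure-drift F_ST prediction 1 - (1 - 1/(2N))^t, t = time since the split."""
    return 1.0 - (1.0 - 1.0 / (2 * n_diploid)) ** t_split


@dataclass
class NeutralCalibrationResult:
    pi_mean: float              # genome-mean per-bp diversity over replicates
    pi_expected: float          # 4*N*mu
    fst_mean: float             # genome-wide weighted Weir-Cockerham estimate
    fst_expected: float         # drift prediction for the realized separation
    tajima_d_mean: float        # mean windowed D over all replicate windows
    n_windows: int
    n_replicates: int


def neutral_calibration(n_replicates: int = 20, seed: int = 1,
                        conditions: dict | None = None) -> NeutralCalibrationResult:
    """Run the neutral two-population study and summarize the three checks.

    Diversity and Tajima's D are computed from all biallelic SNPs segregating
    in the sample; F_ST additionally applies the standard MAF >= 0.05 filter
    (the dataset-level filter of the scan pipeline).
    """
    c = dict(NEUTRAL_CALIBRATION)
    c.update(conditions or {})
    seeds = _derive_seeds(seed, n_replicates)
    pis, fsts, d_all = [], [], []
    n_windows = 0
    for s in seeds:
        params = SimParams(
            n_anc=c["n_anc"], pop_sizes=(c["pop_size"], c["pop_size"]),
            split_gens=(c["split_gens"], c["split_gens"]),
            n_sample=c["n_sample"], seq_len=c["seq_len"], mu=c["mu"],
            rec=c["rec"], seed=int(s), burn_in=c["burn_in"],
            pop_names=("popA", "popB"))
        gm, pm = _as_matrix(simulate(params))
        pops = variant_io.split_populations(gm, pm)
        # per-bp diversity and windowed D on the unfiltered sample
        for name in ("popA", "popB"):
            tab = window_stats.windowed_pi(pops[name])
            pis.append(float(tab["pi"].mean()))
            td = window_stats.windowed_tajima_d(pops[name])
            vals = td.loc[~td["partial"], "tajima_d"].dropna()
            d_all.extend(vals.tolist())
            n_windows += len(vals)
        # weighted FST on the MAF-filtered site set
        gm_f = variant_io.apply_frequency_filters(gm)
        pops_f = variant_io.split_populations(gm_f, pm)
        res = fst_mod.windowed_fst([pops_f["popA"], pops_f["popB"]])
        fsts.append(res.genome_weighted)
    return NeutralCalibrationResult(
        pi_mean=float(np.mean(pis)),
        pi_expected=4 * c["pop_size"] * c["mu"],
        fst_mean=float(np.mean(fsts)),
        fst_expected=drift_fst_expectation(c["pop_size"], c["split_gens"]),
        tajima_d_mean=float(np.mean(d_all)),
        n_windows=n_windows,
        n_replicates=n_replicates,
    )


@dataclass
class SweepRecoveryResult:
    n_replicates: int           # qualifying sweep replicates analysed
    n_detected: int             # merged signal region contains the site
    detection_rate: float
    final_freqs: list
    n_simulated: int            # total sweep simulations run (incl. non-qualifying)
    neutral_signal_rate: float  # conjunction FPR on matched neutral windows
    neutral_single_rates: dict  # per-statistic outlier fraction on neutral runs
    n_neutral_windows: int


def _sweep_params(c: dict, seed: int, with_sweep: bool) -> SimParams:
    pos = _target_position(c["seq_len"])
    sweep = SweepSettings("focal", pos, c["s"], c["focal_gens"]) if with_sweep else None
    return SimParams(
        n_anc=c["n_anc"], pop_sizes=(c["focal_size"], c["ref_size"]),
        split_gens=(c["focal_gens"], c["ref_gens"]), n_sample=c["n_sample"],
        seq_len=c["seq_len"], mu=c["mu"], rec=c["rec"], seed=seed,
        burn_in=c["burn_in"], pop_names=("focal", "ref"), sweep=sweep)


def _target_position(seq_len: int) -> int:
    """Centre of the central full 10-kb window."""
    win = (seq_len // 10_000) // 2
    return win * 10_000 - 5_000


def _scan_once(params: SimParams, c: dict):
    result = simulate(params)
    gm, pm = _as_matrix(result)
    gm = variant_io.apply_frequency_filters(gm)
    table, meta = scan_mod.scan_tables(
        gm, pm, "focal", ["ref"], {"max_extend": c["max_extend"]})
    return result, table, meta


def sweep_recovery(n_replicates: int = 20, seed: int = 2,
                   n_neutral: int = 8, max_simulations: int = 60,
                   conditions: dict | None = None) -> SweepRecoveryResult:
    """Run the sweep-recovery study plus matched neutral false-positive runs.

    Seeds are drawn deterministically from ``seed``; sweep simulations run
    until ``n_replicates`` reach the qualifying frequency (or the simulation
    budget is exhausted, in which case fewer replicates are analysed).
    """
    c = dict(SWEEP_RECOVERY)
    c.update(conditions or {})
    pos = _target_position(c["seq_len"])
    seeds = _derive_seeds(seed, max_simulations + n_neutral)
    sweep_seeds = seeds[:max_simulations]
    neutral_seeds = seeds[max_simulations:]

    detected = 0
    freqs: list[float] = []
    n_sim = 0
    n_qual = 0
    for s in sweep_seeds:
        if n_qual >= n_replicates:
            break
        n_sim += 1
        params = _sweep_params(c, int(s), with_sweep=True)
        result, table, _ = _scan_once(params, c)
        ff = result.truth.final_freq
        if ff is None or ff < c["min_freq"]:
            continue
        n_qual += 1
        freqs.append(ff)
        regions = scan_mod.merge_regions(table)
        if any(r.chrom == result.chrom and r.start <= pos <= r.end
               for r in regions):
            detected += 1

    n_sig = n_ranked = 0
    singles = {stat: 0 for stat in scan_mod.STAT_COLUMNS}
    for s in neutral_seeds[:n_neutral]:
        params = _sweep_params(c, int(s), with_sweep=False)
        _, table, _ = _scan_once(params, c)
        ranked = table[table["ranked"]]
        n_ranked += len(ranked)
        n_sig += int(ranked["signal"].sum())
        for stat in scan_mod.STAT_COLUMNS:
            singles[stat] += int(ranked[f"outlier_{stat}"].sum())

    return SweepRecoveryResult(
        n_replicates=n_qual,
        n_detected=detected,
        detection_rate=detected / n_qual if n_qual else float("nan"),
        final_freqs=freqs,
        n_simulated=n_sim,
        neutral_signal_rate=n_sig / n_ranked if n_ranked else float("nan"),
        neutral_single_rates={k: v / n_ranked if n_ranked else float("nan")
                              for k, v in singles.items()},
        n_neutral_windows=n_ranked,
    )


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31 from one base seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def _as_matrix(result) -> tuple[variant_io.GenotypeMatrix, PopulationMap]:
    """Simulation output as an in-memory GenotypeMatrix plus popmap."""
    hap = np.concatenate([result.haplotypes[p] for p in result.params.pop_names],
                         axis=0).T.astype(np.int8)
    genotypes = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)
    samples = [s for _, s in result.all_samples()]
    gm = variant_io.GenotypeMatrix(
        chrom=result.chrom, positions=result.positions.copy(),
        ref=result.ref.copy(), alt=result.alt.copy(), genotypes=genotypes,
        samples=samples, phase=hap, chrom_length=result.seq_len)
    pm = PopulationMap({s: p for p, s in result.all_samples()},
                       list(result.params.pop_names))
    return gm, pm
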