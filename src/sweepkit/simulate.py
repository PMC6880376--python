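"""Forward Wright-Fisher simulator for multi-population sweep fixtures.

Simulates diploid populations descended star-like from a common ancestor on a
single linear chromosome, with infinite-sites mutation, Poisson crossover
recombination, and an optional additive hard sweep (fitness 1, 1+s, 1+2s) in
one descendant population.  The simulator exists to provide genotype data with
*known* demography and selection truth for calibrating and testing the scan
statistics; it makes no attempt to infer a realistic goat demography.  Default
rates are chosen so that equilibrium diversity (pi ~ 4*N*mu ~ 1.5e-3/bp) and
between-population differentiation (F_ST ~ 0.15-0.2) match the magnitudes
typical of domestic goat resequencing panels.

Fixture output (``write_fixture``) is plain text: VCF v4.2 with phased GT, a
sample->population map, a toy GFF3 gene track, and a JSON ground-truth record.
Identical parameters (including the seed) give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SweepSettings",
    "SimParams",
    "SimTruth",
    "SimResult",
    "simulate",
    "write_fixture",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SweepSettings:
    """A single beneficial mutation introduced into one population.

    ``t_intro`` counts generations before sampling; the mutation enters the
    named population as a single haploid copy.  If it is lost it is
    re-introduced immediately (fresh single copy, same position) up to
    ``max_attempts`` times so that swept fixtures are obtainable; the attempt
    count is recorded in the truth.
    """

    pop: str
    position: int
    s: float
    t_intro: int
    max_attempts: int = 100


@dataclass(frozen=True)
class SimParams:
    """Demography, rates and sampling design for one simulation run.

    Sizes are diploid counts. ``split_gens[i]`` is the number of generations
    population ``i`` has drifted since splitting from the ancestor (star
    topology).  ``mu``/``rec`` are per-bp per-generation rates.  ``burn_in``
    defaults to ``10 * n_anc`` generations, long enough for mutation-drift
    equilibrium of the ancestor starting from a monomorphic state.
    """

    n_anc: int = 100
    pop_sizes: tuple[int, ...] = (100, 100)
    split_gens: tuple[int, ...] = (40, 40)
    n_sample: tuple[int, ...] | int = 15
    seq_len: int = 2_000_000
    mu: float = 3.75e-6
    rec: float = 3.75e-6
    sweep: SweepSettings | None = None
    missing_rate: float = 0.0
    seed: int = 0
    burn_in: int | None = None
    pop_names: tuple[str, ...] | None = None
    chrom: str = "chr1"

    def __post_init__(self):
        npop = len(self.pop_sizes)
        if npop < 1:
            raise ValueError("at least one descendant population is required")
        if len(self.split_gens) != npop:
            raise ValueError("split_gens and pop_sizes must have equal length")
        names = self.pop_names
        if names is None:
            names = tuple(f"pop{i + 1}" for i in range(npop))
        elif len(names) != npop:
            raise ValueError("pop_names and pop_sizes must have equal length")
        object.__setattr__(self, "pop_names", names)
        ns = self.n_sample
        if isinstance(ns, int):
            ns = (ns,) * npop
        else:
            ns = tuple(ns)
            if len(ns) != npop:
                raise ValueError("n_sample and pop_sizes must have equal length")
        object.__setattr__(self, "n_sample", ns)
        if self.n_anc < 2 or any(n < 2 for n in self.pop_sizes):
            raise ValueError("population sizes must be >= 2")
        if any(n < 2 for n in ns):
            raise ValueError("n_sample must be >= 2 per population")
        if any(n > p for n, p in zip(ns, self.pop_sizes)):
            raise ValueError("cannot sample more diploids than the population holds")
        if any(t < 0 for t in self.split_gens):
            raise ValueError("split_gens must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.seq_len < 1 or self.mu < 0 or self.rec < 0:
            raise ValueError("seq_len must be >= 1 and rates non-negative")
        sw = self.sweep
        if sw is not None:
            if sw.pop not in names:
                raise ValueError(f"sweep population {sw.pop!r} not among {names}")
            if not (1 <= sw.position <= self.seq_len):
                raise ValueError("sweep position must lie in [1, seq_len]")
            if sw.s <= 0:
                raise ValueError("selection coefficient s must be > 0")
            idx = names.index(sw.pop)
            if sw.t_intro > self.split_gens[idx]:
                raise ValueError("sweep must be introduced after the population split")
            if sw.t_intro < 1:
                raise ValueError("t_intro must be >= 1")

    @property
    def effective_burn_in(self) -> int:
        return 10 * self.n_anc if self.burn_in is None else self.burn_in


@dataclass
class SimTruth:
    """Ground truth of one run: demography plus the fate of the sweep allele.

    ``final_freq`` is the beneficial-allele frequency among the *sampled*
    haplotypes of the focal population; fields are ``None`` for neutral runs.
    """

    selected_pos: int | None
    selected_pop: str | None
    final_freq: float | None
    sweep_attempts: int | None
    pop_names: list[str]
    pairwise_split_gens: list[list[int]]
    params: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    """Sampled phased haplotypes over the union of segregating sites."""

    chrom: str
    seq_len: int
    positions: np.ndarray  # int64, 1-based, strictly increasing
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: dict[str, np.ndarray]  # pop -> (2*n_sample, n_sites) uint8
    sample_names: dict[str, list[str]]
    truth: SimTruth
    params: SimParams

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def all_samples(self) -> list[tuple[str, str]]:
        return [(p, s) for p in self.params.pop_names for s in self.sample_names[p]]


def _draw_positions(rng: np.random.Generator, n: int, seq_len: int, taken: set[int]) -> list[int]:
    """Draw ``n`` distinct new integer positions (infinite sites: collisions redrawn)."""
    out: list[int] = []
    while len(out) < n:
        for p in rng.integers(1, seq_len + 1, size=n - len(out)):
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
    return out


class _Population:
    """Haplotype pool of one population over its currently segregating sites."""

    def __init__(self, H: np.ndarray, positions: np.ndarray, rng: np.random.Generator,
                 params: SimParams, track_fixed: bool):
        self.H = H  # (n_hap, S) uint8
        self.positions = positions  # int64 sorted
        self.rng = rng
        self.params = params
        self.fixed: set[int] = set()
        self.track_fixed = track_fixed
        self.sweep_pos: int | None = None
        self.sweep_s = 0.0
        self.sweep_attempts = 0
        self.sweep_max_attempts = 0

    # -- sweep bookkeeping -------------------------------------------------
    def introduce_sweep(self, position: int, s: float, max_attempts: int) -> None:
        self.sweep_pos = position
        self.sweep_s = s
        self.sweep_max_attempts = max_attempts
        if position in self.fixed:  # overwritten by the beneficial mutation
            self.fixed.discard(position)
        i = np.searchsorted(self.positions, position)
        if i < self.positions.size and self.positions[i] == position:
            # drop a colliding neutral variant (rare) so the site is clean
            keep = np.ones(self.positions.size, bool)
            keep[i] = False
            self.H = self.H[:, keep]
            self.positions = self.positions[keep]
        self._add_single_copy()

    def _add_single_copy(self) -> None:
        self.sweep_attempts += 1
        n_hap = self.H.shape[0]
        col = np.zeros((n_hap, 1), dtype=np.uint8)
        col[int(self.rng.integers(0, n_hap)), 0] = 1
        i = int(np.searchsorted(self.positions, self.sweep_pos))
        self.H = np.concatenate([self.H[:, :i], col, self.H[:, i:]], axis=1)
        self.positions = np.insert(self.positions, i, self.sweep_pos)

    def sweep_state(self) -> str:
        """'seg', 'fixed' or 'lost' for the beneficial allele."""
        if self.sweep_pos is None:
            return "none"
        if self.sweep_pos in self.fixed:
            return "fixed"
        i = np.searchsorted(self.positions, self.sweep_pos)
        if i < self.positions.size and self.positions[i] == self.sweep_pos:
            return "seg"
        return "lost"

    def _fitness_weights(self) -> np.ndarray | None:
        if self.sweep_pos is None or self.sweep_state() != "seg":
            return None
        i = int(np.searchsorted(self.positions, self.sweep_pos))
        alleles = self.H[:, i].astype(np.float64)
        dosage = alleles[0::2] + alleles[1::2]
        w = 1.0 + self.sweep_s * dosage
        return w / w.sum()

    # -- one Wright-Fisher generation --------------------------------------
    def step(self, n_children: int) -> None:
        p = self.params
        rng = self.rng
        H, positions = self.H, self.positions
        n_par = H.shape[0] // 2
        n_gam = 2 * n_children
        weights = self._fitness_weights()
        if weights is None:
            parents = rng.integers(0, n_par, size=n_gam)
        else:
            parents = rng.choice(n_par, size=n_gam, p=weights)
        start = rng.integers(0, 2, size=n_gam)
        n_xo = rng.poisson(p.rec * p.seq_len, size=n_gam)
        child = np.empty((n_gam, positions.size), dtype=np.uint8)
        plain = n_xo == 0
        child[plain] = H[2 * parents[plain] + start[plain]]
        rec = np.flatnonzero(~plain)
        if rec.size:
            pos_f = positions.astype(np.float64)
            k_max = int(n_xo[rec].max())
            # crossover breakpoints, padded beyond the chromosome end
            bp = np.full((rec.size, k_max), np.inf)
            for m, i in enumerate(rec):
                bp[m, : n_xo[i]] = rng.uniform(0.0, p.seq_len, size=n_xo[i])
            # parity of breakpoints left of each site selects the haplotype
            parity = np.zeros((rec.size, positions.size), dtype=np.uint8)
            for m in range(k_max):
                parity += bp[:, m, None] < pos_f[None, :]
            take_other = (parity & 1).astype(bool)
            A = H[2 * parents[rec] + start[rec]]
            B = H[2 * parents[rec] + 1 - start[rec]]
            child[rec] = np.where(take_other, B, A)
        # new mutations (infinite sites)
        n_new = rng.poisson(n_gam * p.mu * p.seq_len)
        if n_new:
            taken = set(positions.tolist())
            taken.update(self.fixed)
            newpos = _draw_positions(rng, n_new, p.seq_len, taken)
            carriers = rng.integers(0, n_gam, size=n_new)
            cols = np.zeros((n_gam, n_new), dtype=np.uint8)
            cols[carriers, np.arange(n_new)] = 1
            child = np.concatenate([child, cols], axis=1)
            positions = np.concatenate([positions, np.asarray(newpos, dtype=np.int64)])
        # prune lost / fixed columns and restore position order in one gather
        counts = child.sum(axis=0, dtype=np.int64)
        fixed_mask = counts == n_gam
        if self.track_fixed and fixed_mask.any():
            self.fixed.update(int(q) for q in positions[fixed_mask])
        keep = np.flatnonzero((counts > 0) & ~fixed_mask)
        kept_pos = positions[keep]
        order = np.argsort(kept_pos, kind="stable")
        self.H = child[:, keep[order]]
        self.positions = kept_pos[order]
        # rescue a lost beneficial allele
        if self.sweep_pos is not None and self.sweep_state() == "lost":
            if self.sweep_attempts < self.sweep_max_attempts:
                self._add_single_copy()


def simulate(params: SimParams) -> SimResult:
    """Run the forward simulation and sample phased haplotypes.

    Returns the sampled haplotypes of every population over the shared union
    of sites segregating in the combined (meta) sample, plus the ground truth.
    Deterministic for a given ``SimParams``.
    """
    root = np.random.SeedSequence(params.seed)
    npop = len(params.pop_sizes)
    streams = root.spawn(npop + 2)  # ancestor, per-pop, alleles/masking
    rng_anc = np.random.default_rng(streams[0])

    # ancestral burn-in from a monomorphic start
    anc = _Population(
        np.zeros((2 * params.n_anc, 0), dtype=np.uint8),
        np.zeros(0, dtype=np.int64), rng_anc, params, track_fixed=False)
    for _ in range(params.effective_burn_in):
        anc.step(params.n_anc)

    pops: dict[str, _Population] = {}
    for i, name in enumerate(params.pop_names):
        rng_i = np.random.default_rng(streams[1 + i])
        n_i = params.pop_sizes[i]
        t_i = params.split_gens[i]
        if t_i == 0:
            # no drift: deterministic copy/resize of the ancestral pool
            idx = np.arange(2 * n_i) % (2 * params.n_anc)
            pop = _Population(anc.H[idx].copy(), anc.positions.copy(), rng_i,
                              params, track_fixed=True)
        else:
            pop = _Population(anc.H, anc.positions, rng_i, params, track_fixed=True)
        sweep = params.sweep if params.sweep is not None and params.sweep.pop == name else None
        for g in range(t_i):
            if sweep is not None and t_i - g == sweep.t_intro and pop.sweep_pos is None:
                pop.introduce_sweep(sweep.position, sweep.s, sweep.max_attempts)
            pop.step(n_i)
        if sweep is not None and pop.sweep_pos is None:
            pop.introduce_sweep(sweep.position, sweep.s, sweep.max_attempts)
        pops[name] = pop

    # sample the first n_sample diploids of each population (exchangeable rows)
    samples: dict[str, np.ndarray] = {}
    for i, name in enumerate(params.pop_names):
        samples[name] = pops[name].H[: 2 * params.n_sample[i]]

    # union of candidate positions: segregating anywhere or fixed-derived somewhere
    cand: set[int] = set()
    for name in params.pop_names:
        cand.update(pops[name].positions.tolist())
        cand.update(pops[name].fixed)
    all_pos = np.array(sorted(cand), dtype=np.int64)

    mats: dict[str, np.ndarray] = {}
    total = np.zeros(all_pos.size, dtype=np.int64)
    n_hap_total = 0
    for i, name in enumerate(params.pop_names):
        n_hap = 2 * params.n_sample[i]
        M = np.zeros((n_hap, all_pos.size), dtype=np.uint8)
        pop = pops[name]
        if pop.positions.size:
            cols = np.searchsorted(all_pos, pop.positions)
            M[:, cols] = samples[name]
        if pop.fixed:
            fixed_cols = np.searchsorted(all_pos, np.array(sorted(pop.fixed), dtype=np.int64))
            M[:, fixed_cols] = 1
        mats[name] = M
        total += M.sum(axis=0, dtype=np.int64)
        n_hap_total += n_hap
    seg = (total > 0) & (total < n_hap_total)
    positions = all_pos[seg]
    for name in params.pop_names:
        mats[name] = np.ascontiguousarray(mats[name][:, seg])

    rng_misc = np.random.default_rng(streams[-1])
    ref_idx = rng_misc.integers(0, 4, size=positions.size)
    alt_idx = (ref_idx + rng_misc.integers(1, 4, size=positions.size)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    final_freq = None
    attempts = None
    if params.sweep is not None:
        sw = params.sweep
        attempts = pops[sw.pop].sweep_attempts
        i = np.searchsorted(positions, sw.position)
        if i < positions.size and positions[i] == sw.position:
            final_freq = float(mats[sw.pop][:, i].mean())
        else:
            state = pops[sw.pop].sweep_state()
            final_freq = 1.0 if state == "fixed" else 0.0

    t = params.split_gens
    pairwise = [[0 if i == j else t[i] + t[j] for j in range(npop)] for i in range(npop)]
    truth = SimTruth(
        selected_pos=params.sweep.position if params.sweep else None,
        selected_pop=params.sweep.pop if params.sweep else None,
        final_freq=final_freq,
        sweep_attempts=attempts,
        pop_names=list(params.pop_names),
        pairwise_split_gens=pairwise,
        params=_params_dict(params),
    )
    sample_names = {
        name: [f"{name}_{k:03d}" for k in range(params.n_sample[i])]
        for i, name in enumerate(params.pop_names)
    }
    return SimResult(params.chrom, params.seq_len, positions, ref, alt,
                     mats, sample_names, truth, params)


def _params_dict(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    if d["sweep"] is not None:
        d["sweep"] = dataclasses.asdict(params.sweep)
    return d


# ---------------------------------------------------------------------------
# fixture writers

def write_fixture(result: SimResult, out_dir: str | os.PathLike,
                  gene_tile: int = 50_000, gene_len: int = 20_000) -> dict[str, str]:
    """Write VCF, popmap, toy GFF3 and truth JSON for a simulation result.

    Genotype calls are masked at the simulated ``missing_rate`` (written as
    ``./.``); the masking RNG is derived from the simulation seed, so repeated
    calls are byte-identical.  The toy GFF3 tiles one gene per ``gene_tile``
    bp and, when a sweep is present, adds a gene centred on the selected site.
    """
    os.makedirs(out_dir, exist_ok=True)
    params = result.params
    paths = {
        "vcf": os.path.join(out_dir, "sim.vcf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    order = result.all_samples()
    n_samples = len(order)
    hap = np.concatenate([result.haplotypes[p] for p in params.pop_names], axis=0)
    # sites x (2*samples)
    hap = np.ascontiguousarray(hap.T)
    mask_rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(
        len(params.pop_sizes) + 3)[-1])
    if params.missing_rate > 0:
        missing = mask_rng.random((result.n_sites, n_samples)) < params.missing_rate
    else:
        missing = np.zeros((result.n_sites, n_samples), dtype=bool)

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={result.chrom},length={result.seq_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s for _, s in order) + "\n")
        for j in range(result.n_sites):
            a = hap[j, 0::2]
            b = hap[j, 1::2]
            calls = np.char.add(np.char.add(a.astype("U1"), "|"), b.astype("U1"))
            calls[missing[j]] = "./."
            fh.write(f"{result.chrom}\t{result.positions[j]}\t.\t{result.ref[j]}\t"
                     f"{result.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")

    with open(paths["popmap"], "w") as fh:
        for pop, s in order:
            fh.write(f"{s}\t{pop}\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        k = 0
        start = gene_tile // 2 - gene_len // 2 + 1
        while start + gene_len - 1 <= result.seq_len:
            end = start + gene_len - 1
            fh.write(f"{result.chrom}\tsweepkit\tgene\t{start}\t{end}\t.\t+\t.\t"
                     f"ID=gene{k + 1:05d};Name=gene{k + 1:05d}\n")
            k += 1
            start += gene_tile
        sel = result.truth.selected_pos
        if sel is not None:
            g_start = max(1, sel - gene_len // 2)
            g_end = min(result.seq_len, sel + gene_len // 2)
            fh.write(f"{result.chrom}\tsweepkit\tgene\t{g_start}\t{g_end}\t.\t+\t.\t"
                     f"ID=gene_selected;Name=gene_selected\n")

    with open(paths["truth"], "w") as fh:
        fh.write(result.truth.to_json())
        fh.write("\n")
    return paths
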