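# Methods

## Scope and model

sweepkit implements the composite selective-sweep scan used in livestock
resequencing studies: per-population nucleotide diversity (π), Watterson's
θ_W and Tajima's D in non-overlapping 10-kb windows; Weir–Cockerham F_ST per
SNP and as a weighted (ratio-of-sums) window estimate; the haplotype
homozygosity statistic iHH12 per SNP with genome-wide normalization and
window averaging; diversity ratios θπ(reference)/θπ(focal); PLINK-style runs
of homozygosity and the genomic inbreeding coefficient F_ROH; and LD decay.
Windows holding at least 10 SNPs are ranked, each statistic's empirical 95th
percentile (nearest rank) defines its outlier threshold, and a window is
called a selection signal only when it strictly exceeds the F_ST, θπ-ratio
and iHH12 thresholds simultaneously. Signal windows merge into regions;
genes overlapping a region by ≥ 1 bp are called under selection.

Statistic definitions and numerical conventions:

* **π** — per-site unbiased heterozygosity k(n−k)/C(n,2) summed over window
  sites and divided by the *full window width*, so monomorphic bp count as
  invariant. This matches per-bp magnitudes of ~1.5×10⁻³ typical for goat
  and sheep panels. Accessible-base masks are out of scope. The window grid
  is anchored at position 1; the trailing partial window is reported with a
  `partial` flag and never enters outlier ranking.
* **Tajima's D** — classical constants a₁…e₂ from the haplotype count; the
  window's mean pairwise difference is used in absolute units. D requires
  complete genotypes (real data are phased/imputed upstream; simulated data
  are complete by construction); missing calls raise an error rather than
  silently changing n per site. S = 0 windows are undefined (NA).
* **F_ST** — Weir–Cockerham (1984) variance components a, b, c per biallelic
  site from per-population sample sizes, allele frequencies and observed
  heterozygosity, with missing genotypes excluded from counts. Sites where
  any population has no genotyped individual, or where the mean sample size
  is ≤ 1, are skipped. Windows and the genome-wide summary use Σa/Σ(a+b+c)
  ("weighted"); the mean of per-site ratios is also emitted as a diagnostic.
  Negative estimates are retained in tables and clamped to 0 only in summary
  prose.
* **iHH12** — EHH12(x) partitions haplotypes by identity over the span from
  the core site to x, pools the two largest classes, and normalizes by
  C(n,2); the profile is integrated trapezoidally over physical distance on
  both sides, truncating at the interpolated crossing of the EHH cutoff
  (default 0.05), at `max_extend`, or at the chromosome end. Scores are
  z-normalized genome-wide with the population (denominator n) standard
  deviation, then averaged per window. No genetic map is used. A compiled
  (numba) kernel accelerates the per-SNP scan; the pure-NumPy profile
  implementation is the reference path and the two are asserted equal in the
  tests.
* **LD** — D, D′ and r² from phased haplotype counts (genotype-dosage
  correlation as a flagged fallback when phase is absent). Decay curves bin
  pairs by distance (defaults 300 kb / 1 kb) after a MAF ≥ 0.05 filter,
  consistent with the dataset-level filter.
* **ROH** — the scanning-window heuristic: 50-SNP windows (span ≤ 5 Mb) are
  homozygous iff ≤ 1 heterozygous and ≤ 5 missing calls; a SNP is in the ROH
  state when ≥ 5% of its valid containing windows are homozygous; runs split
  at > 100 kb gaps and are filtered by ≥ 10 SNPs, ≥ 100 kb and ≤ 10 kb/SNP
  density. Window-missing and the 5% hit threshold adopt the wrapped tool's
  defaults because typical published commands omit them; both are exposed.
  Segment endpoints are the first/last in-state SNP positions. Segments
  longer than the 5-Mb window cap are allowed when the SNP state supports
  them. F_ROH divides the overlap-merged ROH total by 2.92 Gb, the autosomal
  span of the ARS1 goat assembly.

### Filters

Hard site filters follow the GATK convention (QUAL < 100, QD < 2, MQ < 40,
FS > 60, SOR > 3, MQRankSum < −12.5, ReadPosRankSum < −8.0; all strict, so
boundary values pass); a site missing an annotation passes that particular
rule. Frequency filters remove sites with MAF strictly below 0.05 or a
missing-genotype fraction strictly above 10%, both computed across the union
of all samples (the meta-population); half-calls and non-diploid genotypes
count as missing. Multiallelic records and indels are dropped at read time,
never decomposed. Coordinates are 1-based inclusive internally; BED exports
are 0-based half-open.

### Composite scan choices

* Thresholds are nearest-rank 95th percentiles over ranked windows only
  (≥ 10 SNPs, full span); outlier status is strict ">". Undefined statistic
  values (e.g. θπ ratio with a zero denominator) never qualify.
* θπ-ratio thresholds operate on the raw ratio; log₂ values are for display.
* Tajima's D is computed and reported but does not enter the three-statistic
  conjunction; an any-2-of-3 relaxation exists behind `min_pass`.
* A pooled control comparison treats the union of the control populations'
  samples as a single reference population for π and F_ST, rather than
  averaging per-population statistics.

## The simulator

A discrete-locus forward Wright–Fisher simulator generates the study data:
a single ancestor evolves to mutation–drift equilibrium from a monomorphic
start (default burn-in 10·N_anc generations; experiments use ≥ 6·N_anc,
which leaves expected diversity within e⁻³ ≈ 5% of equilibrium), then
descendant populations split star-like and drift independently. Mutation is
infinite-sites with uniform integer positions (collisions redrawn);
recombination draws a Poisson(rec·L) number of crossovers per meiosis with
uniform breakpoints. An optional beneficial mutation enters one population
as a single copy with additive fitness 1, 1+s, 1+2s; if lost it is
immediately re-seeded as a fresh single copy (up to 100 attempts, counted in
the ground truth) so completed-sweep fixtures are obtainable. Sampling takes
the first n diploids per population (individuals are exchangeable);
fixed-versus-lost bookkeeping per population reconstructs the meta-sample
site set exactly. One seed drives everything through per-population
substreams, so identical parameters give byte-identical fixture files (VCF
with phased GT, popmap, toy GFF3, truth JSON).

Default rates emulate the magnitudes of domestic-goat panels: θ = 4Nμ =
1.5×10⁻³/bp and drift F_ST ≈ 0.18 between populations split 40 generations
at N = 100. These are time-rescaled cartoons, not goat demography: real
breeds have N_e in the thousands and split thousands of generations ago.
What the generator does not emulate: variable recombination and mutation
rate along the chromosome, gene flow after the split, genotyping error
beyond uniform missingness, and background selection. Passing tests
therefore show the estimators and the scan machinery are correct and
calibrated under drift-mutation-recombination dynamics, not that the
pipeline's power on real goat data equals the simulated power.

## Designed experiments

**Neutral calibration** (`sweepkit.calibration.neutral_calibration`): 20
replicates of two populations of N = 50 split 20 generations (t/2N = 0.2),
200-kb chromosome, μ = rec = 7.5×10⁻⁶ so 4Nμ = 1.5×10⁻³. π and windowed
Tajima's D are computed from all sample-segregating biallelic SNPs; F_ST
applies the pipeline's MAF ≥ 0.05 filter first. Checks: genome-mean π within
15% of 4Nμ; genome-wide weighted F_ST within ±0.05 of the pure-drift
prediction 1−(1−1/(2N))^t with t the time since the split; mean windowed D
within (−0.3, 0.3) over ≥ 200 windows.

**Sweep recovery** (`sweepkit.calibration.sweep_recovery`): the focal
population (N = 250) splits from the ancestor (N_anc = 100) and immediately
receives a single-copy additive beneficial mutation (s = 0.1) at the centre
of the middle 10-kb window of a 1-Mb chromosome; the reference population
(N = 100, split 10 generations) stands in for a wild outgroup. The focal
branch lasts 95 generations — approximately the conditional completion time
of an s = 0.1 sweep at this size — so qualifying replicates (final
beneficial-allele frequency ≥ 95%) are sampled close to sweep completion,
where the hitchhiking signature is strongest. rec = 1×10⁻⁶ (ρ/θ ≈ 0.27)
keeps the hitchhiking footprint, roughly 1/(rec·T_sweep) ≈ 10 kb, on the
scale of one analysis window while leaving enough background recombination
for iHH12 contrast. iHH12 uses `max_extend` = 100 kb (several footprint
lengths) so scores measure local homozygosity rather than chromosome-scale
extension room. Replicate seeds are drawn deterministically from one base
seed until 20 replicates qualify. Matched neutral runs (same demography, no
sweep) measure the conjunction's false-positive rate against each single
statistic's 5% tail.

A caveat this experiment makes explicit: under time rescaling, an s = 0.1
sweep completes in ~90 generations while the per-generation recombination
rate is inflated by the same rescaling, so the product rec·T_sweep — which
controls how often the beneficial allele recombines onto additional
haplotype backgrounds during the sojourn at low frequency — is far larger
than in a real-sized population. A substantial minority of completed
simulated sweeps are therefore "soft" at the 10-kb scale: a secondary
recombinant haplotype reaches intermediate frequency, local diversity is not
erased, and the θπ-ratio leg of the three-statistic conjunction fails even
though F_ST at the selected site and iHH12 (which pools the top two
haplotype classes) remain elevated. This depresses the measured detection
rate of the full conjunction relative to what the same scan achieves on
real-timescale sweeps; the false-positive comparison is unaffected.

**ROH recovery**: planted homozygous tracts (200 homozygous SNPs at 1 SNP /
2 kb inside heterozygous flanks) must be recovered with boundary error of at
most one inter-SNP interval, sub-threshold plants (9 SNPs) rejected, and
F_ROH of planted totals must match hand arithmetic against 2.92 Gb.

## Problem sizes and runtime

All experiment sizes were chosen so the full validation suite runs on one
CPU core in well under half an hour: a neutral calibration replicate takes
~1 s and a sweep-recovery replicate (simulation plus full scan) ~15 s. The
per-SNP iHH12 scan uses the compiled kernel when numba is available and
falls back to NumPy otherwise.

## Known limitations

* The simulator's star phylogeny has no post-split migration; Treemix-style
  gene-flow scenarios cannot be emulated.
* iHH12 normalization is a single genome-wide z-score; derived-allele
  frequency bins are not implemented (the cited normalization detail varies
  between tools), only config-level cutoff and extension control.
* The θπ-ratio denominator policy (undefined when the focal window has zero
  diversity) means fully erased windows rely on F_ST and iHH12 via
  neighbouring windows; in practice sweep windows retain a few
  reference-private SNPs and remain defined.
* ROH detection assumes diallelic dosage tracks; no LD pruning is applied
  beforehand, matching common resequencing practice.
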