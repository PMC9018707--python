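# Methods

This note documents the models, estimators, numerical choices and known
limitations of `sweepscan`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Statistics

### Extended haplotype homozygosity and iHS

For a core SNP and core allele with `n_c ≥ 2` carrier haplotypes, EHH at a
marker `x` is the unbiased pair-counting form

    EHH(x) = Σ_h n_h (n_h − 1) / (n_c (n_c − 1)),

where `n_h` counts copies of each distinct haplotype spanning the interval
from the core to `x`. EHH is 1 at the core and non-increasing outward
(refining a partition can only lower pairwise identity); both properties
are asserted in tests, and the whole computation is cross-checked to
1e-12 against a brute-force pair-enumeration oracle on randomized panels.

iHH is the trapezoidal integral of the EHH curve over physical distance
(bp), both arms summed. Arms stop when EHH drops below the cutoff
(default 0.05), at the chromosome end, or at a configured extension/gap
limit. When the cutoff is crossed, the closing segment ends at the first
sub-cutoff marker with its observed EHH value — no extrapolation. We
integrate over physical rather than genetic distance because 50k-chip
data typically carries no genetic map; any constant bp→cM factor cancels
in the iHS ratio.

The raw score per SNP is `ln(iHH_ancestral / iHH_derived)`, standardized
to mean 0 / sd 1 within derived-allele-frequency bins of width 0.025
(population sd, ddof = 0 — this is what makes the per-bin identity exact).
Bins with fewer than two scored SNPs give no score (reason `small_bin`).
Negative standardized scores mark extended derived haplotypes. The
significance scale is

    piHS = −log10(1 − 2|Φ(x) − 0.5|) = −log10(erfc(|x| / √2)),

evaluated directly in the complement form so scores out to |x| ≈ 8 (and
beyond) retain full accuracy; the significance rule is strict
(`piHS > 6`). SNPs with unknown ancestral state, MAF below the floor
(default 0.01), fewer than two carriers of either allele, or a zero
integral are emitted with null scores and a reason code rather than
silently dropped. Arms that reach a chromosome end before the cutoff are
flagged and kept by default (`keep_truncated=False` discards them).

### Site EHH, iES and Rsb

The cross-population ingredient pools both core alleles: with haplotype
class frequencies `f_k` among all `n` haplotypes over the interval,

    h = (n Σ f_k² − 1) / (n − 1),      EHHS(x) = h(core..x) / h(core),

the unbiased homozygosity form. iES is its trapezoidal integral, and per
shared polymorphic SNP

    Rsb = ln(iES_pop1 / iES_pop2),

standardized by subtracting the **median** (robust to the extreme scores
the scan is hunting) and dividing by the ordinary standard deviation, then
mapped through the same −log10 Gaussian-tail transform. Swapping the
populations negates every raw score exactly; the default significance
threshold mirrors the piHS rule (`p_Rsb > 6`) and is a config key.

### Fst and MDS

Per shared SNP, `H_S` is the unweighted mean of the two within-population
expected heterozygosities `2pq` and `H_T = 2 p̄ q̄` with `p̄` the unweighted
mean frequency (populations, not individuals, are the units). The
genome-wide summary is the ratio of sums `(ΣH_T − ΣH_S)/ΣH_T`, which is
stable at low-MAF SNPs; per-SNP values are emitted so either summary is
recoverable. Population structure is visualized by classical
(double-centering + eigendecomposition) MDS on `1 − mean IBS` distances;
only axes with positive eigenvalues are returned, since IBS distances are
not exactly Euclidean-embeddable.

### GRM and mixed-model LOCO association

The VanRaden GRM uses in-sample allele frequencies; monomorphic SNPs are
skipped with a logged count. The association model per SNP is
`y = a + b·x + g + e` with `g ~ N(0, σg² A_loco)`: for SNPs on chromosome
`c` the GRM excludes chromosome `c` and the variance components are
re-estimated by REML for every leave-one-chromosome-out set. With a single
random effect, REML reduces after one eigendecomposition to a 1-D profile
likelihood in the variance ratio, maximized by bounded scalar search on
log10-ratio in [−8, 8] (xatol 1e-8); ratios at the lower bound collapse to
σg² = 0. Negative GRM eigenvalues (numerical) are clipped at zero with a
warning. Per-SNP inference is exact GLS in the rotated basis with a 1-df
Wald chi-square; with σg² = 0 it reduces to OLS exactly (tested). A
single-chromosome panel has an empty leave-out set; the scan then warns
and fits without a polygenic term. Phenotypes are used untransformed (the
intended use is EBVs); raw and Bonferroni-adjusted flags are both
reported because no universal genome-wide threshold exists for this kind
of scan.

Calibration note: LOCO deliberately leaves the candidate chromosome's
polygenic contribution uncontrolled (that is what preserves power). Its
type-I error is therefore evaluated on SNPs of chromosomes that carry no
causal background, with the background on the other half of the genome —
under that design the empirical rate at α = 0.05 is ~0.05 (acceptance
suite). When the background is instead drawn from the full marker GRM,
every tested marker is weakly causal by construction (non-centrality
n·h²/m per SNP) and the rejection rate is legitimately above α; that is
association, not miscalibration.

## Synthetic data generator

The generator produces the statistical structure that a selection-scan
study of a livestock breeding program assumes: two recently diverged
populations of shared ancestry, chip-density markers, one population under
recent directional selection at a focal locus, decade cohorts, and
EBV-like phenotypes.

* **Ancestry.** A neutral coalescent (msprime) generates the shared
  ancestral population of `n_base` diploids at mutation–drift–
  recombination equilibrium. Chip markers are then *ascertained* the way a
  chip is built: segregating sites with MAF ≥ 0.05 thinned evenly to
  `n_snps` per chromosome (mean spacing `spacing_bp`, default 55 kb). The
  mutation rate is set from the expected common-site density
  (`E[#sites with maf > c] ≈ 4 Ne μ L ln((1−c)/c)`) with a 2× margin and
  doubled on the rare shortfall. An earlier pure-drift burn-in design
  (U-shaped initial frequencies plus ~4·Ne generations of forward drift,
  no mutation) was abandoned: without mutation, 4·Ne generations remove
  ~86% of heterozygosity (`(1−1/2N)^t`), leaving too few markers above any
  MAF floor at chip density. The coalescent+ascertainment route gives
  equilibrium LD and full marker density at once; forward time is kept
  exactly where the analysis needs it — the split, selection and decade
  snapshots.
* **Ancestral alleles** are known exactly from the mutation model
  (allele 0 ancestral at every site), so scans on simulated data never
  depend on an external polarization table.
* **Split and selection.** Both daughter populations evolve `g_split`
  generations (default 40) of discrete Wright–Fisher random mating at
  their census sizes (default 1200 diploids each — breeding-program scale,
  which puts split-phase drift Fst in the 0.01–0.02 range), with genotype
  fitnesses 1 : 1+hs : 1+s at the focal locus in the selected population
  during the final `g_sel` generations (default 30, the "30-year program"
  analogue). Emitted panels are samples (defaults 667 and 362 diploids)
  from the final census generations.
* **Recombination** uses at-most-one crossover per adjacent-marker
  interval per meiosis with probability `rho_per_bp × gap` (capped at
  0.5); at 50k-chip spacing the double-crossover correction is
  negligible. Crossovers are placed sparsely (binomial counts per
  interval), making a generation O(populations × markers).
* **Focal locus.** When not pinned by the user, the focal locus models a
  *recent* variant coming under selection — the scenario
  haplotype-extension statistics are designed to detect: among interior
  markers within ±0.1 of the target start frequency (default 0.2), the
  youngest mutation by genealogical age is chosen, so its carriers still
  share an extended haplotype at selection onset. A variant drawn without
  the age condition is typically old (expected age ≈ −4N p ln p/(1−p)
  generations), its carriers sit on thoroughly recombined backgrounds, and
  no detectable footprint forms at realistic s over a few dozen
  generations. Ascertainment guarantees the focal allele segregates at
  the split; a user-pinned monomorphic focal raises an error.
* **Cohorts** map decade labels onto evenly spaced generations across the
  selection phase; each decade's samples are drawn without replacement
  from that generation's snapshot, so later decades come from later
  generations.
* **Phenotypes.** True breeding value = Σ effect × derived-allele dosage
  over `n_qtl` random causal markers (plus the focal effect when
  configured, plus an optional deterministic per-decade gain standing in
  for off-panel polygenic response); the emitted EBV adds Gaussian noise
  scaled so cor(EBV, BV)² equals the configured reliability (default 0.8,
  mimicking high-accuracy progeny-tested EBVs).

Everything is reproducible bit-exactly from (config, seed); all
sub-streams derive from the single config seed.

### What the generator does not emulate

Genotyping error, missingness patterns, pedigree loops and overlapping
generations, migration, sex chromosomes, ascertainment bias between
populations, and selection on multiple correlated traits. Passing tests
on this generator show the statistics behave correctly under their own
model assumptions — not that any particular real dataset would reproduce
a given scan result.

## Problem sizes used by the tests and acceptance script

The simulation-backed checks run at a scaled-down desk size chosen as the
package's own test design: 2,000 markers (~110 Mb at 55 kb spacing),
samples of 200 + 200 diploids from census-1200 populations, 25 replicate
seeds for scan properties, and n = 500 with 20 chromosomes × 100 SNPs for
the mixed-model calibration (≥ 20,000 null SNP tests). The published-table
checks are exact and instantaneous.

## Known limitations

* **Top-1 sweep localization is stochastic at moderate selection.** At
  s = 0.15 for 30 generations the focal allele's frequency gain is capped
  near Δlogit ≈ s·g/2 ≈ 2.25 (additive fitness), and the swept clade
  cannot be younger than its standing phase. The resulting |standardized
  iHS| at the focal region is ~3–4.5, while the expected maximum of ~2,000
  near-Gaussian background scores is already ~3.3–3.8, so the single
  top-scoring SNP falls within 1 Mb of the focal locus in only roughly
  half to two-thirds of replicates under these conditions. Stronger or
  longer selection, or region-level (rather than single-SNP) calling,
  localizes far more reliably.
* The HWE exact test enumerates the full conditional distribution per SNP
  (exact but O(n) per SNP); adequate for chip-scale panels.
* The Rsb scan computes iES per population per SNP independently; no
  sharing of partition refinements between adjacent cores is attempted.
* `classical_mds` forms the full pairwise distance matrix (O(n² m));
  intended for cohort-scale sample counts, not biobanks.
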