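"""Two-population selective-sweep simulator with SNP-chip ascertainment.

The generator emulates the data structure a selection-signature study of a
livestock breeding program assumes: two populations of shared ancestry with
low divergence (Fst on the order of 0.01), SNP-chip marker density (one
marker per ~55 kb), one population under recent directional selection at a
focal derived allele, decade-labelled cohorts drawn from successive
generations, and EBV-like phenotypes whose accuracy (squared correlation
with the true breeding value) is configurable.

Mechanics
---------
* **Ancestry / burn-in.**  A neutral coalescent (msprime) generates the
  shared ancestral population of ``n_base`` diploids at mutation–drift–
  recombination equilibrium, which provides realistic equilibrium LD at
  chip density.  The marker panel is then *ascertained* the way a chip is
  built: segregating sites with MAF >= ``chip_maf`` are thinned to
  ``n_snps`` markers per chromosome (mean spacing ``spacing_bp``).  The
  panel is fixed from here on — no new mutations during the simulated
  decades, as chip markers are a fixed, ascertained set.
* **Ancestral alleles** are known exactly from the mutation model (code 0
  ancestral); every variant is emitted with its ancestral state set.
* **Split and selection.**  The ascertained population is the common pool;
  each daughter population evolves ``g_split`` generations of forward
  Wright–Fisher random mating, the selected one with genotype fitnesses
  1 : 1+hs : 1+s at the focal locus during the final ``g_sel`` generations.
  Forward time makes decade snapshots of the continuing selected
  population direct.
* **Recombination**: at most one crossover per adjacent-marker interval
  per meiosis, probability ``rho_per_bp * gap`` — adequate thinning at
  50k-chip inter-marker distances.

Everything is reproducible bit-exactly from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, make_variant_table

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# Configuration
# --------------------------------------------------------------------------- #
@dataclass
class TraitModel:
    """Additive genetic architecture of one EBV-like trait.

    ``n_qtl`` markers act as causal loci with N(0, ``effect_sd``) effects;
    the focal sweep locus is added with effect ``focal_effect`` when
    non-zero.  ``reliability`` is the squared correlation between the
    emitted EBV and the true breeding value (0.8 mimics high-accuracy
    progeny-tested EBVs).  ``decade_gain`` adds a deterministic per-decade
    increment to the true breeding value, modelling polygenic gain carried
    by loci off the marker panel.
    """

    name: str
    n_qtl: int = 20
    effect_sd: float = 1.0
    focal_effect: float = 0.0
    reliability: float = 0.8
    decade_gain: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.reliability <= 1.0):
            raise ValueError(
                f"trait {self.name!r}: reliability must be in (0, 1], "
                f"got {self.reliability}"
            )
        if self.n_qtl < 0:
            raise ValueError(f"trait {self.name!r}: n_qtl must be >= 0")


@dataclass
class SweepSimConfig:
    """All parameters of the two-population sweep simulation.

    Defaults mirror the study design the generator emulates: sampled panels
    of 667 selected and 362 unselected diploids, ~55 kb marker spacing, a
    ~40-generation window since shared ancestry with selection in the last
    30 (a 30-year program plus early shared ancestry), breeding-population
    census sizes of 1200 diploids (giving split-phase drift Fst on the
    order of 0.01-0.02) and an ancestral effective size of 400 diploids,
    in the range reported for taurine cattle breeds.
    """

    n_base: int = 400
    n_sel: int = 667
    n_unsel: int = 362
    #: census sizes during the split phase; emitted panels sample n_sel /
    #: n_unsel diploids from them (None: census = sample size)
    n_census_sel: int | None = 1200
    n_census_unsel: int | None = 1200
    n_snps: int = 2000
    n_chrom: int = 1
    spacing_bp: float = 55_000.0
    rho_per_bp: float = 1e-8
    s: float = 0.0
    h: float = 0.5
    focal_index: int | None = None
    focal_start_freq: float = 0.1
    chip_maf: float = 0.05
    g_split: int = 40
    g_sel: int = 30
    #: extra neutral forward generations between ascertainment and the split
    g_burn: int = 0
    seed: int = 0
    cohort_decades: dict[int, int] | None = None
    trait_models: list[TraitModel] = field(default_factory=list)

    def validate(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient s must be >= 0")
        if not (0.0 < self.h <= 1.0):
            raise ValueError("dominance h must be in (0, 1]")
        if min(self.n_base, self.n_sel, self.n_unsel, self.n_snps, self.n_chrom) < 1:
            raise ValueError("population sizes, n_snps and n_chrom must be positive")
        if self.census_sel < self.n_sel or self.census_unsel < self.n_unsel:
            raise ValueError("census sizes cannot be smaller than sample sizes")
        if self.g_sel > self.g_split:
            raise ValueError("g_sel cannot exceed g_split")
        if self.g_burn < 0:
            raise ValueError("g_burn must be >= 0")
        if not (0.0 <= self.chip_maf < 0.5):
            raise ValueError("chip_maf must be in [0, 0.5)")
        if self.focal_index is not None and not (
            0 <= self.focal_index < self.n_snps * self.n_chrom
        ):
            raise ValueError("focal_index out of marker range")
        if self.cohort_decades is not None:
            if any(v < 1 for v in self.cohort_decades.values()):
                raise ValueError("cohort sample counts must be positive")
        for t in self.trait_models:
            t.validate()

    @property
    def census_sel(self) -> int:
        return self.n_sel if self.n_census_sel is None else self.n_census_sel

    @property
    def census_unsel(self) -> int:
        return self.n_unsel if self.n_census_unsel is None else self.n_census_unsel

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SweepSimConfig":
        d = dict(d)
        traits = [
            t if isinstance(t, TraitModel) else TraitModel(**t)
            for t in d.pop("trait_models", [])
        ]
        if d.get("cohort_decades") is not None:
            d["cohort_decades"] = {
                int(k): int(v) for k, v in d["cohort_decades"].items()
            }
        return cls(trait_models=traits, **d)


# --------------------------------------------------------------------------- #
# Truth record and output container
# --------------------------------------------------------------------------- #
@dataclass
class SimTruth:
    """Ground truth of one simulation run, for validation and oracles."""

    focal_index: int
    focal_id: str
    s: float
    h: float
    #: derived-allele frequency of the focal locus in the selected
    #: population, one entry per generation from the split (index 0) on
    focal_traj_sel: list[float]
    focal_traj_unsel: list[float]
    #: allele_b frequencies of the emitted selected panel (exact column means)
    final_freq_sel: np.ndarray | None = None
    final_freq_unsel: np.ndarray | None = None
    #: distinct haplotypes of the common pool at the split (the founders of
    #: both daughter populations)
    founder_haplotypes: np.ndarray | None = None
    #: decade label -> focal derived-allele frequency in that cohort
    focal_freq_by_decade: dict[int, float] = field(default_factory=dict)
    #: trait -> true breeding values of the selected panel's samples
    true_bv: dict[str, np.ndarray] = field(default_factory=dict)
    #: trait -> (causal marker indices, effects)
    qtl: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


@dataclass
class SimOutput:
    """Result of :func:`simulate`: two phased panels plus the truth record."""

    panel_sel: HaplotypePanel
    panel_unsel: HaplotypePanel
    truth: SimTruth
    config: SweepSimConfig
    #: decade label -> (generation index, haplotype matrix snapshot) of the
    #: selected population, for cohort assembly
    snapshots: dict[int, tuple[int, np.ndarray]] = field(default_factory=dict)


# --------------------------------------------------------------------------- #
# Coalescent ancestry with chip ascertainment
# --------------------------------------------------------------------------- #
def _ascertained_chromosome(
    config: SweepSimConfig, seed_pair: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One chromosome of the ancestral pool: (positions_bp, haplotypes, ages).

    Simulates neutral equilibrium ancestry for ``n_base`` diploids, drops
    mutations (binary model; allele 0 is ancestral by construction), then
    ascertains the chip: segregating sites with MAF >= ``chip_maf`` thinned
    evenly to ``n_snps`` markers.  The mutation rate is set so the expected
    number of common sites is about twice the target; if ascertainment
    still comes up short the rate is doubled and the chromosome redrawn.
    """
    import msprime

    length = int(config.n_snps * config.spacing_bp)
    # E[# sites with maf in (c, 1-c)] ~= 4 Ne mu L ln((1-c)/c); aim for 2x
    c = max(config.chip_maf, 1.0 / (4 * config.n_base))
    mu = 2.0 * config.n_snps / (
        4.0 * config.n_base * length * np.log((1 - c) / c)
    )
    anc_seed, mut_seed = seed_pair
    for attempt in range(4):
        ts = msprime.sim_ancestry(
            samples=config.n_base,
            population_size=config.n_base,
            sequence_length=length,
            recombination_rate=config.rho_per_bp,
            random_seed=anc_seed,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed + attempt,
        )
        geno = mts.genotype_matrix().T.astype(np.int8)  # (2n, sites)
        positions = np.array([int(s.position) for s in mts.sites()], dtype=np.int64)
        # age (generations) of each site's variant = time of its oldest mutation
        ages = np.zeros(len(positions))
        for site in mts.sites():
            ages[site.id] = max(mut.time for mut in site.mutations)
        freq = geno.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        ok = maf >= config.chip_maf
        if ok.sum() >= config.n_snps:
            idx = np.flatnonzero(ok)
            take = np.unique(
                np.round(np.linspace(0, len(idx) - 1, config.n_snps)).astype(int)
            )
            idx = idx[take]
            return positions[idx] + 1, geno[:, idx], ages[idx]
        logger.warning(
            "chip ascertainment found %d/%d common sites; doubling mutation rate",
            int(ok.sum()), config.n_snps,
        )
        mu *= 2.0
    raise RuntimeError("chip ascertainment failed to reach the target marker count")


def _build_pool(config: SweepSimConfig, rng: np.random.Generator):
    """Ancestral pool over all chromosomes:
    (chrom labels, positions, haplo, variant ages)."""
    chroms, positions, blocks, age_blocks = [], [], [], []
    for chrom_i in range(config.n_chrom):
        seeds = (int(rng.integers(1, 2**31)), int(rng.integers(1, 2**31)))
        pos, hap, ages = _ascertained_chromosome(config, seeds)
        chroms.extend([str(chrom_i + 1)] * len(pos))
        positions.extend(pos.tolist())
        blocks.append(hap)
        age_blocks.append(ages)
    return (
        np.asarray(chroms),
        np.asarray(positions, dtype=np.int64),
        np.hstack(blocks),
        np.concatenate(age_blocks),
    )


# --------------------------------------------------------------------------- #
# Forward Wright–Fisher machinery
# --------------------------------------------------------------------------- #
def _interval_probs(chroms: np.ndarray, positions: np.ndarray, rho: float) -> np.ndarray:
    """Per-interval crossover probability; 0.5 between chromosomes (free)."""
    if len(positions) < 2:
        return np.zeros(0)
    gaps = np.diff(positions).astype(float)
    p = np.minimum(0.5, rho * np.abs(gaps))
    p[chroms[1:] != chroms[:-1]] = 0.5
    return p


def _wf_generation(
    pop: np.ndarray,
    n_offspring: int,
    interval_p: np.ndarray,
    rng: np.random.Generator,
    fitness: np.ndarray | None = None,
) -> np.ndarray:
    """One generation of random mating with recombination.

    ``pop`` is (2N, m); returns (2 * n_offspring, m).  Each gamete picks a
    diploid parent (fitness-weighted when ``fitness`` is given) and
    recombines the parent's two haplotypes with per-interval crossover
    probabilities ``interval_p``.
    """
    n_parents = pop.shape[0] // 2
    m = pop.shape[1]
    n_gam = 2 * n_offspring
    if fitness is None:
        parents = rng.integers(0, n_parents, size=n_gam)
    else:
        parents = rng.choice(n_parents, size=n_gam, p=fitness / fitness.sum())

    h0 = pop[2 * parents]
    h1 = pop[2 * parents + 1]
    start = rng.integers(0, 2, size=n_gam, dtype=np.int8)
    if m == 1 or len(interval_p) == 0 or interval_p.max() <= 0:
        phase = np.broadcast_to(start[:, None], (n_gam, m))
        return np.where(phase == 0, h0, h1)

    # sparse crossover placement: per interval, the number of gametes hit is
    # Binomial(n_gam, p_i); hits land on distinct gametes
    flips = np.zeros((n_gam, m), dtype=np.int8)
    hit_counts = rng.binomial(n_gam, interval_p)
    for i in np.flatnonzero(hit_counts):
        gam = rng.choice(n_gam, size=hit_counts[i], replace=False)
        flips[gam, i + 1] ^= 1  # interval i flips phase from marker i+1 on
    phase = (np.cumsum(flips, axis=1, dtype=np.int8) + start[:, None]) & 1
    return np.where(phase == 0, h0, h1)


def _focal_fitness(
    pop: np.ndarray, focal: int, derived_allele: int, s: float, h: float
) -> np.ndarray:
    dosage = (pop[0::2, focal] == derived_allele).astype(np.int8) + (
        pop[1::2, focal] == derived_allele
    ).astype(np.int8)
    w = np.ones(len(dosage))
    w[dosage == 1] = 1.0 + h * s
    w[dosage == 2] = 1.0 + s
    return w


# --------------------------------------------------------------------------- #
# Main entry points
# --------------------------------------------------------------------------- #
def simulate(config: SweepSimConfig) -> SimOutput:
    """Run the ancestry / split / selection simulation.

    Returns phased panels for the selected and unselected populations with
    ancestral states set by construction, plus the truth record.  When
    ``focal_index`` is None, the focal locus models a *recent* variant
    coming under selection — the scenario haplotype-extension statistics
    are designed to detect: among interior markers whose derived-allele
    frequency lies within 0.1 of ``focal_start_freq``, the youngest
    mutation (by genealogical age) is chosen, so its carriers still share
    an extended haplotype when selection starts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms, positions, pool, ages = _build_pool(config, rng)
    m = pool.shape[1]
    interval_p = _interval_probs(chroms, positions, config.rho_per_bp)

    # allele 0 is ancestral by construction; allele codes: 0 -> 'A', 1 -> 'G'
    ancestral = np.array(["a"] * m)

    for _ in range(config.g_burn):
        pool = _wf_generation(pool, config.n_base, interval_p, rng)

    founders = np.unique(pool, axis=0)
    derived_freq_pool = pool.mean(axis=0)

    if config.focal_index is None:
        segregating = (derived_freq_pool > 0) & (derived_freq_pool < 1)
        if not segregating.any():
            raise RuntimeError("no segregating marker available as focal locus")
        third = m // 3
        interior = np.zeros(m, dtype=bool)
        interior[third : m - third] = True
        if not (segregating & interior).any():
            interior[:] = True
        near = (
            segregating
            & interior
            & (np.abs(derived_freq_pool - config.focal_start_freq) <= 0.1)
        )
        if near.any():
            # youngest variant near the target frequency: a recently
            # expanded clade whose carriers still share a long haplotype
            cost = np.where(near, ages, np.inf)
        else:
            cost = np.abs(derived_freq_pool - config.focal_start_freq)
            cost[~(segregating & interior)] = np.inf
        focal = int(np.argmin(cost))
    else:
        focal = int(config.focal_index)
        if not (0 < derived_freq_pool[focal] < 1):
            raise RuntimeError(
                f"focal marker {focal} is monomorphic in the ancestral pool"
            )

    # decade -> generation schedule over the selection phase
    decade_gen: dict[int, int] = {}
    if config.cohort_decades:
        decades = sorted(config.cohort_decades)
        g_start = config.g_split - config.g_sel
        if len(decades) == 1:
            decade_gen[decades[0]] = max(config.g_split, 1)
        else:
            for i, dec in enumerate(decades):
                decade_gen[dec] = max(
                    1, g_start + round(i * config.g_sel / (len(decades) - 1))
                )

    # split and evolve
    snapshots: dict[int, tuple[int, np.ndarray]] = {}
    traj_sel = [float(derived_freq_pool[focal])]
    traj_unsel = [float(derived_freq_pool[focal])]
    pop_sel = pool
    pop_unsel = pool
    n_gen = max(config.g_split, 1)  # g_split = 0 still needs one draw per panel
    sel_start = config.g_split - config.g_sel
    for g in range(1, n_gen + 1):
        selecting = config.s > 0 and sel_start < g <= config.g_split
        fitness = (
            _focal_fitness(pop_sel, focal, 1, config.s, config.h)
            if selecting
            else None
        )
        pop_sel = _wf_generation(pop_sel, config.census_sel, interval_p, rng, fitness)
        pop_unsel = _wf_generation(pop_unsel, config.census_unsel, interval_p, rng)
        traj_sel.append(float(pop_sel[:, focal].mean()))
        traj_unsel.append(float(pop_unsel[:, focal].mean()))
        for dec, gg in decade_gen.items():
            if gg == g and dec not in snapshots:
                snapshots[dec] = (g, pop_sel.copy())
    for dec in decade_gen:  # safety net for schedules beyond the run
        if dec not in snapshots:
            snapshots[dec] = (n_gen, pop_sel.copy())

    variants = make_variant_table(
        chroms,
        positions,
        [f"snp{j:05d}" for j in range(m)],
        ["A"] * m,
        ["G"] * m,
        ancestral,
    )

    def build_panel(p: np.ndarray, n_sample: int, label: str) -> HaplotypePanel:
        n_avail = p.shape[0] // 2
        if n_sample < n_avail:
            chosen = np.sort(rng.choice(n_avail, size=n_sample, replace=False))
            idx = np.empty(2 * n_sample, dtype=np.int64)
            idx[0::2] = 2 * chosen
            idx[1::2] = 2 * chosen + 1
            p = p[idx]
        n = p.shape[0] // 2
        samples = pd.DataFrame(
            {
                "sample_id": [f"{label}_{i:04d}" for i in range(n)],
                "population": [label] * n,
            }
        )
        return HaplotypePanel(
            variants=variants.copy(), haplo=p, samples=samples, phased=True
        )

    panel_sel = build_panel(pop_sel, config.n_sel, "selected")
    panel_unsel = build_panel(pop_unsel, config.n_unsel, "unselected")
    truth = SimTruth(
        focal_index=focal,
        focal_id=str(variants["id"].iloc[focal]),
        s=config.s,
        h=config.h,
        focal_traj_sel=traj_sel,
        focal_traj_unsel=traj_unsel,
        final_freq_sel=panel_sel.freq_b(),
        final_freq_unsel=panel_unsel.freq_b(),
        founder_haplotypes=founders,
    )
    out = SimOutput(
        panel_sel=panel_sel,
        panel_unsel=panel_unsel,
        truth=truth,
        config=config,
        snapshots=snapshots,
    )
    if config.cohort_decades:
        out = assign_cohorts(out, config.cohort_decades, seed=int(rng.integers(2**31)))
    if config.trait_models:
        out = simulate_ebv(out, config.trait_models, seed=int(rng.integers(2**31)))
    return out


def assign_cohorts(
    sim_output: SimOutput,
    cohort_decades: dict[int, int],
    seed: int,
) -> SimOutput:
    """Assemble the selected panel from decade cohorts.

    Each decade's samples are drawn without replacement from the generation
    snapshot assigned to that decade (later decades come from later
    generations); ``cohort_decade`` is set on the resulting samples.
    Requesting more samples than a snapshot holds raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    pieces_hap = []
    pieces_meta = []
    for dec in sorted(cohort_decades):
        count = cohort_decades[dec]
        if dec not in sim_output.snapshots:
            raise ValueError(f"no generation snapshot stored for decade {dec}")
        gen, snap = sim_output.snapshots[dec]
        n_avail = snap.shape[0] // 2
        if count > n_avail:
            raise ValueError(
                f"decade {dec}: requested {count} samples but only {n_avail} simulated"
            )
        chosen = np.sort(rng.choice(n_avail, size=count, replace=False))
        rows = np.empty(2 * count, dtype=np.int64)
        rows[0::2] = 2 * chosen
        rows[1::2] = 2 * chosen + 1
        pieces_hap.append(snap[rows])
        pieces_meta.append(
            pd.DataFrame(
                {
                    "sample_id": [f"selected_g{gen:03d}_{i:04d}" for i in chosen],
                    "population": "selected",
                    "cohort_decade": dec,
                }
            )
        )
    haplo = np.vstack(pieces_hap)
    samples = pd.concat(pieces_meta, ignore_index=True)
    panel = HaplotypePanel(
        variants=sim_output.panel_sel.variants.copy(),
        haplo=haplo,
        samples=samples,
        phased=True,
    )
    focal = sim_output.truth.focal_index
    by_decade = {
        dec: float(
            panel.take_samples(
                (panel.samples["cohort_decade"] == dec).to_numpy()
            ).haplo[:, focal].mean()
        )
        for dec in sorted(cohort_decades)
    }
    truth = dataclasses.replace(
        sim_output.truth,
        focal_freq_by_decade=by_decade,
        final_freq_sel=panel.freq_b(),
    )
    return SimOutput(
        panel_sel=panel,
        panel_unsel=sim_output.panel_unsel,
        truth=truth,
        config=sim_output.config,
        snapshots=sim_output.snapshots,
    )


def simulate_ebv(
    sim_output: SimOutput,
    trait_models: Sequence[TraitModel] | TraitModel,
    seed: int,
) -> SimOutput:
    """Attach EBV-like phenotypes to the selected panel.

    Per trait: ``n_qtl`` causal markers get N(0, effect_sd) effects (the
    focal locus is added with ``focal_effect`` when non-zero); the true
    breeding value is the effect-weighted derived-allele dosage plus any
    per-decade gain; the EBV adds Gaussian noise scaled so that
    cor(EBV, BV)^2 equals ``reliability``.
    """
    if isinstance(trait_models, TraitModel):
        trait_models = [trait_models]
    rng = np.random.default_rng(seed)
    panel = sim_output.panel_sel.copy()
    truth = sim_output.truth
    derived_code = panel.derived_code()
    known = derived_code >= 0
    dos_b = panel.dosage()
    dosage = np.where(derived_code == 1, dos_b, 2 - dos_b)
    dosage[:, ~known] = 0

    decade_index = np.zeros(panel.n_samples)
    if "cohort_decade" in panel.samples.columns:
        decs = sorted(panel.samples["cohort_decade"].dropna().unique())
        lookup = {d: i for i, d in enumerate(decs)}
        decade_index = (
            panel.samples["cohort_decade"].map(lookup).fillna(0).to_numpy(dtype=float)
        )

    true_bv = dict(truth.true_bv)
    qtl_record = dict(truth.qtl)
    for tm in trait_models:
        tm.validate()
        candidates = np.flatnonzero(known)
        n_qtl = min(tm.n_qtl, len(candidates))
        qtl = (
            rng.choice(candidates, size=n_qtl, replace=False)
            if n_qtl
            else np.array([], dtype=int)
        )
        effects = rng.normal(0.0, tm.effect_sd, size=len(qtl))
        if tm.focal_effect != 0.0:
            if truth.focal_index not in qtl:
                qtl = np.append(qtl, truth.focal_index)
                effects = np.append(effects, 0.0)
            effects[qtl == truth.focal_index] = tm.focal_effect
        bv = dosage[:, qtl] @ effects if len(qtl) else np.zeros(panel.n_samples)
        bv = bv + tm.decade_gain * decade_index
        var_bv = float(np.var(bv))
        if tm.reliability >= 1.0:
            ebv = bv.copy()
        else:
            noise_sd = (
                np.sqrt(var_bv * (1.0 - tm.reliability) / tm.reliability)
                if var_bv > 0
                else 1.0
            )
            ebv = bv + rng.normal(0.0, noise_sd, size=len(bv))
        panel.samples[tm.name] = ebv
        true_bv[tm.name] = bv
        qtl_record[tm.name] = (qtl, effects)

    truth = dataclasses.replace(truth, true_bv=true_bv, qtl=qtl_record)
    return SimOutput(
        panel_sel=panel,
        panel_unsel=sim_output.panel_unsel,
        truth=truth,
        config=sim_output.config,
        snapshots=sim_output.snapshots,
    )
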