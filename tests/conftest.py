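"""Shared fixtures: tiny hand-built panels and small simulated datasets."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from sweepscan import HaplotypePanel, SweepSimConfig, make_variant_table, simulate

DATA_DIR = Path(__file__).parent / "data"


def build_panel(
    haplo,
    positions=None,
    chrom="1",
    ancestral=None,
    phased=True,
    populations=None,
    sample_prefix="s",
):
    """Construct a small panel from a literal haplotype matrix."""
    haplo = np.asarray(haplo, dtype=np.int8)
    m = haplo.shape[1]
    n = haplo.shape[0] // 2
    if positions is None:
        positions = (np.arange(m) + 1) * 1000
    if ancestral is None:
        ancestral = ["a"] * m
    if isinstance(chrom, str):
        chrom = [chrom] * m
    variants = make_variant_table(
        chrom, positions, [f"m{j}" for j in range(m)], ["A"] * m, ["G"] * m, ancestral
    )
    if populations is None:
        populations = ["pop1"] * n
    samples = pd.DataFrame(
        {"sample_id": [f"{sample_prefix}{i}" for i in range(n)], "population": populations}
    )
    return HaplotypePanel(variants=variants, haplo=haplo, samples=samples, phased=phased)


@pytest.fixture(scope="session")
def reported_scores() -> pd.DataFrame:
    """Published genome-scan summary: 37 significant iHS SNPs with piHS."""
    return pd.read_csv(DATA_DIR / "ihs_reported_scores.tsv", sep="\t", dtype={"chrom": str})


@pytest.fixture(scope="session")
def small_sweep():
    """One small sweep simulation shared across tests (seeded)."""
    cfg = SweepSimConfig(
        n_base=150,
        n_sel=80,
        n_unsel=60,
        n_census_sel=300,
        n_census_unsel=300,
        n_snps=300,
        s=0.3,
        g_split=30,
        g_sel=25,
        seed=11,
        focal_start_freq=0.2,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_neutral():
    """Matching neutral (s = 0) simulation."""
    cfg = SweepSimConfig(
        n_base=150,
        n_sel=80,
        n_unsel=60,
        n_census_sel=300,
        n_census_unsel=300,
        n_snps=300,
        s=0.0,
        g_split=30,
        g_sel=25,
        seed=12,
    )
    return simulate(cfg)
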