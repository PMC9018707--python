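"""I/O round trips, ancestral annotation and QC filtering."""

import math

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    PanelError,
    attach_ancestral,
    hwe_exact_test,
    qc_filter,
    read_ped_map,
    read_phased_table,
    write_phased_table,
)
from sweepscan.genotype_io import ParseError, write_ped_map

from conftest import build_panel


# --------------------------------------------------------------------------- #
# Hardy–Weinberg exact test vs enumeration oracle
# --------------------------------------------------------------------------- #
def hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Brute-force exact HWE p: enumerate every heterozygote count with the
    observed allele counts, weight by the conditional (hypergeometric-type)
    probability, and sum outcomes no more likely than the observed one."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    probs = {}
    for h in range(min(na, nb) + 1):
        if (na - h) % 2:
            continue
        ha = (na - h) // 2
        hb = (nb - h) // 2
        if ha < 0 or hb < 0:
            continue
        logp = (
            math.lgamma(n + 1)
            - math.lgamma(ha + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hb + 1)
            + h * math.log(2)
            + math.lgamma(na + 1)
            + math.lgamma(nb + 1)
            - math.lgamma(2 * n + 1)
        )
        probs[h] = math.exp(logp)
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


@pytest.mark.parametrize(
    "counts",
    [
        (25, 50, 25),
        (0, 100, 0),
        (57, 14, 50),
        (0, 1, 99),
        (10, 0, 10),
        (3, 5, 192),
        (1, 0, 0),
        (40, 20, 40),
    ],
)
def test_hwe_matches_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-10)


def test_hwe_random_cases_match_oracle():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(1, 200))
        p = rng.random()
        g = rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])
        assert hwe_exact_test(*g) == pytest.approx(hwe_oracle(*g), abs=1e-10)


def test_hwe_perfect_equilibrium_retained_and_excess_het_removed():
    assert hwe_exact_test(25, 50, 25) > 0.5  # exact p ~ 1 at HWE proportions
    assert hwe_exact_test(0, 100, 0) < 1e-4  # all-het grossly out of HWE


# --------------------------------------------------------------------------- #
# PED/MAP
# --------------------------------------------------------------------------- #
def write_toy_ped_map(tmp_path, ped_rows, map_rows):
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    ped.write_text("\n".join(ped_rows) + "\n")
    mp.write_text("\n".join(map_rows) + "\n")
    return ped, mp


def test_read_ped_map_roundtrip(tmp_path):
    ped, mp = write_toy_ped_map(
        tmp_path,
        [
            "fam1 ind1 0 0 1 -9 A A A G G G",
            "fam1 ind2 0 0 2 -9 A G G G 0 0",
        ],
        ["1 snp1 0 100", "1 snp2 0 200", "1 snp3 0 300"],
    )
    panel = read_ped_map(ped, mp)
    assert panel.n_haplotypes == 4 and panel.n_variants == 3
    assert not panel.phased
    # "0 0" is a missing entry, not an allele
    assert panel.haplo[2, 2] == -1 and panel.haplo[3, 2] == -1
    assert list(panel.variants["id"]) == ["snp1", "snp2", "snp3"]
    # write + read back preserves genotypes
    ped2, mp2 = tmp_path / "rt.ped", tmp_path / "rt.map"
    write_ped_map(panel, ped2, mp2)
    again = read_ped_map(ped2, mp2)
    assert np.array_equal(np.sort(again.haplo, axis=0), np.sort(panel.haplo, axis=0))


def test_read_map_rejects_unsorted_positions(tmp_path):
    ped, mp = write_toy_ped_map(
        tmp_path, ["f i 0 0 0 -9 A A G G"], ["1 snp1 0 200", "1 snp2 0 100"]
    )
    with pytest.raises(ParseError, match="not strictly increasing"):
        read_ped_map(ped, mp)


def test_read_ped_rejects_wrong_field_count(tmp_path):
    ped, mp = write_toy_ped_map(
        tmp_path, ["f i 0 0 0 -9 A A G"], ["1 snp1 0 100", "1 snp2 0 200"]
    )
    with pytest.raises(ParseError, match="line 1"):
        read_ped_map(ped, mp)


def test_duplicate_marker_id_rejected(tmp_path):
    ped, mp = write_toy_ped_map(
        tmp_path, ["f i 0 0 0 -9 A A G G"], ["1 snp1 0 100", "1 snp1 0 200"]
    )
    with pytest.raises(ParseError, match="duplicate"):
        read_ped_map(ped, mp)


# --------------------------------------------------------------------------- #
# Phased TSV trio
# --------------------------------------------------------------------------- #
def test_phased_table_roundtrip_bit_exact(tmp_path, small_sweep):
    panel = small_sweep.panel_sel
    write_phased_table(panel, tmp_path / "p")
    again = read_phased_table(tmp_path / "p")
    assert again.equals(panel)


def test_phased_table_rejects_odd_row_count(tmp_path):
    panel = build_panel([[0, 1], [1, 0]])
    write_phased_table(panel, tmp_path / "p")
    ht = (tmp_path / "p.haplo.tsv").read_text().splitlines()
    (tmp_path / "p.haplo.tsv").write_text("\n".join(ht + [ht[-1].replace("\t1\t", "\t2\t")]) + "\n")
    with pytest.raises(ParseError, match="exactly two haplotype rows"):
        read_phased_table(tmp_path / "p")


def test_phased_table_rejects_stray_allele(tmp_path):
    panel = build_panel([[0, 1], [1, 0]])
    write_phased_table(panel, tmp_path / "p")
    txt = (tmp_path / "p.haplo.tsv").read_text().replace("A", "T")
    (tmp_path / "p.haplo.tsv").write_text(txt)
    with pytest.raises(ParseError, match="not in"):
        read_phased_table(tmp_path / "p")


def test_phased_vcf_roundtrip(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0|1\n"
    )
    from sweepscan import read_phased_vcf

    panel = read_phased_vcf(vcf)
    assert panel.phased and panel.n_variants == 1
    assert list(panel.haplo[:, 0]) == [0, 1]


def test_phased_vcf_rejects_unphased(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1,length=1000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/1\n"
    )
    from sweepscan import read_phased_vcf

    with pytest.raises(ParseError, match="unphased"):
        read_phased_vcf(vcf)


# --------------------------------------------------------------------------- #
# Ancestral annotation
# --------------------------------------------------------------------------- #
def test_attach_ancestral_sets_states_and_flags_unknowns(tmp_path, caplog):
    panel = build_panel([[0, 1, 0], [1, 0, 0]], ancestral=[None, None, None])
    table = tmp_path / "anc.tsv"
    # m0: ancestral G (allele_b); m1 absent; m2 contradictory nucleotide
    table.write_text("marker_id\tancestral_allele\nm0\tG\nm2\tC\n")
    out = attach_ancestral(panel, table)
    assert out.variants["ancestral"].tolist()[0] == "b"
    assert out.variants["ancestral"].isna().tolist()[1:] == [True, True]
    # derived allele of m0 is A (allele_a -> code 0)
    assert out.derived_code()[0] == 0


# --------------------------------------------------------------------------- #
# QC filter
# --------------------------------------------------------------------------- #
def hwe_ok_panel():
    """60 samples, 4 SNPs: HWE-balanced, all-het, low-MAF, normal."""
    rng = np.random.default_rng(5)
    n = 60
    dosages = np.empty((n, 4), dtype=int)
    dosages[:, 0] = rng.permutation([0] * 15 + [1] * 30 + [2] * 15)
    dosages[:, 1] = 1  # every sample heterozygous: HWE failure
    dosages[:, 2] = [1] + [0] * (n - 1)  # MAF = 1/120 < 0.01
    dosages[:, 3] = rng.binomial(2, 0.4, size=n)
    haplo = np.zeros((2 * n, 4), dtype=np.int8)
    haplo[0::2] = (dosages >= 1).astype(np.int8)
    haplo[1::2] = (dosages == 2).astype(np.int8)
    return build_panel(haplo, phased=True)


def test_qc_filter_reason_accounting_and_idempotence():
    panel = hwe_ok_panel()
    out, report = qc_filter(panel)
    assert report.n_input_snps == 4
    assert report.removed_snps["hwe"] == 1
    assert report.removed_snps["maf"] == 1
    assert report.n_kept_snps + sum(report.removed_snps.values()) == report.n_input_snps
    assert set(out.variants["id"]) == {"m0", "m3"}
    again, report2 = qc_filter(out)
    assert again.equals(out)
    assert sum(report2.removed_snps.values()) == 0


def test_qc_filter_call_rate_and_sample_missingness():
    haplo = np.array(
        [[0, 0], [1, -1], [0, 0], [1, 1], [0, 0], [1, 1], [0, 0], [0, 1]], dtype=np.int8
    )
    # sample 0 misses SNP 1 (50% individual missingness) -> dropped first
    panel = build_panel(haplo, phased=False)
    out, report = qc_filter(panel, min_maf=0.0, max_missing=0.4)
    assert report.n_kept_samples == 3
    assert report.removed_snps["call_rate"] == 0


def test_qc_filter_errors_when_nothing_survives():
    panel = build_panel([[1, 1], [1, 1], [1, 1], [1, 1]], phased=False)  # monomorphic
    with pytest.raises(PanelError, match="no SNPs survive"):
        qc_filter(panel, min_maf=0.01)
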