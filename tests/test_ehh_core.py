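"""EHH decay, iHH integration, iHS scan, piHS transform, bifurcation trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    bifurcation_tree,
    call_significant,
    compute_ehh,
    integrate_ihh,
    pihs_transform,
    scan_ihs,
)
from sweepscan.ehh_core import EHHError, EHHProfile

from conftest import build_panel


# --------------------------------------------------------------------------- #
# Brute-force oracle: pairwise interval identity
# --------------------------------------------------------------------------- #
def ehh_oracle(haplo, rows, core, target):
    """EHH at ``target`` for carriers ``rows``: fraction of carrier pairs
    identical at every marker between core and target (inclusive)."""
    lo, hi = min(core, target), max(core, target)
    pairs = list(itertools.combinations(rows, 2))
    if not pairs:
        return float("nan")
    same = sum(
        1 for a, b in pairs if np.array_equal(haplo[a, lo : hi + 1], haplo[b, lo : hi + 1])
    )
    return same / len(pairs)


def profile_to_map(profile: EHHProfile):
    out = {}
    for pos, ehh in zip(profile.left_pos, profile.left_ehh):
        out[int(pos)] = ehh
    for pos, ehh in zip(profile.right_pos, profile.right_ehh):
        out[int(pos)] = ehh
    return out


def test_ehh_matches_pair_enumeration_oracle_on_random_panels():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n_hap = int(rng.integers(4, 31)) // 2 * 2
        m = int(rng.integers(4, 21))
        haplo = rng.integers(0, 2, size=(n_hap, m)).astype(np.int8)
        panel = build_panel(haplo)
        core = int(rng.integers(0, m))
        for allele in (0, 1):
            rows = np.flatnonzero(haplo[:, core] == allele)
            if len(rows) < 2:
                continue
            prof = compute_ehh(panel, core, allele, cutoff=0.0)
            got = profile_to_map(prof)
            pos = panel.variants["pos_bp"].to_numpy()
            for target in range(m):
                expected = ehh_oracle(haplo, rows, core, target)
                assert got[int(pos[target])] == pytest.approx(expected, abs=1e-12)


def test_ehh_monotone_and_bounded(small_sweep):
    panel = small_sweep.panel_sel
    rng = np.random.default_rng(1)
    for core in rng.integers(0, panel.n_variants, size=12):
        for allele in (0, 1):
            if (panel.haplo[:, core] == allele).sum() < 2:
                continue
            prof = compute_ehh(panel, int(core), allele)
            for arm in (prof.left_ehh, prof.right_ehh):
                assert arm[0] == 1.0
                assert np.all(np.diff(arm) <= 1e-12)
                assert np.all((arm >= 0) & (arm <= 1))


def test_ehh_identical_carriers_stay_at_one():
    # all carriers of allele 1 share one haplotype across the chromosome
    haplo = np.array(
        [[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 0, 0]], dtype=np.int8
    )
    panel = build_panel(haplo)
    prof = compute_ehh(panel, 0, 1)
    assert np.all(prof.right_ehh == 1.0)
    assert prof.stop_right == "chrom_end" and prof.stop_left == "chrom_end"


def test_ehh_four_carriers_two_identical_pairs_gives_one_third():
    # 4 carriers of allele 1 at the core; at the next marker they split into
    # two identical pairs: 2 homozygous pairs of C(4,2)=6 -> EHH = 1/3
    haplo = np.array(
        [[1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1]], dtype=np.int8
    )
    panel = build_panel(haplo)
    prof = compute_ehh(panel, 0, 1, cutoff=0.0)
    assert prof.right_ehh[1] == pytest.approx(1 / 3, abs=1e-15)


def test_ehh_all_distinct_truncates_immediately():
    haplo = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]], dtype=np.int8)
    panel = build_panel(haplo)
    prof = compute_ehh(panel, 0, 1, cutoff=0.05)
    assert prof.right_ehh[-1] == 0.0
    assert prof.stop_right == "cutoff"


def test_ehh_few_carriers_raises():
    panel = build_panel([[1, 0], [0, 0], [0, 1], [0, 0]])
    with pytest.raises(EHHError, match="carrier"):
        compute_ehh(panel, 0, 1)


def test_ehh_refuses_unphased():
    panel = build_panel([[1, 0], [0, 0], [1, 1], [0, 0]], phased=False)
    with pytest.raises(Exception, match="phased"):
        compute_ehh(panel, 0, 1)


# --------------------------------------------------------------------------- #
# iHH integration
# --------------------------------------------------------------------------- #
def make_profile(left, right):
    return EHHProfile(
        core_index=0,
        core_allele="derived",
        core_pos=int(left[0][0]),
        n_carriers=4,
        left_pos=np.array([p for p, _ in left]),
        left_ehh=np.array([v for _, v in left]),
        right_pos=np.array([p for p, _ in right]),
        right_ehh=np.array([v for _, v in right]),
    )


@pytest.mark.parametrize(
    "left, right, expected",
    [
        # EHH == 1 over one arm of length L -> contribution L
        ([(0, 1.0)], [(0, 1.0), (500, 1.0), (2000, 1.0)], 2000.0),
        # hand trapezoid: (0,1), (1000,0.5), (2000,0.0) -> 750 + 250
        ([(0, 1.0)], [(0, 1.0), (1000, 0.5), (2000, 0.0)], 1000.0),
        # single core point, immediate truncation -> 0
        ([(0, 1.0)], [(0, 1.0)], 0.0),
    ],
)
def test_integrate_ihh_trapezoid(left, right, expected):
    assert integrate_ihh(make_profile(left, right)) == pytest.approx(expected)


# --------------------------------------------------------------------------- #
# piHS transform
# --------------------------------------------------------------------------- #
@pytest.mark.parametrize(
    "x, expected",
    [(6.936, 11.395), (-7.64, 13.662), (-6.16, 9.139), (5.588, 7.640), (4.962, 6.157)],
)
def test_pihs_reproduces_reported_pairs(x, expected):
    assert pihs_transform(x) == pytest.approx(expected, abs=0.01)


def test_pihs_zero_and_symmetry_and_deep_tail():
    assert pihs_transform(0.0) == 0.0
    assert pihs_transform(4.962) == pihs_transform(-4.962)
    # stable far into the tail: 2*Q(8) ~ 1.2e-15
    assert pihs_transform(8.0) == pytest.approx(-np.log10(1.244e-15), abs=0.01)
    arr = pihs_transform(np.array([-3.0, 0.0, 3.0]))
    assert arr[0] == arr[2] and arr[1] == 0.0


# --------------------------------------------------------------------------- #
# Genome-wide scan
# --------------------------------------------------------------------------- #
def test_scan_standardization_identity(small_sweep):
    scan = scan_ihs(small_sweep.panel_sel)
    ok = scan[scan["std_ihs"].notna()].copy()
    assert len(ok) > 50
    bins = (ok["freq_derived"] / 0.025).astype(int)
    for _, grp in ok.groupby(bins):
        if len(grp) >= 2:
            assert grp["std_ihs"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["std_ihs"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_scan_sample_order_invariance(small_sweep):
    panel = small_sweep.panel_sel
    scan1 = scan_ihs(panel)
    rng = np.random.default_rng(3)
    perm = rng.permutation(panel.n_samples)
    scan2 = scan_ihs(panel.take_samples(perm))
    pd.testing.assert_frame_equal(scan1, scan2)


def test_scan_sweep_sign_convention(small_sweep):
    """At the swept focal SNP the standardized score is negative (the
    extended haplotype belongs to the derived allele)."""
    scan = scan_ihs(small_sweep.panel_sel)
    fi = small_sweep.truth.focal_index
    fp = small_sweep.panel_sel.variants["pos_bp"].iloc[fi]
    near = scan[(scan["pos_bp"] - fp).abs() <= 500_000]
    near = near[near["std_ihs"].notna()]
    assert near["std_ihs"].min() < 0


def test_scan_equal_ihh_gives_zero_raw():
    # perfectly symmetric panel: ancestral and derived carriers mirror each
    # other, so iHH_a == iHH_d at the core
    haplo = np.array(
        [[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.int8
    )
    panel = build_panel(haplo)
    scan = scan_ihs(panel, min_maf=0.0, freq_bin=1.0)
    assert scan["raw_ihs"].iloc[1] == pytest.approx(0.0, abs=1e-12)


def test_call_significant_boundary_and_classes(reported_scores):
    scan = pd.DataFrame(
        {
            "id": [f"x{i}" for i in range(3)],
            "std_ihs": [6.0, -6.0, 0.0],
        }
    )
    # pihs(6.0) > 6 -> significant; exactly-zero score never significant
    out = call_significant(scan)
    assert out["significant"].tolist() == [True, True, False]
    assert out["allele_class"].tolist() == ["ancestral", "derived", None]
    # pihs exactly equal to the threshold is NOT significant (strict rule)
    from scipy.special import erfcinv

    x = float(np.sqrt(2) * erfcinv(1e-6))  # pihs(x) == 6 exactly
    row = pd.DataFrame({"id": ["y"], "std_ihs": [x]})
    val = float(call_significant(row)["pihs"].iloc[0])
    assert abs(val - 6.0) < 1e-9
    flagged = call_significant(row, threshold=val)
    assert not bool(flagged["significant"].iloc[0])


def test_call_significant_empty_scan():
    out = call_significant(pd.DataFrame({"id": [], "std_ihs": []}))
    assert len(out) == 0


# --------------------------------------------------------------------------- #
# Bifurcation trees
# --------------------------------------------------------------------------- #
def test_bifurcation_conservation_and_order(small_sweep):
    panel = small_sweep.panel_sel
    fi = small_sweep.truth.focal_index
    tree = bifurcation_tree(panel, fi, "derived", direction="right", max_markers=8)
    assert tree.count == int((panel.haplo[:, fi] == 1).sum())

    def check(node):
        if node.children:
            assert sum(c.count for c in node.children) == node.count
            alleles = [c.allele for c in node.children]
            assert alleles == sorted(alleles)  # allele-0 branch first
            for c in node.children:
                check(c)

    check(tree)


def test_bifurcation_zero_recombination_leaves_bounded_by_founders():
    from sweepscan import SweepSimConfig, simulate

    cfg = SweepSimConfig(
        n_base=40, n_sel=30, n_unsel=20, n_census_sel=40, n_census_unsel=40,
        n_snps=60, rho_per_bp=0.0, s=0.0, g_split=10, g_sel=5, seed=21,
    )
    out = simulate(cfg)
    founders = out.truth.founder_haplotypes
    panel = out.panel_sel
    core = panel.n_variants // 2
    for allele in (0, 1):
        if (panel.haplo[:, core] == allele).sum() == 0:
            continue
        tree = bifurcation_tree(panel, core, allele, "right", max_markers=panel.n_variants)
        assert len(tree.leaves()) <= len(founders)


def test_bifurcation_single_carrier_is_path():
    haplo = np.array([[1, 0, 1], [0, 1, 0], [0, 0, 0], [0, 1, 1]], dtype=np.int8)
    panel = build_panel(haplo)
    tree = bifurcation_tree(panel, 0, 1, "right", max_markers=5)
    node, depth = tree, 0
    while node.children:
        assert len(node.children) == 1 and node.count == 1
        node = node.children[0]
        depth += 1
    assert depth == 2  # truncated at the chromosome end
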