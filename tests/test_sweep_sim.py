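"""Wright–Fisher sweep simulator: reproducibility, selection response,
cohorts and EBV phenotypes."""

import numpy as np
import pytest

from sweepscan import (
    SweepSimConfig,
    TraitModel,
    assign_cohorts,
    compute_fst,
    simulate,
    simulate_ebv,
)


def small_config(**kw):
    base = dict(
        n_base=100, n_sel=60, n_unsel=50, n_census_sel=150, n_census_unsel=150,
        n_snps=150, s=0.0, g_split=20, g_sel=15, seed=1,
    )
    base.update(kw)
    return SweepSimConfig(**base)


# --------------------------------------------------------------------------- #
# Structure and reproducibility
# --------------------------------------------------------------------------- #
def test_simulate_emits_phased_panels_with_known_ancestral():
    out = simulate(small_config())
    for panel in (out.panel_sel, out.panel_unsel):
        assert panel.phased
        assert panel.variants["ancestral"].notna().all()
        assert not (panel.haplo == -1).any()
    assert out.panel_sel.n_samples == 60
    assert out.panel_unsel.n_samples == 50


def test_simulate_bit_exact_reproducibility():
    a = simulate(small_config(seed=9, s=0.1))
    b = simulate(small_config(seed=9, s=0.1))
    assert a.panel_sel.equals(b.panel_sel)
    assert a.panel_unsel.equals(b.panel_unsel)
    assert a.truth.focal_traj_sel == b.truth.focal_traj_sel


def test_truth_frequencies_match_panel_columns_exactly():
    out = simulate(small_config(seed=4))
    np.testing.assert_array_equal(out.truth.final_freq_sel, out.panel_sel.freq_b())
    np.testing.assert_array_equal(out.truth.final_freq_unsel, out.panel_unsel.freq_b())


def test_no_divergence_limit_gives_near_zero_fst():
    cfg = small_config(g_split=0, g_sel=0, n_snps=400, n_sel=100, n_unsel=100,
                      n_census_sel=None, n_census_unsel=None, seed=3)
    out = simulate(cfg)
    fst = compute_fst(out.panel_sel, out.panel_unsel).genome_wide
    assert 0 <= fst < 0.01


def test_zero_recombination_emits_only_founder_haplotypes():
    out = simulate(small_config(rho_per_bp=0.0, seed=6))
    founders = {bytes(h) for h in out.truth.founder_haplotypes}
    for h in out.panel_sel.haplo:
        assert bytes(h) in founders
    for h in out.panel_unsel.haplo:
        assert bytes(h) in founders


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="g_sel"):
        simulate(small_config(g_sel=99))
    with pytest.raises(ValueError, match="dominance"):
        simulate(small_config(h=0.0))
    with pytest.raises(ValueError, match="census"):
        simulate(small_config(n_census_sel=10))


# --------------------------------------------------------------------------- #
# Selection response vs deterministic oracle
# --------------------------------------------------------------------------- #
def deterministic_final_freq(p0, s, h, generations):
    """Deterministic allele-frequency iteration under viability selection."""
    p = p0
    for _ in range(generations):
        q = 1 - p
        w_bar = 1 + 2 * p * q * h * s + p * p * s
        p = (p * p * (1 + s) + p * q * (1 + h * s)) / w_bar
    return p


def test_selection_raises_focal_frequency_over_unselected():
    wins = 0
    n_seeds = 12
    for seed in range(n_seeds):
        out = simulate(small_config(s=0.1, g_split=40, g_sel=40, seed=100 + seed,
                                    focal_start_freq=0.1))
        if out.truth.focal_traj_sel[-1] > out.truth.focal_traj_unsel[-1]:
            wins += 1
    # the deterministic iteration predicts a clear rise (0.1 -> ~0.5 at
    # s=0.1, h=0.5, 40 generations), so selection should win almost always
    assert deterministic_final_freq(0.1, 0.1, 0.5, 40) > 0.35
    assert wins >= int(0.8 * n_seeds)


def test_final_frequency_tracks_deterministic_prediction_in_mean():
    s, g = 0.3, 25
    finals, starts = [], []
    for seed in range(8):
        out = simulate(small_config(s=s, g_split=g, g_sel=g, seed=200 + seed,
                                    focal_start_freq=0.2))
        starts.append(out.truth.focal_traj_sel[0])
        finals.append(out.truth.focal_traj_sel[-1])
    predicted = np.mean([deterministic_final_freq(p0, s, 0.5, g) for p0 in starts])
    assert np.mean(finals) == pytest.approx(predicted, abs=0.15)


# --------------------------------------------------------------------------- #
# Cohorts
# --------------------------------------------------------------------------- #
def test_assign_cohorts_draws_later_decades_from_later_generations():
    decades = {1980: 12, 1990: 12, 2000: 12, 2010: 12}
    out = simulate(small_config(seed=13, s=0.2, cohort_decades=decades))
    panel = out.panel_sel
    assert panel.n_samples == 48
    assert panel.samples["sample_id"].is_unique
    gens = [out.snapshots[d][0] for d in sorted(decades)]
    assert gens == sorted(gens) and gens[0] < gens[-1]
    counts = panel.samples["cohort_decade"].value_counts()
    assert set(counts.index) == set(decades) and (counts == 12).all()


def test_assign_cohorts_single_decade_and_overdraw_error():
    out = simulate(small_config(seed=14, cohort_decades={2010: 20}))
    assert (out.panel_sel.samples["cohort_decade"] == 2010).all()
    with pytest.raises(ValueError, match="requested"):
        assign_cohorts(out, {2010: 10_000}, seed=0)


def test_focal_frequency_by_decade_rises_under_selection():
    decades = {1980: 15, 1990: 15, 2000: 15, 2010: 15}
    rises = 0
    n_seeds = 10
    for seed in range(n_seeds):
        out = simulate(
            small_config(seed=300 + seed, s=0.2, g_split=30, g_sel=30,
                         cohort_decades=decades, focal_start_freq=0.2)
        )
        freqs = [out.truth.focal_freq_by_decade[d] for d in sorted(decades)]
        if freqs[-1] >= freqs[0]:
            rises += 1
    assert rises >= int(0.9 * n_seeds)


# --------------------------------------------------------------------------- #
# EBV phenotypes
# --------------------------------------------------------------------------- #
def test_ebv_reliability_one_equals_true_bv():
    out = simulate(small_config(seed=15))
    out = simulate_ebv(out, TraitModel("CWT", n_qtl=10, reliability=1.0), seed=1)
    np.testing.assert_array_equal(
        out.panel_sel.samples["CWT"].to_numpy(), out.truth.true_bv["CWT"]
    )


def test_ebv_zero_effects_is_pure_noise():
    out = simulate(small_config(seed=16))
    out = simulate_ebv(out, TraitModel("flat", n_qtl=0, reliability=0.5), seed=2)
    ebv = out.panel_sel.samples["flat"].to_numpy()
    assert np.all(out.truth.true_bv["flat"] == 0)
    assert abs(ebv.mean()) < 3 * ebv.std(ddof=1) / np.sqrt(len(ebv))


def test_ebv_reliability_controls_correlation():
    out = simulate(small_config(seed=17, n_sel=400, n_census_sel=400))
    out = simulate_ebv(out, TraitModel("t", n_qtl=30, reliability=0.8), seed=3)
    r2 = np.corrcoef(out.panel_sel.samples["t"], out.truth.true_bv["t"])[0, 1] ** 2
    assert r2 == pytest.approx(0.8, abs=0.1)


def test_ebv_regression_recovers_focal_effect():
    cfg = small_config(seed=18, s=0.1, n_sel=500, n_census_sel=600, n_snps=200)
    out = simulate(cfg)
    beta = 1.5
    out = simulate_ebv(
        out, TraitModel("CWT", n_qtl=0, focal_effect=beta, reliability=0.8), seed=4
    )
    y = out.panel_sel.samples["CWT"].to_numpy()
    code = out.panel_sel.derived_code()[out.truth.focal_index]
    dos = out.panel_sel.dosage()[:, out.truth.focal_index]
    x = dos if code == 1 else 2 - dos
    x1 = np.column_stack([np.ones_like(x), x])
    coef, res_, rank_, sv_ = np.linalg.lstsq(x1, y, rcond=None)
    resid = y - x1 @ coef
    se = np.sqrt(
        resid @ resid / (len(y) - 2) * np.linalg.inv(x1.T @ x1)[1, 1]
    )
    assert coef[1] == pytest.approx(beta, abs=2 * se)


def test_ebv_invalid_reliability_rejected():
    out = simulate(small_config(seed=19))
    with pytest.raises(ValueError, match="reliability"):
        simulate_ebv(out, TraitModel("x", reliability=1.5), seed=0)


def test_decade_gain_shifts_cohort_means():
    decades = {1980: 20, 1990: 20, 2000: 20, 2010: 20}
    out = simulate(small_config(seed=20, cohort_decades=decades))
    gain = 2.0
    out = simulate_ebv(
        out,
        TraitModel("t", n_qtl=0, decade_gain=gain, reliability=1.0),
        seed=5,
    )
    means = out.panel_sel.samples.groupby("cohort_decade")["t"].mean()
    diffs = np.diff(means[sorted(decades)].to_numpy())
    np.testing.assert_allclose(diffs, gain, atol=1e-9)
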