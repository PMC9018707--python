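"""Decadal trend analysis at focal SNPs and pairwise linkage disequilibrium.

The trend analysis tracks, per decade cohort, the ancestral/derived allele
frequencies at chosen SNPs and the mean EBV per trait — the direct readout
of whether haplotype turnover at a putative sweep locus moves with the
realized genetic gain of the breeding program.

LD is computed from phased haplotype counts (exact two-locus frequencies,
no EM): ``D = p_AB - p_A p_B``, ``r^2 = D^2 / (p_A p_a p_B p_b)`` and
``D' = D / D_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, PanelError


# --------------------------------------------------------------------------- #
# Cohort trends
# --------------------------------------------------------------------------- #
@dataclass
class CohortTrend:
    """Per-decade allele frequencies and EBV summaries.

    ``allele_freq`` rows: (decade, snp id) with haplotype count and
    ancestral/derived frequencies; ``ebv`` rows: (decade, trait) with
    sample count, mean EBV and its standard error.  Decades ascend.
    """

    allele_freq: pd.DataFrame
    ebv: pd.DataFrame


def cohort_trend(
    panel: HaplotypePanel,
    snp_ids: list[str],
    traits: list[str] | None = None,
) -> CohortTrend:
    """Decadal allele-frequency and EBV trends at the given SNPs.

    Requires ``cohort_decade`` on every sample used and a known ancestral
    state at each requested SNP.  Decades with zero samples yield rows of
    nulls.  Frequencies are exact column counts over the cohort's
    haplotypes.
    """
    if "cohort_decade" not in panel.samples.columns:
        raise PanelError("samples lack a cohort_decade column")
    traits = traits or []
    for t in traits:
        if t not in panel.samples.columns:
            raise PanelError(f"trait column {t!r} absent from sample table")
    idx = {mid: j for j, mid in enumerate(panel.variants["id"])}
    missing = [s for s in snp_ids if s not in idx]
    if missing:
        raise PanelError(f"SNP id(s) not in panel: {missing[:5]}")
    derived_code = panel.derived_code()
    for s in snp_ids:
        if derived_code[idx[s]] < 0:
            raise PanelError(f"SNP {s!r} has unknown ancestral state")

    decades = sorted(panel.samples["cohort_decade"].dropna().unique())
    freq_rows, ebv_rows = [], []
    for dec in decades:
        members = (panel.samples["cohort_decade"] == dec).to_numpy()
        n = int(members.sum())
        if n == 0:
            for s in snp_ids:
                freq_rows.append((dec, s, 0, np.nan, np.nan))
            for t in traits:
                ebv_rows.append((dec, t, 0, np.nan, np.nan))
            continue
        sub = panel.take_samples(members)
        for s in snp_ids:
            j = idx[s]
            n_hap = sub.n_haplotypes
            n_derived = int((sub.haplo[:, j] == derived_code[j]).sum())
            freq_rows.append(
                (dec, s, n_hap, 1.0 - n_derived / n_hap, n_derived / n_hap)
            )
        for t in traits:
            vals = sub.samples[t].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            mean = float(vals.mean()) if len(vals) else np.nan
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            ebv_rows.append((dec, t, len(vals), mean, sem))

    allele_freq = pd.DataFrame(
        freq_rows,
        columns=["decade", "snp_id", "n_haplotypes", "freq_ancestral", "freq_derived"],
    )
    ebv = pd.DataFrame(
        ebv_rows, columns=["decade", "trait", "n_samples", "mean_ebv", "se_ebv"]
    )
    return CohortTrend(allele_freq=allele_freq, ebv=ebv)


def haplotype_class_ratio(
    panel: HaplotypePanel, snp_id: str
) -> pd.DataFrame:
    """Per-decade counts of haplotypes classified ancestral vs derived.

    A region's haplotypes are classified by their allele at its most
    significant SNP (``snp_id``); the returned frame gives per-decade
    counts and the derived:ancestral ratio.
    """
    trend = cohort_trend(panel, [snp_id])
    df = trend.allele_freq.copy()
    df["n_ancestral"] = (df["n_haplotypes"] * df["freq_ancestral"]).round().astype("Int64")
    df["n_derived"] = (df["n_haplotypes"] * df["freq_derived"]).round().astype("Int64")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["derived_ancestral_ratio"] = df["n_derived"] / df["n_ancestral"]
    return df[
        ["decade", "snp_id", "n_haplotypes", "n_ancestral", "n_derived",
         "derived_ancestral_ratio"]
    ]


# --------------------------------------------------------------------------- #
# Linkage disequilibrium
# --------------------------------------------------------------------------- #
@dataclass
class LDMatrix:
    """Pairwise r^2 and D' over a marker window.

    Matrices are symmetric with NaN where a pair was skipped (beyond
    ``max_dist_bp`` or a monomorphic member); the r^2 diagonal is 1 for
    polymorphic markers.
    """

    marker_ids: list[str]
    pos_bp: np.ndarray
    r2: np.ndarray
    dprime: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format upper triangle (id_a, id_b, dist_bp, r2, dprime)."""
        rows = []
        k = len(self.marker_ids)
        for i in range(k):
            for j in range(i + 1, k):
                if np.isfinite(self.r2[i, j]) or np.isfinite(self.dprime[i, j]):
                    rows.append(
                        (
                            self.marker_ids[i],
                            self.marker_ids[j],
                            int(abs(self.pos_bp[j] - self.pos_bp[i])),
                            self.r2[i, j],
                            self.dprime[i, j],
                        )
                    )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "dist_bp", "r2", "dprime"])


def ld_matrix(
    panel: HaplotypePanel,
    marker_ids: list[str] | None = None,
    window: tuple[str, int, int] | None = None,
    max_dist_bp: float | None = 500_000.0,
) -> LDMatrix:
    """Haplotype-based pairwise LD over a marker list or genomic window.

    ``window`` is (chrom, start_bp, end_bp), inclusive.  Pairs farther
    apart than ``max_dist_bp`` (default 500 kb, the usual chip-practice
    limit; pass None for unlimited) and pairs involving a monomorphic
    marker get NaN entries.
    """
    panel.require_phased()
    if marker_ids is not None:
        idx = {mid: j for j, mid in enumerate(panel.variants["id"])}
        missing = [s for s in marker_ids if s not in idx]
        if missing:
            raise PanelError(f"marker id(s) not in panel: {missing[:5]}")
        cols = np.array([idx[s] for s in marker_ids])
    elif window is not None:
        chrom, start, end = window
        sel = (
            (panel.variants["chrom"] == str(chrom))
            & (panel.variants["pos_bp"] >= start)
            & (panel.variants["pos_bp"] <= end)
        ).to_numpy()
        cols = np.flatnonzero(sel)
    else:
        cols = np.arange(panel.n_variants)
    if len(cols) == 0:
        raise PanelError("no markers selected for LD")

    hap = panel.haplo[:, cols].astype(np.float64)
    n = hap.shape[0]
    p = hap.mean(axis=0)  # freq of allele coded 1
    k = len(cols)
    pos = panel.variants["pos_bp"].to_numpy()[cols]
    chroms = panel.variants["chrom"].to_numpy()[cols]

    # exact two-locus haplotype frequency of the (1, 1) class
    p11 = (hap.T @ hap) / n
    d = p11 - np.outer(p, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.outer(p * (1 - p), p * (1 - p))
        r2 = d**2 / denom
    # D' normalizes by D_max = min(pA*qB, qA*pB) when D > 0 and
    # min(pA*pB, qA*qB) when D < 0
    pa, qa = p, 1 - p
    dmax_pos = np.minimum(np.outer(pa, qa), np.outer(qa, pa))
    dmax_neg = np.minimum(np.outer(pa, pa), np.outer(qa, qa))
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = np.where(d >= 0, d / dmax_pos, d / dmax_neg)

    mono = (p <= 0) | (p >= 1)
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    dprime[mono, :] = np.nan
    dprime[:, mono] = np.nan
    if max_dist_bp is not None:
        dist = np.abs(pos[:, None] - pos[None, :])
        far = dist > max_dist_bp
        r2[far] = np.nan
        dprime[far] = np.nan
    cross = chroms[:, None] != chroms[None, :]
    r2[cross] = np.nan
    dprime[cross] = np.nan
    return LDMatrix(
        marker_ids=list(panel.variants["id"].iloc[cols]),
        pos_bp=pos,
        r2=r2,
        dprime=dprime,
    )
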