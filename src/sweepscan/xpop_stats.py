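"""Between-population statistics: site EHH (EHHS), iES, Rsb, Fst and MDS.

Rsb contrasts haplotype extension between two populations.  The per-site
ingredient is the Tang-style site EHH: the haplotype homozygosity of *all*
haplotypes (both core alleles pooled) over the interval core..x, with the
unbiased (n - 1) correction,

    h(core..x) = (n * sum_k f_k^2 - 1) / (n - 1),     EHHS(x) = h(core..x) / h(core),

integrated over physical distance to give iES per population.  Per SNP,
``Rsb = ln(iES_pop1 / iES_pop2)``, standardized by subtracting the median
(robust to the very outliers the scan is hunting) and dividing by the
standard deviation, then mapped to a -log10 two-sided Gaussian tail
probability exactly like piHS.  Positive standardized values point to
extended haplotypes in the numerator population.

Fst here is the heterozygosity form ``(H_T - H_S) / H_T`` with the
population-mean allele frequency unweighted by sample size; the genome-wide
summary is the ratio of sums, which is stable at low-MAF SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehh_core import EHHError, EHHProfile, _walk_arm, integrate_ihh, pihs_transform
from .panel import HaplotypePanel, PanelError


# --------------------------------------------------------------------------- #
# Site EHH and iES
# --------------------------------------------------------------------------- #
def _core_homozygosity(alleles: np.ndarray) -> float:
    n = len(alleles)
    counts = np.bincount(alleles.astype(np.int64))
    return (float((counts.astype(float) ** 2).sum() / n) - 1.0) / (n - 1)


def compute_ehhs(
    panel: HaplotypePanel,
    core_index: int,
    cutoff: float = 0.05,
    max_extension_bp: float | None = None,
    max_gap_bp: float | None = None,
) -> EHHProfile:
    """Site-EHH decay profile around ``core_index`` (both alleles pooled).

    EHHS(core) = 1 by construction; values decay outward as recombinant and
    mutant haplotypes split the pooled partition.  Needs at least two
    haplotypes; a monomorphic core is legal (its core homozygosity is 1).
    """
    panel.require_phased()
    n = panel.n_haplotypes
    if n < 2:
        raise EHHError("need at least two haplotypes for EHHS")
    rows = np.arange(n)
    core_alleles = panel.haplo[:, core_index]
    h0 = _core_homozygosity(core_alleles)
    positions = panel.variants["pos_bp"].to_numpy()
    lo, hi = panel.chrom_bounds(core_index)
    core_pos = int(positions[core_index])

    rp, re_, why_r = _walk_arm(
        panel.haplo, rows, positions, core_index, hi, +1,
        cutoff, max_extension_bp, max_gap_bp, "site",
        init_keys=core_alleles, norm=h0,
    )
    lp, le_, why_l = _walk_arm(
        panel.haplo, rows, positions, core_index, lo - 1, -1,
        cutoff, max_extension_bp, max_gap_bp, "site",
        init_keys=core_alleles, norm=h0,
    )
    return EHHProfile(
        core_index=core_index,
        core_allele="site",
        core_pos=core_pos,
        n_carriers=n,
        left_pos=np.asarray([core_pos] + lp, dtype=np.int64),
        left_ehh=np.asarray([1.0] + le_),
        right_pos=np.asarray([core_pos] + rp, dtype=np.int64),
        right_ehh=np.asarray([1.0] + re_),
        stop_left=why_l,
        stop_right=why_r,
    )


def integrate_ies(profile: EHHProfile) -> float:
    """Trapezoidal integral of a site-EHH profile (alias of the iHH rule)."""
    return integrate_ihh(profile)


# --------------------------------------------------------------------------- #
# Rsb scan
# --------------------------------------------------------------------------- #
RSB_COLUMNS = [
    "chrom", "pos_bp", "id", "ies_pop1", "ies_pop2",
    "raw_rsb", "std_rsb", "p_rsb", "significant", "reason",
]


def shared_polymorphic_ids(panel1: HaplotypePanel, panel2: HaplotypePanel) -> list[str]:
    """Marker ids present and polymorphic (0 < freq < 1) in both panels."""
    f1 = dict(zip(panel1.variants["id"], panel1.freq_b()))
    f2 = dict(zip(panel2.variants["id"], panel2.freq_b()))
    return [
        mid for mid, p in f1.items()
        if mid in f2 and 0.0 < p < 1.0 and 0.0 < f2[mid] < 1.0
    ]


def scan_rsb(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    shared_snps: list[str] | None = None,
    cutoff: float = 0.05,
    max_extension_bp: float | None = None,
    threshold: float = 6.0,
) -> pd.DataFrame:
    """Rsb scan contrasting haplotype extension of ``panel1`` over ``panel2``.

    The scan is restricted to SNPs present and polymorphic in both panels
    (or the explicit ``shared_snps`` list).  Positive standardized scores
    point to extended haplotypes in ``panel1`` (the numerator population);
    swapping the panels negates every raw score exactly.  The result's
    ``attrs`` record the orientation.
    """
    panel1.require_phased()
    panel2.require_phased()
    if shared_snps is None:
        shared_snps = shared_polymorphic_ids(panel1, panel2)
    if not shared_snps:
        raise EHHError("no shared polymorphic SNPs between the two panels")

    idx1 = {mid: j for j, mid in enumerate(panel1.variants["id"])}
    idx2 = {mid: j for j, mid in enumerate(panel2.variants["id"])}
    rows = []
    for mid in shared_snps:
        j1, j2 = idx1[mid], idx2[mid]
        ies1 = integrate_ies(compute_ehhs(panel1, j1, cutoff, max_extension_bp))
        ies2 = integrate_ies(compute_ehhs(panel2, j2, cutoff, max_extension_bp))
        if ies1 <= 0 or ies2 <= 0:
            raw = np.nan
            reason = "zero_ies"
        else:
            raw = math.log(ies1 / ies2)
            reason = "ok"
        rows.append(
            (
                panel1.variants["chrom"].iloc[j1],
                panel1.variants["pos_bp"].iloc[j1],
                mid,
                ies1 if ies1 > 0 else np.nan,
                ies2 if ies2 > 0 else np.nan,
                raw,
                reason,
            )
        )
    scan = pd.DataFrame(
        rows, columns=["chrom", "pos_bp", "id", "ies_pop1", "ies_pop2", "raw_rsb", "reason"]
    )
    raw = scan["raw_rsb"].to_numpy(dtype=float)
    std = np.full(raw.shape, np.nan)
    ok = np.isfinite(raw)
    if ok.sum() >= 2 and np.std(raw[ok]) > 0:
        std[ok] = (raw[ok] - np.median(raw[ok])) / np.std(raw[ok], ddof=0)
    p_rsb = np.full(raw.shape, np.nan)
    p_rsb[np.isfinite(std)] = pihs_transform(std[np.isfinite(std)])
    scan["std_rsb"] = std
    scan["p_rsb"] = p_rsb
    scan["significant"] = np.where(np.isfinite(p_rsb), p_rsb > threshold, False)
    scan = scan[RSB_COLUMNS]
    scan.attrs["numerator"] = str(panel1.samples["population"].iloc[0]) if len(panel1.samples) else "pop1"
    scan.attrs["denominator"] = str(panel2.samples["population"].iloc[0]) if len(panel2.samples) else "pop2"
    return scan


# --------------------------------------------------------------------------- #
# Fst
# --------------------------------------------------------------------------- #
@dataclass
class FstResult:
    """Per-SNP heterozygosity components and the genome-wide summary.

    ``per_snp`` columns: id, p1, p2, h_t, h_s, fst (NaN where the pooled
    sample is monomorphic).  ``genome_wide`` is the ratio of the summed
    components, excluding monomorphic SNPs.
    """

    per_snp: pd.DataFrame
    genome_wide: float


def compute_fst(panel1: HaplotypePanel, panel2: HaplotypePanel) -> FstResult:
    """Heterozygosity-based Fst over the SNPs shared by the two panels.

    Per SNP: ``H_S`` is the mean of the two within-population expected
    heterozygosities ``2 p q``; ``H_T = 2 p̄ q̄`` with the unweighted mean
    frequency ``p̄``; ``fst = (H_T - H_S) / H_T`` (NaN when ``H_T = 0``).
    """
    ids1 = list(panel1.variants["id"])
    f1 = dict(zip(ids1, panel1.freq_b()))
    f2 = dict(zip(panel2.variants["id"], panel2.freq_b()))
    shared = [mid for mid in ids1 if mid in f2]
    if not shared:
        raise PanelError("no shared SNPs between the two panels")
    p1 = np.array([f1[mid] for mid in shared])
    p2 = np.array([f2[mid] for mid in shared])
    h_s = (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2.0
    p_bar = (p1 + p2) / 2.0
    h_t = 2 * p_bar * (1 - p_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / h_t, np.nan)
    per_snp = pd.DataFrame(
        {"id": shared, "p1": p1, "p2": p2, "h_t": h_t, "h_s": h_s, "fst": fst}
    )
    poly = h_t > 0
    genome = float((h_t[poly].sum() - h_s[poly].sum()) / h_t[poly].sum()) if poly.any() else float("nan")
    return FstResult(per_snp=per_snp, genome_wide=genome)


# --------------------------------------------------------------------------- #
# Classical MDS on identity-by-state distances
# --------------------------------------------------------------------------- #
@dataclass
class MDSResult:
    """Classical-MDS coordinates of the pooled samples.

    ``coordinates`` is ``(n_samples, dims)``; ``eigenvalues`` the retained
    eigenvalues of the double-centred squared-distance matrix; ``distance``
    the 1 - mean-IBS matrix the embedding reproduces.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: list[str]
    distance: np.ndarray


def ibs_distance(dosage: np.ndarray) -> np.ndarray:
    """1 - mean identity-by-state sharing per sample pair.

    IBS sharing of genotypes g, g' in {0,1,2} at one SNP is
    ``1 - |g - g'| / 2``; the distance averages over SNPs.
    """
    n = dosage.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(dosage[i] - dosage)  # (n, m)
        dist[i] = np.nanmean(diff, axis=1) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def classical_mds(
    panels: HaplotypePanel | list[HaplotypePanel], dims: int = 4
) -> MDSResult:
    """Classical (metric) MDS of pooled samples on 1 - IBS distances.

    Double-centres the squared-distance matrix and eigendecomposes it; the
    top ``dims`` positive-eigenvalue axes are returned (fewer, with a
    warning logged, when the matrix has lower rank).
    """
    import logging

    if isinstance(panels, HaplotypePanel):
        pooled = panels
    else:
        base = panels[0]
        for other in panels[1:]:
            if list(other.variants["id"]) != list(base.variants["id"]):
                raise PanelError("panels must share an identical variant list for MDS")
        pooled = HaplotypePanel(
            variants=base.variants,
            haplo=np.vstack([p.haplo for p in panels]),
            samples=pd.concat([p.samples for p in panels], ignore_index=True),
            phased=all(p.phased for p in panels),
        )
    dosage = pooled.dosage()
    if np.isnan(dosage).any():
        raise PanelError("MDS requires complete genotypes (run QC first)")
    dist = ibs_distance(dosage)
    n = dist.shape[0]
    j_center = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_center @ (dist**2) @ j_center
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = evals > max(1e-12, 1e-9 * abs(evals[0])) if n else evals > 0
    available = int(positive.sum())
    if available < dims:
        logging.getLogger(__name__).warning(
            "MDS: only %d positive dimensions available (requested %d)",
            available, dims,
        )
    k = min(dims, available)
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return MDSResult(
        coordinates=coords,
        eigenvalues=evals[:k],
        sample_ids=list(pooled.samples["sample_id"]),
        distance=dist,
    )
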