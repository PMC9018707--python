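"""Genomic relationship matrix and mixed-linear-model LOCO association.

The model per candidate SNP is

    y = a + b x + g + e,      g ~ N(0, sigma_g^2 A),   e ~ N(0, sigma_e^2 I),

where ``y`` is the (EBV) phenotype, ``x`` the allele dosage and ``A`` the
VanRaden genomic relationship matrix

    A_jk = (1/N) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

built from in-sample allele frequencies.  Testing runs
leave-one-chromosome-out (LOCO): the polygenic term for SNPs on chromosome
``c`` uses a GRM built from all other chromosomes, and the variance
components are re-estimated for every LOCO set, which avoids the candidate
signal absorbing into its own covariance (proximal contamination).

With a single random effect, REML reduces to a one-dimensional profile
likelihood over the variance ratio after one eigendecomposition of the GRM;
the per-SNP test is then an exact generalized-least-squares fit with a
1-df Wald chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import HaplotypePanel, PanelError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# GRM
# --------------------------------------------------------------------------- #
@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its provenance.

    ``matrix`` is ``n x n`` symmetric; ``p`` holds the in-sample
    allele_b frequency of each of the ``n_snps`` markers that entered the
    average (monomorphic markers are skipped).
    """

    matrix: np.ndarray
    sample_ids: list[str]
    chromosomes_included: list[str]
    p: np.ndarray
    snp_ids: list[str]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def compute_grm(panel: HaplotypePanel, exclude_chrom=None) -> GRM:
    """Build the GRM from dosages, optionally leaving out chromosome(s).

    ``exclude_chrom`` is a single label or a collection of labels.  SNPs
    monomorphic in-sample contribute nothing and are skipped (count logged).
    Raises ``PanelError`` when no SNP remains.
    """
    if exclude_chrom is None:
        excluded: set[str] = set()
    elif isinstance(exclude_chrom, (str, int)):
        excluded = {str(exclude_chrom)}
    else:
        excluded = {str(c) for c in exclude_chrom}
    keep_chrom = ~panel.variants["chrom"].astype(str).isin(excluded).to_numpy()

    dosage = panel.dosage()
    if np.isnan(dosage).any():
        raise PanelError("GRM requires complete genotypes (run QC first)")
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((keep_chrom & ~poly).sum())
    if n_mono:
        logger.info("GRM: skipped %d monomorphic SNP(s)", n_mono)
    keep = keep_chrom & poly
    if not keep.any():
        raise PanelError("GRM: no polymorphic SNPs left after exclusions")

    x = dosage[:, keep]
    pk = p[keep]
    w = (x - 2 * pk) / np.sqrt(2 * pk * (1 - pk))
    a = (w @ w.T) / keep.sum()
    chroms_in = [c for c in dict.fromkeys(panel.variants["chrom"]) if str(c) not in excluded]
    return GRM(
        matrix=a,
        sample_ids=list(panel.samples["sample_id"]),
        chromosomes_included=chroms_in,
        p=pk,
        snp_ids=list(panel.variants.loc[keep, "id"]),
    )


# --------------------------------------------------------------------------- #
# REML variance components
# --------------------------------------------------------------------------- #
def _eigh_psd(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    evals, evecs = np.linalg.eigh((k + k.T) / 2.0)
    if evals.min() < -1e-8 * max(1.0, abs(evals.max())):
        logger.warning(
            "GRM numerically non-PSD (min eigenvalue %.3g); clipping at 0",
            evals.min(),
        )
    return np.clip(evals, 0.0, None), evecs


def fit_variance_components(
    y: np.ndarray,
    grm: GRM | np.ndarray,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """REML estimates of (sigma_g^2, sigma_e^2) for y = mu + g + e.

    Exploits the single-random-effect structure: after one
    eigendecomposition of the GRM the REML log-likelihood is a 1-D function
    of the variance ratio, maximized by bounded scalar search (relative
    tolerance 1e-8 on the log-ratio).  Pass ``eig`` to reuse a
    decomposition.  A constant ``y`` yields (0, 0).
    """
    k = grm.matrix if isinstance(grm, GRM) else np.asarray(grm)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != k.shape[0]:
        raise ValueError("y length does not match GRM dimension")
    if np.var(y) == 0:
        return 0.0, 0.0
    lam, u = _eigh_psd(k) if eig is None else eig
    yt = u.T @ y
    ot = u.T @ np.ones(n)

    def neg_reml(log_ratio: float) -> float:
        ratio = 10.0**log_ratio  # sigma_g^2 / sigma_e^2
        d = ratio * lam + 1.0
        w = 1.0 / d
        xtx = float(np.sum(w * ot * ot))
        beta = float(np.sum(w * ot * yt)) / xtx
        r = yt - ot * beta
        rss = float(np.sum(w * r * r))
        sigma_e2 = rss / (n - 1)
        if sigma_e2 <= 0:
            return np.inf
        return 0.5 * (
            float(np.sum(np.log(d))) + (n - 1) * np.log(sigma_e2) + np.log(xtx)
        )

    res = optimize.minimize_scalar(
        neg_reml, bounds=(-8.0, 8.0), method="bounded", options={"xatol": 1e-8}
    )
    ratio = 10.0**res.x
    # at the lower boundary the polygenic term is effectively absent
    if res.x <= -7.99:
        ratio = 0.0
    d = ratio * lam + 1.0
    w = 1.0 / d
    xtx = float(np.sum(w * ot * ot))
    beta = float(np.sum(w * ot * yt)) / xtx
    r = yt - ot * beta
    sigma_e2 = float(np.sum(w * r * r)) / (n - 1)
    sigma_g2 = ratio * sigma_e2
    return sigma_g2, sigma_e2


# --------------------------------------------------------------------------- #
# LOCO association scan
# --------------------------------------------------------------------------- #
GWAS_COLUMNS = [
    "chrom", "pos_bp", "id", "freq", "beta", "se", "wald_chi2", "p",
    "neglog10p", "sigma_g2", "sigma_e2", "bonferroni_significant",
]


def build_loco_cache(panel: HaplotypePanel) -> dict:
    """Precompute per-chromosome LOCO GRMs and their eigendecompositions.

    The cache is independent of the phenotype, so repeated scans of the
    same panel (replicate phenotypes, multiple traits) skip the expensive
    matrix work.  Pass the result to :func:`mlm_loco_scan`.
    """
    cache = {}
    for chrom in panel.chromosomes:
        try:
            grm = compute_grm(panel, exclude_chrom=chrom)
        except PanelError:
            grm = GRM(
                np.zeros((panel.n_samples, panel.n_samples)),
                list(panel.samples["sample_id"]), [], np.array([]), [],
            )
        lam, u = _eigh_psd(grm.matrix)
        cache[str(chrom)] = (grm, lam, u)
    return cache


def mlm_loco_scan(
    panel: HaplotypePanel,
    phenotype: pd.DataFrame | pd.Series | np.ndarray,
    trait: str | None = None,
    variance_components: tuple[float, float] | None = None,
    alpha: float = 0.05,
    loco_cache: dict | None = None,
) -> pd.DataFrame:
    """Mixed-model association of every SNP with a phenotype, LOCO style.

    ``phenotype`` is a DataFrame carrying ``sample_id`` plus the ``trait``
    column (aligned by id), a Series/array aligned with the panel's
    samples, or the name of a column already present in the panel's sample
    table (pass it as ``trait`` with ``phenotype=None`` is not supported —
    give the table).  Samples with missing phenotype are dropped.

    For each chromosome the GRM excludes that chromosome, variance
    components are refitted, and each SNP gets an exact GLS fit of
    ``y = a + b x`` under ``sigma_g^2 A_loco + sigma_e^2 I`` with a 1-df
    Wald test.  ``variance_components`` overrides the REML fit (useful for
    the sigma_g^2 = 0 reduction to OLS).  Monomorphic SNPs are emitted with
    null results; a chromosome with no polymorphic SNPs is skipped with a
    warning.  The Bonferroni flag uses ``alpha`` over the number of tested
    SNPs.
    """
    if isinstance(phenotype, pd.DataFrame):
        if trait is None:
            raise ValueError("trait column name required with a phenotype table")
        merged = panel.samples[["sample_id"]].merge(
            phenotype[["sample_id", trait]], on="sample_id", how="left"
        )
        y_full = merged[trait].to_numpy(dtype=float)
    else:
        y_full = np.asarray(phenotype, dtype=float)
        if len(y_full) != panel.n_samples:
            raise ValueError("phenotype length does not match the panel")

    keep = np.isfinite(y_full)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples with phenotype")
    work = panel.take_samples(keep) if not keep.all() else panel
    y = y_full[keep]

    dosage = work.dosage()
    if np.isnan(dosage).any():
        raise PanelError("association requires complete genotypes (run QC first)")
    n = len(y)
    m = work.n_variants
    freq = dosage.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    chi2 = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    sg2 = np.full(m, np.nan)
    se2 = np.full(m, np.nan)

    chrom_arr = work.variants["chrom"].to_numpy()
    ones = np.ones(n)
    for chrom in dict.fromkeys(chrom_arr):
        on_c = chrom_arr == chrom
        if not poly[on_c].any():
            logger.warning("chromosome %s: all SNPs monomorphic; skipped", chrom)
            continue
        if loco_cache is not None and str(chrom) in loco_cache:
            grm, lam, u = loco_cache[str(chrom)]
        else:
            try:
                grm = compute_grm(work, exclude_chrom=chrom)
            except PanelError:
                # single-chromosome panel: no polygenic term can be fitted
                logger.warning(
                    "no SNPs outside chromosome %s; fitting without a polygenic term",
                    chrom,
                )
                grm = GRM(
                    np.zeros((n, n)), list(work.samples["sample_id"]), [], np.array([]), []
                )
            lam, u = _eigh_psd(grm.matrix)
        if variance_components is None:
            sigma_g2, sigma_e2 = fit_variance_components(y, grm, eig=(lam, u))
        else:
            sigma_g2, sigma_e2 = variance_components
        d = sigma_g2 * lam + sigma_e2
        if np.all(d <= 0):
            d = np.ones_like(d)
        w = 1.0 / d
        yt = u.T @ y
        ot = u.T @ ones
        cols = np.flatnonzero(on_c & poly)
        xt = u.T @ dosage[:, cols]  # (n, k)
        a11 = float(np.sum(w * ot * ot))
        b1 = float(np.sum(w * ot * yt))
        a12 = xt.T @ (w * ot)
        a22 = np.einsum("ij,i,ij->j", xt, w, xt)
        b2 = xt.T @ (w * yt)
        det = a11 * a22 - a12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            b_hat = (a11 * b2 - a12 * b1) / det
            var_b = a11 / det
        beta[cols] = b_hat
        se[cols] = np.sqrt(var_b)
        chi2[cols] = b_hat**2 / var_b
        pval[cols] = stats.chi2.sf(chi2[cols], df=1)
        sg2[on_c] = sigma_g2
        se2[on_c] = sigma_e2

    n_tested = int(np.isfinite(pval).sum())
    bonf = np.zeros(m, dtype=bool)
    if n_tested:
        bonf[np.isfinite(pval)] = pval[np.isfinite(pval)] < alpha / n_tested
    with np.errstate(divide="ignore"):
        neglog = -np.log10(pval)
    out = pd.DataFrame(
        {
            "chrom": work.variants["chrom"],
            "pos_bp": work.variants["pos_bp"],
            "id": work.variants["id"],
            "freq": freq,
            "beta": beta,
            "se": se,
            "wald_chi2": chi2,
            "p": pval,
            "neglog10p": neglog,
            "sigma_g2": sg2,
            "sigma_e2": se2,
            "bonferroni_significant": bonf,
        }
    )
    return out[GWAS_COLUMNS]
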