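"""Core in-memory containers for phased/unphased SNP panels.

The central object is :class:`HaplotypePanel`: a haplotype-by-variant allele
matrix (two rows per diploid sample) together with a variant map and sample
metadata.  Every statistic in the package operates on this container.

Allele coding is positional: ``0`` means the variant's ``allele_a``, ``1``
means ``allele_b`` and ``-1`` marks a missing allele (only legal on unphased
panels).  Ancestral/derived status is carried per variant as which of the two
alleles (``"a"``/``"b"``) is ancestral, or missing when unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: columns every variant table must carry, in this order
VARIANT_COLUMNS = ["chrom", "pos_bp", "id", "allele_a", "allele_b", "ancestral"]

#: columns every sample table must carry (trait/phenotype columns may follow)
SAMPLE_COLUMNS = ["sample_id", "population"]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


def make_variant_table(
    chrom: Sequence,
    pos_bp: Sequence[int],
    ids: Sequence[str],
    allele_a: Sequence[str],
    allele_b: Sequence[str],
    ancestral: Sequence | None = None,
) -> pd.DataFrame:
    """Assemble a well-formed variant table.

    ``ancestral`` holds ``"a"``/``"b"`` per variant (which declared allele is
    ancestral) or ``None`` when unknown.
    """
    n = len(ids)
    if ancestral is None:
        ancestral = [None] * n
    df = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom],
            "pos_bp": np.asarray(pos_bp, dtype=np.int64),
            "id": list(ids),
            "allele_a": list(allele_a),
            "allele_b": list(allele_b),
            "ancestral": list(ancestral),
        }
    )
    return df


@dataclass
class HaplotypePanel:
    """Phased or unphased allele matrix plus variant map and sample metadata.

    Parameters
    ----------
    variants
        One row per variant with columns :data:`VARIANT_COLUMNS`; positions
        are 1-based physical bp, strictly increasing within a chromosome.
    haplo
        ``(2 * n_samples, n_variants)`` int8 matrix over ``{0, 1}`` (plus
        ``-1`` for missing alleles on unphased panels).  Rows ``2i`` and
        ``2i + 1`` are the two haplotypes of sample ``i``.
    samples
        One row per sample; must carry ``sample_id`` and ``population``;
        may carry ``cohort_decade`` and phenotype columns (EBVs, real units).
    phased
        True when rows are genuine haplotypes; EHH-family statistics refuse
        unphased panels.
    """

    variants: pd.DataFrame
    haplo: np.ndarray
    samples: pd.DataFrame
    phased: bool = False

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.haplo = np.ascontiguousarray(np.asarray(self.haplo, dtype=np.int8))
        self._validate()

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise PanelError(f"variant table lacks columns {missing_cols}")
        for c in SAMPLE_COLUMNS:
            if c not in self.samples.columns:
                raise PanelError(f"sample table lacks column {c!r}")
        if self.haplo.ndim != 2:
            raise PanelError("haplo must be a 2-D matrix")
        if self.haplo.shape[0] != 2 * len(self.samples):
            raise PanelError(
                f"haplo has {self.haplo.shape[0]} rows for {len(self.samples)} "
                "samples; expected exactly two haplotypes per sample"
            )
        if self.haplo.shape[1] != len(self.variants):
            raise PanelError(
                f"haplo has {self.haplo.shape[1]} columns for "
                f"{len(self.variants)} variants"
            )
        ok = np.isin(self.haplo, (0, 1, MISSING))
        if not ok.all():
            bad = np.unique(self.haplo[~ok])
            raise PanelError(f"allele codes outside {{0, 1, -1}}: {bad}")
        if self.phased and (self.haplo == MISSING).any():
            raise PanelError("phased panel contains missing alleles")
        pos = self.variants["pos_bp"].to_numpy()
        if len(pos) and pos.min() < 1:
            raise PanelError("positions must be >= 1 (1-based bp)")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            p = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(p) > 0):
                raise PanelError(
                    f"positions on chromosome {chrom} not strictly increasing"
                )
        same = self.variants["allele_a"] == self.variants["allele_b"]
        if same.any():
            raise PanelError(
                f"allele_a == allele_b at variants "
                f"{list(self.variants.loc[same, 'id'].head())}"
            )
        anc = self.variants["ancestral"]
        bad_anc = anc.notna() & ~anc.isin(["a", "b"])
        if bad_anc.any():
            raise PanelError("ancestral column must be 'a', 'b' or missing")

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haplo.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplo.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.variants["chrom"]))

    def require_phased(self) -> None:
        if not self.phased:
            raise PanelError("operation requires a phased panel")

    # -- frequencies ---------------------------------------------------- #
    def freq_b(self) -> np.ndarray:
        """Frequency of ``allele_b`` per variant, ignoring missing alleles."""
        obs = self.haplo != MISSING
        n_obs = obs.sum(axis=0)
        n_b = (self.haplo == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, n_b / np.maximum(n_obs, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.freq_b()
        return np.minimum(p, 1.0 - p)

    def derived_code(self) -> np.ndarray:
        """Per-variant allele code (0/1) of the *derived* allele; -1 unknown."""
        anc = self.variants["ancestral"]
        out = np.full(self.n_variants, MISSING, dtype=np.int8)
        out[(anc == "a").to_numpy()] = 1
        out[(anc == "b").to_numpy()] = 0
        return out

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per variant; NaN where ancestral unknown."""
        code = self.derived_code()
        p_b = self.freq_b()
        out = np.where(code == 1, p_b, 1.0 - p_b)
        out[code == MISSING] = np.nan
        return out

    # -- genotypes ------------------------------------------------------ #
    def dosage(self) -> np.ndarray:
        """``(n_samples, n_variants)`` count of allele_b copies; NaN if missing."""
        a0 = self.haplo[0::2].astype(np.float64)
        a1 = self.haplo[1::2].astype(np.float64)
        a0[a0 == MISSING] = np.nan
        a1[a1 == MISSING] = np.nan
        return a0 + a1

    def genotype_counts(self) -> np.ndarray:
        """Per-variant (hom_a, het, hom_b) counts over fully called samples."""
        d = self.dosage()
        out = np.empty((self.n_variants, 3), dtype=np.int64)
        out[:, 0] = np.nansum(d == 0, axis=0)
        out[:, 1] = np.nansum(d == 1, axis=0)
        out[:, 2] = np.nansum(d == 2, axis=0)
        return out

    # -- subsetting ------------------------------------------------------ #
    def take_variants(self, index: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the variant positions in ``index`` (kept order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            variants=self.variants.iloc[index],
            haplo=self.haplo[:, index],
            samples=self.samples,
            phased=self.phased,
        )

    def take_samples(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        rows = np.empty(2 * len(index), dtype=np.int64)
        rows[0::2] = 2 * index
        rows[1::2] = 2 * index + 1
        return HaplotypePanel(
            variants=self.variants,
            haplo=self.haplo[rows],
            samples=self.samples.iloc[index],
            phased=self.phased,
        )

    def chromosome(self, chrom) -> "HaplotypePanel":
        mask = (self.variants["chrom"] == str(chrom)).to_numpy()
        return self.take_variants(mask)

    def iter_chromosomes(self) -> Iterator[tuple[str, "HaplotypePanel"]]:
        for chrom in self.chromosomes:
            yield chrom, self.chromosome(chrom)

    def chrom_bounds(self, variant_index: int) -> tuple[int, int]:
        """Half-open [start, stop) variant-index range of the chromosome
        containing ``variant_index``."""
        chrom = self.variants["chrom"].iloc[variant_index]
        mask = (self.variants["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        return int(idx[0]), int(idx[-1]) + 1

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            variants=self.variants.copy(),
            haplo=self.haplo.copy(),
            samples=self.samples.copy(),
            phased=self.phased,
        )

    def equals(self, other: "HaplotypePanel") -> bool:
        return (
            self.phased == other.phased
            and np.array_equal(self.haplo, other.haplo)
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
        )
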