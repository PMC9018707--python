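"""Reading, writing and quality control of SNP genotype/haplotype data.

Supported formats
-----------------
* PLINK text PED/MAP (unphased genotypes, missing allele code ``0``)
* phased-haplotype TSV trio written by :func:`write_phased_table`
  (``<prefix>.haplo.tsv`` with two rows per sample, plus ``.variants.tsv``
  and ``.samples.tsv`` sidecars)
* phased VCF (``GT`` fields with ``|`` separators), via cyvcf2
* ancestral-allele TSV (``marker_id``, ``ancestral_allele``)

Quality control follows standard SNP-chip practice: per-sample missingness,
per-SNP call rate, an exact Hardy–Weinberg test (mid-less Wigginton-style
enumeration, computed within each population separately) and a minor-allele
frequency floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    MISSING,
    HaplotypePanel,
    PanelError,
    make_variant_table,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# --------------------------------------------------------------------------- #
# Hardy–Weinberg exact test
# --------------------------------------------------------------------------- #
def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the observed allele counts and sums the probabilities of all outcomes no
    more likely than the observed one (the convention PLINK's ``--hwe``
    filter uses).

    Parameters are genotype counts for a biallelic SNP.  Returns 1.0 for
    monomorphic SNPs (the test is degenerate there).
    """
    n_hom_a, n_het, n_hom_b = int(n_hom_a), int(n_het), int(n_hom_b)
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        return 1.0
    # rare allele count; heterozygote count shares its parity
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    if rare == 0:
        return 1.0

    probs = np.zeros(rare + 1)
    # start from the most heterozygous admissible configuration and recurse
    # downward: P(het-2)/P(het) = het*(het-1) / (4*(homR+1)*(homC+1))
    het = rare if (rare % 2 == n_het % 2) else rare - 1
    # admissible het counts run het, het-2, ..., parity of n_het
    hom_r = (rare - het) // 2
    hom_c = n - het - hom_r
    probs[het] = 1.0
    h = het
    while h >= 2:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    total = probs.sum()
    probs /= total
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# --------------------------------------------------------------------------- #
# PLINK PED/MAP
# --------------------------------------------------------------------------- #
def read_map(map_path: str | Path) -> pd.DataFrame:
    """Read a PLINK MAP file (3 or 4 whitespace-delimited columns)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, mid, _cm, pos = parts
            elif len(parts) == 3:
                chrom, mid, pos = parts
            else:
                raise ParseError(
                    f"{map_path}: line {lineno}: expected 3 or 4 columns, "
                    f"got {len(parts)}"
                )
            try:
                pos = int(pos)
            except ValueError as exc:
                raise ParseError(
                    f"{map_path}: line {lineno}: position {pos!r} not an integer"
                ) from exc
            rows.append((chrom, mid, pos))
    df = pd.DataFrame(rows, columns=["chrom", "id", "pos_bp"])
    dup = df["id"].duplicated()
    if dup.any():
        raise ParseError(
            f"{map_path}: duplicate marker id(s): "
            f"{df.loc[dup, 'id'].unique()[:5].tolist()}"
        )
    for chrom, grp in df.groupby("chrom", sort=False):
        if not grp["pos_bp"].is_monotonic_increasing or grp["pos_bp"].duplicated().any():
            raise ParseError(
                f"{map_path}: positions on chromosome {chrom} not strictly increasing"
            )
    return df


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> HaplotypePanel:
    """Read PLINK text PED + MAP into an unphased :class:`HaplotypePanel`.

    Alleles at each SNP are assigned positionally: ``allele_a`` is the
    alphabetically first nucleotide observed, ``allele_b`` the second (or
    ``"N"`` if the SNP is monomorphic in the file).  The PED missing code
    ``0`` becomes a missing entry, never an allele.
    """
    vmap = read_map(map_path)
    m = len(vmap)
    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"for {m} markers, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            populations.append(fid)
            sample_ids.append(iid)
            allele_rows.append(parts[6:])
    if not sample_ids:
        raise ParseError(f"{ped_path}: no samples")

    alleles = np.asarray(allele_rows, dtype="U8").reshape(len(sample_ids), m, 2)
    allele_a, allele_b = [], []
    haplo = np.full((2 * len(sample_ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ParseError(
                f"{ped_path}: marker {vmap['id'].iloc[j]!r} has more than two "
                f"alleles: {observed}"
            )
        a = observed[0] if observed else "N"
        b = observed[1] if len(observed) == 2 else ("N" if a != "N" else "X")
        allele_a.append(a)
        allele_b.append(b)
        flat = col.ravel()  # order: sample0 allele0, sample0 allele1, ...
        code = np.full(flat.shape, MISSING, dtype=np.int8)
        code[flat == a] = 0
        code[flat == b] = 1
        haplo[:, j] = code

    variants = make_variant_table(
        vmap["chrom"], vmap["pos_bp"], vmap["id"], allele_a, allele_b
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    return HaplotypePanel(variants=variants, haplo=haplo, samples=samples, phased=False)


def write_ped_map(
    panel: HaplotypePanel, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a panel as PLINK text PED/MAP (genotypes only; phase dropped)."""
    with open(map_path, "w") as fh:
        for _, v in panel.variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['id']}\t0\t{v['pos_bp']}\n")
    letters = np.stack(
        [panel.variants["allele_a"].to_numpy(), panel.variants["allele_b"].to_numpy()]
    )
    with open(ped_path, "w") as fh:
        for i, s in panel.samples.iterrows():
            h0 = panel.haplo[2 * i]
            h1 = panel.haplo[2 * i + 1]
            cols = []
            for j in range(panel.n_variants):
                a0 = "0" if h0[j] == MISSING else letters[h0[j], j]
                a1 = "0" if h1[j] == MISSING else letters[h1[j], j]
                cols.append(f"{a0} {a1}")
            fh.write(
                f"{s['population']} {s['sample_id']} 0 0 0 -9 " + " ".join(cols) + "\n"
            )


# --------------------------------------------------------------------------- #
# Phased-haplotype TSV trio
# --------------------------------------------------------------------------- #
def write_phased_table(panel: HaplotypePanel, prefix: str | Path) -> None:
    """Write a phased panel as ``<prefix>.haplo.tsv`` + variant/sample sidecars.

    The haplotype table has two rows per sample (columns ``sample_id``,
    ``hap`` then one nucleotide column per marker id); it round-trips
    bit-exactly through :func:`read_phased_table`.
    """
    panel.require_phased()
    prefix = str(prefix)
    letters = np.stack(
        [panel.variants["allele_a"].to_numpy(), panel.variants["allele_b"].to_numpy()]
    )
    nuc = letters[panel.haplo, np.arange(panel.n_variants)[None, :]]
    df = pd.DataFrame(nuc, columns=panel.variants["id"])
    df.insert(0, "hap", np.tile([0, 1], panel.n_samples))
    df.insert(0, "sample_id", np.repeat(panel.samples["sample_id"].to_numpy(), 2))
    df.to_csv(prefix + ".haplo.tsv", sep="\t", index=False)
    panel.variants.to_csv(
        prefix + ".variants.tsv", sep="\t", index=False, float_format="%.17g"
    )
    panel.samples.to_csv(
        prefix + ".samples.tsv", sep="\t", index=False, float_format="%.17g"
    )


def read_phased_table(prefix: str | Path) -> HaplotypePanel:
    """Read the phased TSV trio written by :func:`write_phased_table`."""
    prefix = str(prefix)
    variants = pd.read_csv(prefix + ".variants.tsv", sep="\t", dtype={"chrom": str})
    if "ancestral" not in variants.columns:
        variants["ancestral"] = None
    variants["ancestral"] = variants["ancestral"].where(
        variants["ancestral"].isin(["a", "b"]), None
    )
    samples = pd.read_csv(prefix + ".samples.tsv", sep="\t", dtype={"sample_id": str})
    ht = pd.read_csv(prefix + ".haplo.tsv", sep="\t", dtype=str)
    counts = ht["sample_id"].value_counts()
    bad = counts[counts != 2]
    if len(bad):
        raise ParseError(
            f"{prefix}.haplo.tsv: sample(s) without exactly two haplotype rows: "
            f"{bad.index[:5].tolist()}"
        )
    order = {sid: k for k, sid in enumerate(samples["sample_id"])}
    missing_meta = set(ht["sample_id"]) - set(order)
    if missing_meta:
        raise ParseError(
            f"{prefix}.haplo.tsv: samples missing from sidecar: "
            f"{sorted(missing_meta)[:5]}"
        )
    ht = ht.sort_values(
        ["sample_id", "hap"], key=lambda s: s.map(order) if s.name == "sample_id" else s
    )
    nuc = ht[variants["id"]].to_numpy(dtype="U8")
    haplo = np.full(nuc.shape, MISSING, dtype=np.int8)
    for j, (a, b) in enumerate(
        zip(variants["allele_a"].astype(str), variants["allele_b"].astype(str))
    ):
        col = nuc[:, j]
        haplo[col == a, j] = 0
        haplo[col == b, j] = 1
        stray = ~np.isin(col, (a, b))
        if stray.any():
            raise ParseError(
                f"{prefix}.haplo.tsv: marker {variants['id'].iloc[j]!r} carries "
                f"allele(s) {sorted(set(col[stray]))} not in "
                f"({a!r}, {b!r})"
            )
    return HaplotypePanel(variants=variants, haplo=haplo, samples=samples, phased=True)


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF (all GT fields ``|``-separated) into a panel.

    REF maps to ``allele_a``, ALT to ``allele_b``.  Any ``/``-separated
    (unphased) genotype raises :class:`ParseError`.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, positions, ids, ref, alt = [], [], [], [], []
    columns = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(f"{path}: variant {var.ID or var.POS} is not biallelic")
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            if not g[2]:
                raise ParseError(
                    f"{path}: unphased genotype ('/' separator) for sample "
                    f"{sample_ids[i]} at {var.CHROM}:{var.POS}"
                )
            if g[0] < 0 or g[1] < 0:
                raise ParseError(
                    f"{path}: missing genotype at {var.CHROM}:{var.POS}"
                )
            col[2 * i] = g[0]
            col[2 * i + 1] = g[1]
        chroms.append(var.CHROM)
        positions.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ref.append(var.REF)
        alt.append(var.ALT[0])
        columns.append(col)
    variants = make_variant_table(chroms, positions, ids, ref, alt)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "population": ["unknown"] * len(sample_ids)}
    )
    haplo = np.stack(columns, axis=1) if columns else np.empty((2 * len(sample_ids), 0), dtype=np.int8)
    return HaplotypePanel(variants=variants, haplo=haplo, samples=samples, phased=True)


# --------------------------------------------------------------------------- #
# Ancestral-allele annotation
# --------------------------------------------------------------------------- #
def attach_ancestral(panel: HaplotypePanel, table_path: str | Path) -> HaplotypePanel:
    """Attach ancestral-allele states from a two-column TSV.

    The table maps ``marker_id`` to ``ancestral_allele`` (a nucleotide).
    Markers absent from the table, or whose listed nucleotide matches
    neither declared allele, are flagged unknown (the latter with a logged
    warning); unknown-ancestral SNPs are skipped by the iHS scan but remain
    available to cross-population statistics.
    """
    tab = pd.read_csv(table_path, sep="\t", dtype=str)
    if not {"marker_id", "ancestral_allele"} <= set(tab.columns):
        if tab.shape[1] < 2:
            raise ParseError(f"{table_path}: need columns marker_id, ancestral_allele")
        tab.columns = ["marker_id", "ancestral_allele"] + list(tab.columns[2:])
    lookup = dict(zip(tab["marker_id"], tab["ancestral_allele"]))
    out = panel.copy()
    states: list[str | None] = []
    n_mismatch = 0
    for _, v in out.variants.iterrows():
        anc = lookup.get(v["id"])
        if anc is None:
            states.append(None)
        elif anc == v["allele_a"]:
            states.append("a")
        elif anc == v["allele_b"]:
            states.append("b")
        else:
            n_mismatch += 1
            logger.warning(
                "marker %s: ancestral allele %r matches neither %r nor %r; "
                "flagged unknown",
                v["id"], anc, v["allele_a"], v["allele_b"],
            )
            states.append(None)
    out.variants["ancestral"] = states
    if n_mismatch:
        logger.warning("%d marker(s) with contradictory ancestral alleles", n_mismatch)
    return out


def write_ancestral_table(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel's known ancestral states as a marker/nucleotide TSV."""
    letters = np.stack(
        [panel.variants["allele_a"].to_numpy(), panel.variants["allele_b"].to_numpy()]
    )
    rows = []
    for j, anc in enumerate(panel.variants["ancestral"]):
        if anc in ("a", "b"):
            rows.append((panel.variants["id"].iloc[j], letters[0 if anc == "a" else 1, j]))
    pd.DataFrame(rows, columns=["marker_id", "ancestral_allele"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------- #
# Quality control
# --------------------------------------------------------------------------- #
@dataclass
class QCReport:
    """Accounting of a QC pass: input/kept counts and per-filter removals.

    Filters are applied sequentially (sample missingness → call rate → HWE →
    MAF), so each SNP is counted against the first filter that removes it and
    ``n_kept + sum(removed_snps.values()) == n_input_snps``.
    """

    n_input_snps: int
    n_kept_snps: int
    n_input_samples: int
    n_kept_samples: int
    removed_snps: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("input_snps", self.n_input_snps),
            ("kept_snps", self.n_kept_snps),
            ("input_samples", self.n_input_samples),
            ("kept_samples", self.n_kept_samples),
        ]
        rows += [(f"removed_{k}", v) for k, v in self.removed_snps.items()]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def qc_filter(
    panel: HaplotypePanel,
    hwe_p: float = 1e-4,
    min_call: float = 0.90,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
) -> tuple[HaplotypePanel, QCReport]:
    """Apply standard SNP-chip QC and return the filtered panel plus a report.

    Filters, in order:

    1. samples with per-individual missingness > ``max_missing`` removed;
    2. SNPs with call rate < ``min_call`` removed;
    3. SNPs out of Hardy–Weinberg equilibrium (exact-test p < ``hwe_p``)
       removed — the test runs within each population separately and a SNP
       is dropped if it fails in any population present in the panel;
    4. SNPs with minor allele frequency < ``min_maf`` removed.

    Raises ``PanelError`` if nothing survives.  Idempotent: a second pass
    removes nothing.
    """
    n_input_snps = panel.n_variants
    n_input_samples = panel.n_samples

    # 1. per-individual missingness
    miss_by_sample = (panel.haplo == MISSING)[0::2] | (panel.haplo == MISSING)[1::2]
    ind_missing = miss_by_sample.mean(axis=1) if panel.n_variants else np.zeros(panel.n_samples)
    keep_samples = ind_missing <= max_missing
    work = panel.take_samples(keep_samples) if not keep_samples.all() else panel

    # 2. per-SNP call rate
    called = (work.haplo[0::2] != MISSING) & (work.haplo[1::2] != MISSING)
    call_rate = called.mean(axis=0) if work.n_samples else np.zeros(work.n_variants)
    fail_call = call_rate < min_call

    # 3. HWE within each population
    fail_hwe = np.zeros(work.n_variants, dtype=bool)
    for pop in work.samples["population"].unique():
        sub = work.take_samples((work.samples["population"] == pop).to_numpy())
        counts = sub.genotype_counts()
        for j in range(sub.n_variants):
            if fail_call[j] or fail_hwe[j]:
                continue
            p = hwe_exact_test(counts[j, 0], counts[j, 1], counts[j, 2])
            if p < hwe_p:
                fail_hwe[j] = True
    fail_hwe &= ~fail_call

    # 4. MAF
    maf = work.maf()
    fail_maf = (np.nan_to_num(maf) < min_maf) & ~fail_call & ~fail_hwe

    keep = ~(fail_call | fail_hwe | fail_maf)
    if not keep.any():
        raise PanelError("no SNPs survive QC")
    out = work.take_variants(keep)

    report = QCReport(
        n_input_snps=n_input_snps,
        n_kept_snps=out.n_variants,
        n_input_samples=n_input_samples,
        n_kept_samples=out.n_samples,
        removed_snps={
            "call_rate": int(fail_call.sum()),
            "hwe": int(fail_hwe.sum()),
            "maf": int(fail_maf.sum()),
        },
        thresholds={
            "hwe_p": hwe_p,
            "min_call": min_call,
            "max_missing": max_missing,
            "min_maf": min_maf,
        },
    )
    logger.info(
        "QC: %d/%d SNPs kept (%d call-rate, %d HWE, %d MAF removed); "
        "%d/%d samples kept",
        report.n_kept_snps, report.n_input_snps,
        *report.removed_snps.values(),
        report.n_kept_samples, report.n_input_samples,
    )
    return out, report
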