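"""End-to-end orchestration: sim → QC → iHS/Rsb/Fst/MDS → GWAS → trends.

A :class:`RunConfig` drives the whole run; every stage writes TSV outputs
into the run directory and the final manifest (JSON) records package
version, seeds, thresholds, record counts and SHA-256 checksums of every
output, so a rerun with the same config and seed is bit-identical and
verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ehh_core import scan_ihs
from .genotype_io import attach_ancestral, qc_filter, read_phased_table, write_phased_table
from .haplo_trends import cohort_trend, ld_matrix
from .mlm_gwas import mlm_loco_scan
from .sweep_sim import SweepSimConfig, simulate
from .xpop_stats import classical_mds, compute_fst, scan_rsb

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Defaults follow standard chip QC practice (HWE exact p < 1e-4, call
    rate >= 0.90, individual missingness <= 0.10, MAF >= 0.01) and the
    piHS > 6 significance rule; the Rsb threshold mirrors the piHS one.
    """

    out_dir: str = "sweepscan_run"
    # either simulate ...
    sim: SweepSimConfig | None = None
    # ... or load phased TSV trios written by write_phased_table
    panel_sel_prefix: str | None = None
    panel_unsel_prefix: str | None = None
    ancestral_table: str | None = None
    # QC
    hwe_p: float = 1e-4
    min_call: float = 0.90
    max_missing: float = 0.10
    min_maf: float = 0.01
    # EHH-family statistics
    ehh_cutoff: float = 0.05
    freq_bin: float = 0.025
    ihs_threshold: float = 6.0
    rsb_threshold: float = 6.0
    max_extension_bp: float | None = None
    # downstream
    mds_dims: int = 4
    gwas_traits: list[str] = field(default_factory=list)
    trend_traits: list[str] = field(default_factory=list)
    ld_window_bp: float = 500_000.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("sim") is not None:
            raw["sim"] = SweepSimConfig.from_dict(raw["sim"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the report directory.

    Any stage failure raises ``RuntimeError`` naming the stage; outputs of
    completed stages stay on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sweepscan",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "hwe_p": config.hwe_p,
            "min_call": config.min_call,
            "max_missing": config.max_missing,
            "min_maf": config.min_maf,
            "ehh_cutoff": config.ehh_cutoff,
            "freq_bin": config.freq_bin,
            "ihs_threshold": config.ihs_threshold,
            "rsb_threshold": config.rsb_threshold,
            "ld_window_bp": config.ld_window_bp,
        },
        "stages": {},
        "outputs": {},
    }
    stage = "setup"
    truth = None
    try:
        # ------------------------------------------------------------ sim/load
        if config.sim is not None:
            stage = "sim"
            sim_cfg = dataclasses.replace(config.sim, seed=config.sim.seed or config.seed)
            result = simulate(sim_cfg)
            panel_sel, panel_unsel = result.panel_sel, result.panel_unsel
            truth = result.truth
            write_phased_table(panel_sel, out / "panel_selected")
            write_phased_table(panel_unsel, out / "panel_unselected")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "focal_index": truth.focal_index,
                        "focal_id": truth.focal_id,
                        "s": truth.s,
                        "h": truth.h,
                        "focal_traj_sel": truth.focal_traj_sel,
                        "focal_traj_unsel": truth.focal_traj_unsel,
                        "focal_freq_by_decade": truth.focal_freq_by_decade,
                    },
                    fh,
                    indent=1,
                )
            manifest["stages"]["sim"] = {
                "n_sel": panel_sel.n_samples,
                "n_unsel": panel_unsel.n_samples,
                "n_snps": panel_sel.n_variants,
                "focal_id": truth.focal_id,
            }
        else:
            stage = "load"
            if not (config.panel_sel_prefix and config.panel_unsel_prefix):
                raise ValueError("need either a sim config or two panel prefixes")
            panel_sel = read_phased_table(config.panel_sel_prefix)
            panel_unsel = read_phased_table(config.panel_unsel_prefix)
            if config.ancestral_table:
                panel_sel = attach_ancestral(panel_sel, config.ancestral_table)
                panel_unsel = attach_ancestral(panel_unsel, config.ancestral_table)
            manifest["stages"]["load"] = {
                "n_sel": panel_sel.n_samples,
                "n_unsel": panel_unsel.n_samples,
            }

        # ------------------------------------------------------------ QC
        stage = "qc"
        qc_panels = {}
        for label, panel in (("selected", panel_sel), ("unselected", panel_unsel)):
            filtered, report = qc_filter(
                panel,
                hwe_p=config.hwe_p,
                min_call=config.min_call,
                max_missing=config.max_missing,
                min_maf=config.min_maf,
            )
            report.write(out / f"qc_{label}.tsv")
            qc_panels[label] = filtered
            manifest["stages"][f"qc_{label}"] = {
                "n_input": report.n_input_snps,
                "n_kept": report.n_kept_snps,
                "removed": report.removed_snps,
            }
        panel_sel, panel_unsel = qc_panels["selected"], qc_panels["unselected"]

        # ------------------------------------------------------------ iHS
        stage = "ihs"
        for label, panel in (("selected", panel_sel), ("unselected", panel_unsel)):
            scan = scan_ihs(
                panel,
                min_maf=config.min_maf,
                cutoff=config.ehh_cutoff,
                freq_bin=config.freq_bin,
                max_extension_bp=config.max_extension_bp,
                threshold=config.ihs_threshold,
            )
            scan.to_csv(out / f"ihs_{label}.tsv", sep="\t", index=False)
            manifest["stages"][f"ihs_{label}"] = {
                "n_scored": int(scan["std_ihs"].notna().sum()),
                "n_significant": int(scan["significant"].sum()),
            }

        # ------------------------------------------------------------ Rsb
        stage = "rsb"
        rsb = scan_rsb(
            panel_sel,
            panel_unsel,
            cutoff=config.ehh_cutoff,
            max_extension_bp=config.max_extension_bp,
            threshold=config.rsb_threshold,
        )
        rsb.to_csv(out / "rsb.tsv", sep="\t", index=False)
        manifest["stages"]["rsb"] = {
            "numerator": rsb.attrs.get("numerator"),
            "denominator": rsb.attrs.get("denominator"),
            "n_scored": int(rsb["std_rsb"].notna().sum()),
            "n_significant": int(rsb["significant"].sum()),
        }

        # ------------------------------------------------------------ Fst + MDS
        stage = "fst"
        fst = compute_fst(panel_sel, panel_unsel)
        fst.per_snp.to_csv(out / "fst.tsv", sep="\t", index=False)
        manifest["stages"]["fst"] = {"genome_wide": fst.genome_wide}

        stage = "mds"
        shared = [
            mid for mid in panel_sel.variants["id"]
            if mid in set(panel_unsel.variants["id"])
        ]
        sel_shared = panel_sel.take_variants(
            panel_sel.variants["id"].isin(shared).to_numpy()
        )
        unsel_shared = panel_unsel.take_variants(
            panel_unsel.variants["id"].isin(shared).to_numpy()
        )
        mds = classical_mds([sel_shared, unsel_shared], dims=config.mds_dims)
        import pandas as pd

        coords = pd.DataFrame(
            mds.coordinates,
            columns=[f"dim{i+1}" for i in range(mds.coordinates.shape[1])],
        )
        coords.insert(0, "sample_id", mds.sample_ids)
        coords.to_csv(out / "mds.tsv", sep="\t", index=False)
        manifest["stages"]["mds"] = {
            "dims": int(mds.coordinates.shape[1]),
            "eigenvalues": [float(v) for v in mds.eigenvalues],
        }

        # ------------------------------------------------------------ GWAS
        traits = [t for t in config.gwas_traits if t in panel_sel.samples.columns]
        for trait in traits:
            stage = f"gwas:{trait}"
            assoc = mlm_loco_scan(panel_sel, panel_sel.samples[trait].to_numpy())
            assoc.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            manifest["stages"][f"gwas_{trait}"] = {
                "n_tested": int(assoc["p"].notna().sum()),
                "min_p": float(assoc["p"].min()),
            }

        # ------------------------------------------------------------ trends
        if "cohort_decade" in panel_sel.samples.columns and truth is not None:
            stage = "trends"
            trend_traits = [
                t for t in (config.trend_traits or config.gwas_traits)
                if t in panel_sel.samples.columns
            ]
            trend = cohort_trend(panel_sel, [truth.focal_id], trend_traits)
            trend.allele_freq.to_csv(out / "trend_allele_freq.tsv", sep="\t", index=False)
            trend.ebv.to_csv(out / "trend_ebv.tsv", sep="\t", index=False)
            manifest["stages"]["trends"] = {
                "n_decades": int(trend.allele_freq["decade"].nunique())
            }

        # ------------------------------------------------------------ LD near focal
        if truth is not None:
            stage = "ld"
            chrom = str(panel_sel.variants["chrom"].iloc[0])
            focal_pos = None
            hit = panel_sel.variants["id"] == truth.focal_id
            if hit.any():
                focal_pos = int(panel_sel.variants.loc[hit, "pos_bp"].iloc[0])
                ld = ld_matrix(
                    panel_sel,
                    window=(
                        chrom,
                        focal_pos - config.ld_window_bp,
                        focal_pos + config.ld_window_bp,
                    ),
                    max_dist_bp=config.ld_window_bp,
                )
                ld.to_frame().to_csv(out / "ld_focal.tsv", sep="\t", index=False)
                manifest["stages"]["ld"] = {"n_pairs": len(ld.to_frame())}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if path.name == "manifest.json":
            continue
        manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
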