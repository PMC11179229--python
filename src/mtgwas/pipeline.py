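"""End-to-end orchestration: filters -> kinship -> stage 1 -> null model ->
LOCO GLS scan -> classification -> per-SNP refits -> LD on hits.

The pipeline operates on in-memory objects (a :class:`GenotypeMatrix`,
plot-level trial tables and/or a line x trait BLUE matrix) and writes every
stage's table plus a JSON manifest to an output directory, so a run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    GenotypeMatrix,
    compute_maf,
    filter_snps,
    impute_mode,
    loco_grms,
    vanraden_grm,
    write_kinship_tsv,
)
from .ld import ld_neighborhood
from .multitrait import reml_null, select_structure
from .scan import (
    LD_EXTENT_BP,
    SORGHUM_GENOME_BP,
    bonferroni_threshold,
    classify_associations,
    gls_scan,
    refit_snp,
)
from .simulate import DesignSpec
from .trials import cullis_h2, fit_trial, standardize_traits

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "TrialInput", "run_pipeline", "report_summary"]


@dataclass
class TrialInput:
    """Plot-level records plus the design they were collected under."""

    records: pd.DataFrame
    design: DesignSpec
    log_transform: bool = False


@dataclass
class RunConfig:
    """Thresholds and settings of one association-mapping run.

    Defaults: MAF 0.01 for panel characterization, MAF 0.025 and 20%
    missingness for the GWAS marker set, alpha 0.05 with a 150-kb LD extent
    over the ten-chromosome sorghum assembly total for the significance
    threshold, and a fixed suggestive threshold of 4.0.
    """

    maf_characterization: float = 0.01
    maf_gwas: float = 0.025
    missing_max: float = 0.20
    alpha: float = 0.05
    ld_extent_bp: float = LD_EXTENT_BP
    genome_length_bp: float = SORGHUM_GENOME_BP
    structures: tuple[str, ...] = ("FA1", "FA2", "UNS")
    threshold_sug: float = 4.0
    ld_window_bp: int = 2_000_000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.maf_gwas <= 0.5 or not 0 <= self.maf_characterization <= 0.5:
            raise ValueError("MAF thresholds must be in [0, 0.5]")
        if not 0 <= self.missing_max <= 1:
            raise ValueError("missing_max must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def threshold_sig(self) -> float:
        return bonferroni_threshold(
            self.alpha, self.genome_length_bp, self.ld_extent_bp
        )


def run_pipeline(
    cfg: RunConfig,
    G: GenotypeMatrix,
    trials: dict[str, TrialInput] | None = None,
    blues: pd.DataFrame | None = None,
) -> dict:
    """Execute every stage and return the run artifacts.

    Either ``trials`` (plot-level data per trait, fitted in stage 1) or
    ``blues`` (a ready line x trait matrix of adjusted means) must be given.
    Tables are written under ``cfg.outdir`` when set; partial outputs are
    retained if a later stage raises.
    """
    if not cfg.structures:
        raise ValueError("no covariance structure candidates configured")
    if trials is None and blues is None:
        raise ValueError("need plot-level trials or a BLUE matrix")
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    art: dict = {"config": asdict(cfg)}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # --- marker filters -----------------------------------------------------
    _stage("filter")
    n_input = G.n_snps
    G_gwas = filter_snps(G, cfg.maf_gwas, cfg.missing_max)
    G_gwas = impute_mode(G_gwas)
    art["n_snps_input"] = n_input
    art["n_snps_gwas"] = G_gwas.n_snps
    art["snp_info"] = compute_maf(G_gwas)

    # --- kinship ------------------------------------------------------------
    _stage("kinship")
    K_full = vanraden_grm(G_gwas)
    loco = loco_grms(G_gwas)
    if outdir:
        write_kinship_tsv(K_full, outdir / "kinship_full.tsv")

    # --- stage 1 ------------------------------------------------------------
    h2_rows = []
    if trials is not None:
        _stage("stage1")
        blue_cols = {}
        for trait, ti in trials.items():
            fr = fit_trial(ti.records, ti.design, line_as="random",
                           log_transform=ti.log_transform)
            h2 = cullis_h2(fr)
            ff = fit_trial(ti.records, ti.design, line_as="fixed",
                           log_transform=ti.log_transform)
            blue_cols[trait] = ff.blues
            h2_rows.append(
                {"trait": trait, "H2": h2.h2, "vbar_blup": h2.vbar_blup,
                 "sigma_g2": fr.sigma_g2, "sigma_e2": fr.sigma_e2}
            )
        blues = pd.DataFrame(blue_cols)
    assert blues is not None
    blues = blues.reindex([str(l) for l in G_gwas.line_ids])
    art["h2"] = pd.DataFrame(h2_rows)
    if outdir:
        blues.to_csv(outdir / "blues.csv", index_label="line")
        art["h2"].to_csv(outdir / "heritability.tsv", sep="\t", index=False)

    # --- standardize and null fits -------------------------------------------
    _stage("standardize")
    Y = standardize_traits(blues)
    _stage("null")
    fits = [reml_null(Y, K_full, s) for s in cfg.structures]
    best = select_structure(fits) if len(fits) > 1 else fits[0]
    art["null_fits"] = {f.structure: f.to_dict() for f in fits}
    art["selected_structure"] = best.structure
    art["null_fit"] = best
    if outdir:
        (outdir / "null_fits.json").write_text(
            json.dumps(art["null_fits"], indent=2)
        )

    # --- scan ----------------------------------------------------------------
    _stage("scan")
    scan = gls_scan(Y, G_gwas, best, loco)
    scan = classify_associations(scan, cfg.threshold_sig, cfg.threshold_sug)
    art["scan"] = scan
    if outdir:
        scan.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        scan[["chrom", "pos", "minus_log10_p"]].to_csv(
            outdir / "manhattan.tsv", sep="\t", index=False
        )

    # --- refits of hits -------------------------------------------------------
    _stage("refit")
    hits = scan.loc[scan["classification"] != "none"]
    info = compute_maf(G_gwas).set_index("snp")
    snp_col = {s: j for j, s in enumerate(G_gwas.snp_map["snp"])}
    refits, refit_rows = [], []
    for _, row in hits.iterrows():
        j = snp_col[row["snp"]]
        res = refit_snp(
            Y,
            G_gwas.calls[:, j],
            K_full,
            best.structure,
            snp_id=row["snp"],
            classification=row["classification"],
            null_fit=best,
            maf=float(info.at[row["snp"], "maf"]),
        )
        refits.append(res)
        for trait, r in res.effects.iterrows():
            refit_rows.append(
                {"snp": res.snp, "chrom": row["chrom"], "pos": row["pos"],
                 "classification": res.classification, "trait": trait, **r}
            )
    art["refits"] = refits
    art["refit_table"] = pd.DataFrame(refit_rows)
    if outdir and refit_rows:
        art["refit_table"].to_csv(outdir / "snp_effects.tsv", sep="\t", index=False)

    # --- LD around hits --------------------------------------------------------
    _stage("ld")
    if len(hits):
        ld = ld_neighborhood(G_gwas, hits["snp"].tolist(), cfg.ld_window_bp)
    else:
        ld = pd.DataFrame(
            columns=["snp_a", "snp_b", "chrom", "dist_bp", "r2", "fisher_p"]
        )
    art["ld"] = ld
    if outdir:
        ld.to_csv(outdir / "ld_hits.tsv", sep="\t", index=False)

    # --- manifest ---------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "maf_characterization": cfg.maf_characterization,
            "maf_gwas": cfg.maf_gwas,
            "missing_max": cfg.missing_max,
            "alpha": cfg.alpha,
            "ld_extent_bp": cfg.ld_extent_bp,
            "genome_length_bp": cfg.genome_length_bp,
            "threshold_sig": cfg.threshold_sig,
            "threshold_sug": cfg.threshold_sug,
            "ld_window_bp": cfg.ld_window_bp,
        },
        "structures": list(cfg.structures),
        "selected_structure": best.structure,
        "counts": {
            "lines": G_gwas.n_lines,
            "snps_input": n_input,
            "snps_gwas": G_gwas.n_snps,
            "traits": int(Y.shape[1]),
            "significant": int((scan["classification"] == "significant").sum()),
            "suggestive": int((scan["classification"] == "suggestive").sum()),
        },
    }
    art["manifest"] = manifest
    if outdir:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return art


def report_summary(art: dict) -> str:
    """Human-readable run summary: per-chromosome hit counts, favorable-allele
    tally, mean variance explained per trait, selected structure."""
    scan: pd.DataFrame = art["scan"]
    lines = []
    lines.append(f"selected covariance structure: {art['selected_structure']}")
    thr = art["manifest"]["thresholds"]
    lines.append(
        f"thresholds: significant >= {thr['threshold_sig']:.2f}, "
        f"suggestive >= {thr['threshold_sug']:.2f}"
    )
    counts = art["manifest"]["counts"]
    lines.append(
        f"{counts['significant']} significant and {counts['suggestive']} "
        f"suggestive SNPs over {counts['snps_gwas']} markers"
    )
    lines.append("per-chromosome hits (significant/suggestive):")
    if len(scan):
        for chrom, grp in scan.groupby("chrom", sort=False):
            ns = int((grp["classification"] == "significant").sum())
            nu = int((grp["classification"] == "suggestive").sum())
            lines.append(f"  {chrom}: {ns}/{nu}")
    rt: pd.DataFrame = art.get("refit_table", pd.DataFrame())
    if len(rt):
        fav = rt.groupby("snp")["favorable_allele"].agg(
            lambda s: s.value_counts().idxmax()
        )
        n_minor = int((fav == "minor").sum())
        n_major = int((fav == "major").sum())
        lines.append(f"favorable allele: minor for {n_minor} SNPs, major for {n_major}")
        mean_ve = rt.groupby("trait")["pct_var_explained"].mean()
        lines.append("mean % variance explained per trait (associated SNPs):")
        for trait, v in mean_ve.items():
            lines.append(f"  {trait}: {v:.2f}")
    return "\n".join(lines)
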