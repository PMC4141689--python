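"""End-to-end two-stage GWAS: QC -> SMMA scan -> prescreen -> MEML -> thresholds.

``run_two_stage`` reproduces the standard analysis flow: quality control and
mean imputation, REML null fit, a genome-wide single-marker mixed-model scan,
selection of the ``top_k`` SNPs with the smallest p-values, the joint
multi-SNP EM fit on that subset, permutation thresholds for both statistics
(-log10 p for SMMA, SNP heritability for MEML), and a significant-SNP table.
Every stage writes a TSV and a machine-readable manifest records seeds,
thresholds and counts, sufficient to reproduce the run byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_pedigree_csv, read_phenotype_tsv, read_plink_text
from .kinship import AMatrix, a_matrix
from .meml import MEMLConfig, MEMLFit, fit_meml
from .panel import PedigreeTable, PhenotypeVector, SNPPanel, mean_impute, qc_filter
from .permutation import permutation_threshold
from .smma import SMMAScanner, fit_null_reml, prescreen, smma_scan

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class GwasRunConfig:
    """Inputs and knobs for one two-stage run (single trait)."""

    out_dir: str | Path = "gwas_out"
    ped_path: str | Path | None = None
    map_path: str | Path | None = None
    pheno_path: str | Path | None = None
    pedigree_path: str | Path | None = None
    ind_missing_max: float = 0.10
    call_rate_min: float = 0.90
    maf_min: float = 0.03
    hwe_p_min: float = 1e-6
    top_k: int = 500
    n_perm: int = 1000
    alpha: float = 0.05
    meml: MEMLConfig = field(default_factory=MEMLConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise PipelineError("top_k must be >= 1")


@dataclass
class GwasRunResult:
    smma_table: pd.DataFrame
    meml_table: pd.DataFrame
    significant: pd.DataFrame       # columns: snp, chrom, pos, h2
    smma_threshold: float           # on -log10 p
    meml_threshold: float           # on h2
    manifest: dict
    meml_fit: MEMLFit


def run_two_stage(config: GwasRunConfig,
                  panel: SNPPanel | None = None,
                  phenotype: PhenotypeVector | None = None,
                  pedigree: PedigreeTable | None = None) -> GwasRunResult:
    """Run the full two-stage analysis; inputs may be in-memory or file paths."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if panel is None:
            panel = read_plink_text(config.ped_path, config.map_path)
        if phenotype is None:
            phenotype = read_phenotype_tsv(config.pheno_path)
        if pedigree is None:
            pedigree = read_pedigree_csv(config.pedigree_path)

        stage = "qc"
        panel_qc, qc_report = qc_filter(
            panel, ind_missing_max=config.ind_missing_max,
            call_rate_min=config.call_rate_min, maf_min=config.maf_min,
            hwe_p_min=config.hwe_p_min)
        phenotype, panel_qc = phenotype.aligned_to(panel_qc)
        X, freq = mean_impute(panel_qc)

        stage = "kinship"
        A_full = a_matrix(pedigree)
        A = A_full.submatrix(panel_qc.individual_ids)

        stage = "reml"
        vc = fit_null_reml(phenotype.values, A)

        stage = "smma"
        smma_res = smma_scan(phenotype.values, panel_qc, A, vc, X=X)
        smma_res.table.to_csv(out / "smma.tsv", sep="\t", index=False)

        stage = "prescreen"
        k = min(config.top_k, int(smma_res.table["tested"].sum()))
        idx = prescreen(smma_res, k=config.top_k)

        stage = "meml"
        Xs = X[:, idx]
        fit = fit_meml(phenotype.values, None, A, config.meml, X=Xs, snp_freq=freq[idx])
        meml_table = pd.DataFrame({
            "snp": panel_qc.snp_map["name"].to_numpy()[idx],
            "chrom": panel_qc.snp_map["chrom"].to_numpy()[idx],
            "pos": panel_qc.snp_map["pos"].to_numpy()[idx],
            "gamma": fit.state.gamma,
            "h2": fit.heritabilities,
        })

        stage = "permutation"
        scanner = SMMAScanner(X, A, vc)
        smma_perm = permutation_threshold(
            phenotype.values, scanner.neg_log10_p_stat,
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed)

        def h2_stat(yp: np.ndarray) -> np.ndarray:
            return fit_meml(yp, None, A, config.meml, X=Xs,
                            snp_freq=freq[idx]).heritabilities

        meml_perm = permutation_threshold(
            phenotype.values, h2_stat, n_perm=config.n_perm,
            alpha=config.alpha, seed=config.seed)
        pd.DataFrame({"smma_max_neglog10p": smma_perm.null_maxima,
                      "meml_max_h2": meml_perm.null_maxima}).to_csv(
            out / "null_maxima.tsv", sep="\t", index=False)

        stage = "report"
        meml_table["significant"] = (meml_table["h2"] > meml_perm.threshold).astype(int)
        meml_table.to_csv(out / "meml.tsv", sep="\t", index=False)
        significant = meml_table.loc[meml_table["significant"] == 1,
                                     ["snp", "chrom", "pos", "h2"]].reset_index(drop=True)
        significant.to_csv(out / "significant.tsv", sep="\t", index=False)

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
            "top_k": config.top_k,
            "prescreened": int(len(idx)),
            "qc": {
                "individuals_removed": qc_report.n_individuals_removed,
                "snps_removed_callrate": qc_report.n_snps_removed_callrate,
                "snps_removed_maf": qc_report.n_snps_removed_maf,
                "snps_removed_hwe": qc_report.n_snps_removed_hwe,
                "snps_surviving": len(qc_report.surviving_snp_names),
            },
            "n_individuals": panel_qc.n_individuals,
            "variance_components": {"sigma_g2": float(vc.sigma_g2),
                                    "sigma_e2": float(vc.sigma_e2),
                                    "boundary": bool(vc.boundary),
                                    "identifiable": bool(vc.identifiable)},
            "meml": {"a": config.meml.a, "b": config.meml.b, "tol": config.meml.tol,
                     "max_iter": config.meml.max_iter,
                     "n_iterations": fit.n_iterations, "converged": fit.converged},
            "thresholds": {"smma_neglog10p": float(smma_perm.threshold),
                           "meml_h2": float(meml_perm.threshold)},
            "n_significant": int(len(significant)),
            "runtime_s": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    except Exception as e:
        raise PipelineError(f"two-stage pipeline failed at stage {stage!r}: {e}") from e

    logger.info("two-stage run finished in %.1fs (%d significant SNPs)",
                time.time() - t0, len(significant))
    return GwasRunResult(smma_table=smma_res.table, meml_table=meml_table,
                         significant=significant,
                         smma_threshold=smma_perm.threshold,
                         meml_threshold=meml_perm.threshold,
                         manifest=manifest, meml_fit=fit)


def needle_plot(meml_table: pd.DataFrame, threshold: float, path: str | Path) -> None:
    """Per-chromosome needle plot of SNP heritabilities with the threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = meml_table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(9, 3))
    x = np.arange(len(tab))
    ax.vlines(x, 0, tab["h2"], lw=0.8)
    ax.axhline(threshold, ls=":", color="red", label=f"permutation threshold")
    for chrom, grp in tab.groupby("chrom"):
        ax.axvline(grp.index.max() + 0.5, ls=":", color="grey", lw=0.5)
    ax.set_xlabel("SNP (genome order)")
    ax.set_ylabel("SNP heritability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def nearest_features(significant: pd.DataFrame, bed_path: str | Path,
                     window: int = 200_000) -> pd.DataFrame:
    """Convenience stub: nearest BED feature within ``window`` bp of each SNP.

    Expects a plain BED file (chrom, start, end, name).  Purely annotational;
    not part of the statistical pipeline.
    """
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name"])
    rows = []
    for _, snp in significant.iterrows():
        feats = bed[bed["chrom"].astype(str) == str(snp["chrom"])]
        if feats.empty:
            rows.append((snp["snp"], None, np.nan))
            continue
        dist = np.where((snp["pos"] >= feats["start"]) & (snp["pos"] <= feats["end"]),
                        0, np.minimum(np.abs(feats["start"] - snp["pos"]),
                                      np.abs(feats["end"] - snp["pos"])))
        k = int(np.argmin(dist))
        if dist[k] <= window:
            rows.append((snp["snp"], feats.iloc[k]["name"], int(dist[k])))
        else:
            rows.append((snp["snp"], None, np.nan))
    return pd.DataFrame(rows, columns=["snp", "feature", "distance"])
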