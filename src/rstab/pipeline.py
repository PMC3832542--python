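"""End-to-end orchestration: score -> PCA -> GWAS -> permutation -> eQTL.

``simulate_study`` writes a complete synthetic study to disk in the same
formats the readers consume, so a simulated study round-trips through the
full pipeline. ``run_pipeline`` executes the analysis on any study bundle
and writes the report files; any stage failure aborts with the failing
stage named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import association, eqtl, io, simulate, stability
from .config import PipelineConfig, SimulationConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate a synthetic study and write it as a pipeline-ready bundle.

    Writes genotypes.tsv, expression.tsv, halflife.tsv, annotation.tsv and
    covariates.tsv (sample sex) plus the simulation config used.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = simulate.simulate_genotypes(config)
    halflife = simulate.simulate_halflife_table(config)
    expr = simulate.simulate_expression(genotypes, halflife, config)

    io.write_genotypes_tsv(genotypes, out / "genotypes.tsv")
    io.write_expression(expr, out / "expression.tsv")
    io.write_halflife(halflife[["half_life_h", "source"]], out / "halflife.tsv")
    annot = halflife.rename_axis("gene_id")
    io.write_annotation(annot, out / "annotation.tsv")
    io.write_covariates(genotypes.samples[["sex"]], out / "covariates.tsv")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
    return out


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``.

    Stages: read inputs, classify genes, compute RS-scores, MAF-filter
    genotypes, genotype PCA, covariate-adjusted GWAS with genomic-lambda
    diagnostic and Bonferroni adjustment, min-p permutation test, then cis
    and trans eQTL scans for the top SNP. Returns the report bundle as a
    dict and writes all report files to ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, exc) from exc

    genotypes = stage("read_genotypes", io.read_genotypes, config.genotypes,
                      config.genotype_format)
    expr = stage("read_expression", io.read_expression, config.expression)
    halflife = stage("read_halflife", io.read_halflife, config.halflife)
    annot = stage("read_annotation", io.read_annotation, config.annotation)
    sex_cov: Optional[pd.DataFrame] = None
    if config.covariates is not None:
        sex_cov = stage("read_covariates", io.read_covariates, config.covariates)

    class_table = annot if config.scheme in ("housekeeping", "coding") else halflife
    cls = stage("classify_genes", stability.classify_genes, class_table,
                config.scheme, config.threshold_hours)
    scores = stage("rs_score", stability.rs_score, expr, cls)

    filtered = stage("maf_filter", association.maf_filter, genotypes, config.maf_threshold)
    pcs = stage("genotype_pca", association.genotype_pca, filtered, config.n_pcs)
    if sex_cov is not None and "sex" in sex_cov.columns:
        covariates = pcs.join(sex_cov[["sex"]], how="inner")
    else:
        covariates = pcs

    assoc = stage("gwas_scan", association.gwas_scan, filtered, scores, covariates)
    lam = stage("genomic_lambda", association.genomic_lambda,
                assoc["p_value"].dropna().to_numpy())
    perm = stage(
        "permutation_minp", association.permutation_minp,
        filtered, scores, covariates, config.n_perm, config.seed,
    )

    top_snp_id = assoc.index[0]
    top_dosage = filtered.dosages.loc[top_snp_id]
    cis = stage("cis_window_scan", eqtl.cis_window_scan,
                filtered.snps.loc[top_snp_id], top_dosage, expr, annot, config.cis_window)
    trans = stage("trans_eqtl_scan", eqtl.trans_eqtl_scan,
                  top_dosage, expr, config.fdr_threshold)

    io.write_scores(scores, out / "rs_scores.tsv")
    io.write_classification(cls, out / "classification.tsv")
    io.write_association(assoc, out / "association.tsv")
    io.write_manhattan_table(assoc, out / "manhattan.tsv")
    io.write_covariates(covariates, out / "covariates_used.tsv")
    io.write_eqtl(cis, top_snp_id, out / "eqtl_cis.tsv")
    io.write_eqtl(trans, top_snp_id, out / "eqtl_trans.tsv")

    summary = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_samples": int(len(scores)),
        "n_snps_tested": int(len(assoc)),
        "n_genes_classified": int(len(cls)),
        "top_snp": str(top_snp_id),
        "top_snp_p": float(assoc["p_value"].iloc[0]),
        "top_snp_bonferroni_p": float(assoc["bonferroni_p"].iloc[0]),
        "genomic_lambda": float(lam),
        "permutation_p": perm.permutation_p,
        "observed_min_p": perm.observed_min_p,
        "n_perm": perm.n_perm,
        "n_trans_associated": int(trans["associated"].sum()),
        "thresholds": {
            "scheme": config.scheme,
            "threshold_hours": config.threshold_hours,
            "maf_threshold": config.maf_threshold,
            "n_pcs": config.n_pcs,
            "n_perm": config.n_perm,
            "fdr_threshold": config.fdr_threshold,
            "cis_window": config.cis_window,
        },
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(out / "run.log", "w") as fh:
        fh.write(f"rstab {__version__}; seed={config.seed}; config_hash={summary['config_hash']}\n")
        for k, v in summary["thresholds"].items():
            fh.write(f"{k}={v}\n")
        fh.write(perm.summary() + "\n")
    return summary
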