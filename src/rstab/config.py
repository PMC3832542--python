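"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study generator.

    The generator emulates the structure of a multi-population LCL expression
    study: genotypes in Hardy-Weinberg proportions with Balding-Nichols
    allele-frequency divergence between populations, a long/short half-life
    dichotomy at 4 hours, and a single trans-acting causal SNP whose minor
    allele dosage shifts the log-expression of long-lived transcripts.

    Parameters
    ----------
    n_samples : samples per population.
    n_pops : number of populations.
    fst : Balding-Nichols divergence parameter in [0, 1); 0 means no structure.
    n_snps : number of independent SNPs.
    maf_range : (low, high) ancestral minor-allele frequency range in (0, 0.5].
    n_genes : number of genes.
    frac_long : fraction of genes designated long-lived (half-life >= 4 h).
    causal_snp_index : index of the causal SNP, or None for the global null.
    effect_size : shift in log-expression of long-lived genes per unit of
        causal minor-allele dosage.
    noise_sd : residual standard deviation on the log-expression scale.
    baseline_sd : standard deviation of per-gene log-expression baselines.
    sex_effect : additive shift of long-lived gene log-expression in samples
        with sex code 1 (default 0: no sex bias).
    pop_shift : additive shift of long-lived gene log-expression per
        population index (default 0); a non-zero value injects a
        population-correlated phenotype confound.
    enrichment_odds : odds ratio by which long-lived genes are enriched for
        housekeeping and coding status.
    n_chroms : number of chromosomes in the synthetic genome.
    chrom_length : length (bp) of each synthetic chromosome.
    seed : RNG seed; identical config + seed gives bit-identical output.
    """

    n_samples: int = 100
    n_pops: int = 2
    fst: float = 0.1
    n_snps: int = 1000
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_genes: int = 1000
    frac_long: float = 0.5
    causal_snp_index: Optional[int] = 0
    effect_size: float = 0.026
    noise_sd: float = 0.5
    baseline_sd: float = 1.0
    sex_effect: float = 0.0
    pop_shift: float = 0.0
    enrichment_odds: float = 3.0
    n_chroms: int = 5
    chrom_length: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_pops", "n_snps", "n_genes", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not (0.0 < self.frac_long < 1.0):
            raise ValueError(f"frac_long must be in (0, 1), got {self.frac_long}")
        if self.causal_snp_index is not None and not (0 <= self.causal_snp_index < self.n_snps):
            raise ValueError("causal_snp_index out of range")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class PipelineConfig:
    """File paths and analysis thresholds for the end-to-end pipeline.

    Defaults: 4 h half-life threshold, MAF cutoff 0.01, 5 genotype PCs,
    1000 permutations, FDR 0.1, 1 Mb cis window.
    """

    genotypes: str = "genotypes.tsv"
    genotype_format: str = "tsv"  # "tsv" or "vcf"
    expression: str = "expression.tsv"
    halflife: str = "halflife.tsv"
    annotation: str = "annotation.tsv"
    covariates: Optional[str] = None  # sample_id<TAB>sex
    out_dir: str = "rstab_out"
    scheme: str = "half_life_threshold"
    threshold_hours: float = 4.0
    maf_threshold: float = 0.01
    n_pcs: int = 5
    n_perm: int = 1000
    fdr_threshold: float = 0.1
    cis_window: int = 1_000_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
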