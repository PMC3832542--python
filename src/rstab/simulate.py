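"""Synthetic study generator.

Produces genotypes, half-life tables, expression matrices and paired
knockdown/control sets with the statistical structure the downstream analysis
assumes: Hardy-Weinberg genotypes with Balding-Nichols divergence between
populations, a bimodal half-life distribution straddling the 4-hour
long/short boundary, and a log-additive causal model in which one SNP's
minor-allele dosage raises the expression of long-lived transcripts in trans.

All generators are deterministic given the config (seed included); each
operation derives an independent child RNG stream from the config seed, so
e.g. the half-life table does not depend on how many SNPs were simulated.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datatypes import GenotypeMatrix, validate_expression

_STREAMS = {"genotypes": 1, "halflife": 2, "expression": 3, "knockdown": 4}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


def _sample_ids(config: SimulationConfig) -> pd.Index:
    n = config.n_samples * config.n_pops
    return pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate independent SNP dosages for ``n_pops`` populations.

    For each SNP an ancestral frequency p is drawn uniformly from
    ``maf_range``; per-population frequencies follow the Balding-Nichols model
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst`` (equal to p when F = 0),
    and per-sample dosages are Binomial(2, p_pop), i.e. Hardy-Weinberg
    within population. SNPs are placed uniformly on a synthetic genome of
    ``n_chroms`` chromosomes. Sample sex is Bernoulli(0.5).
    """
    rng = _rng(config, "genotypes")
    n_total = config.n_samples * config.n_pops
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)

    if config.fst > 0.0:
        ratio = (1.0 - config.fst) / config.fst
        a = p_anc * ratio
        b = (1.0 - p_anc) * ratio
        p_pop = rng.beta(a[:, None], b[:, None], size=(config.n_snps, config.n_pops))
    else:
        p_pop = np.repeat(p_anc[:, None], config.n_pops, axis=1)

    pop_of_sample = np.repeat(np.arange(config.n_pops), config.n_samples)
    dosages = rng.binomial(2, p_pop[:, pop_of_sample]).astype(float)

    chrom_idx = rng.integers(0, config.n_chroms, size=config.n_snps)
    pos = rng.integers(1, config.chrom_length + 1, size=config.n_snps)
    snp_ids = pd.Index([f"snp{i:05d}" for i in range(config.n_snps)], name="snp_id")
    snps = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "pos": pos,
            "major": "A",
            "minor": "G",
        },
        index=snp_ids,
    )
    sample_ids = _sample_ids(config)
    samples = pd.DataFrame(
        {
            "population": [f"pop{p + 1}" for p in pop_of_sample],
            "sex": rng.integers(0, 2, size=n_total),
        },
        index=sample_ids,
    )
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=snp_ids, columns=sample_ids), snps, samples
    )


def _enriched_flags(
    rng: np.random.Generator, is_long: np.ndarray, base_rate: float, odds: float
) -> np.ndarray:
    """Bernoulli flags whose odds among long-lived genes are ``odds`` times
    the odds among short-lived genes (base rate applies to short)."""
    base_odds = base_rate / (1.0 - base_rate)
    p_long = base_odds * odds / (1.0 + base_odds * odds)
    p = np.where(is_long, p_long, base_rate)
    return rng.random(is_long.shape) < p


def simulate_halflife_table(config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-gene half-lives plus gene annotation.

    Half-lives come from a two-component log-normal mixture with the
    components truncated at the 4-hour boundary, so that exactly
    ``round(frac_long * n_genes)`` genes are long-lived (half-life >= 4 h).
    The long component has median 12 h, the short component median 2 h
    (log-sd 0.5 each), spanning the range typical of mammalian mRNA decay.
    Housekeeping and coding flags are enriched among long-lived genes at
    ``enrichment_odds``; gene TSS positions are uniform on the synthetic
    genome; a fraction of short-lived genes carry an AU-rich-element target
    flag (ARE-mediated decay produces unstable transcripts).
    """
    if not (0.0 < config.frac_long < 1.0):  # guarded again: score undefined otherwise
        raise ValueError("frac_long must leave both groups non-empty")
    rng = _rng(config, "halflife")
    n_long = int(round(config.frac_long * config.n_genes))
    n_short = config.n_genes - n_long
    if n_long == 0 or n_short == 0:
        raise ValueError("frac_long leaves an empty long or short group at this n_genes")

    def _truncated_lognormal(n: int, median: float, lower: Optional[float], upper: Optional[float]) -> np.ndarray:
        out = np.empty(0)
        while out.size < n:
            draw = rng.lognormal(mean=np.log(median), sigma=0.5, size=2 * n)
            if lower is not None:
                draw = draw[draw >= lower]
            if upper is not None:
                draw = draw[draw < upper]
            out = np.concatenate([out, draw])
        return out[:n]

    hl = np.concatenate(
        [
            _truncated_lognormal(n_long, 12.0, lower=4.0, upper=None),
            _truncated_lognormal(n_short, 2.0, lower=None, upper=4.0),
        ]
    )
    is_long = hl >= 4.0

    housekeeping = _enriched_flags(rng, is_long, base_rate=0.2, odds=config.enrichment_odds)
    coding = _enriched_flags(rng, is_long, base_rate=0.5, odds=config.enrichment_odds)
    # ARE decay targets are depleted among stable transcripts
    are_target = _enriched_flags(rng, ~is_long, base_rate=0.1, odds=config.enrichment_odds)

    chrom_idx = rng.integers(0, config.n_chroms, size=config.n_genes)
    tss = rng.integers(1, config.chrom_length + 1, size=config.n_genes)

    gene_ids = pd.Index([f"gene{i:05d}" for i in range(config.n_genes)], name="gene_id")
    return pd.DataFrame(
        {
            "half_life_h": hl,
            "source": "synthetic",
            "biotype": np.where(coding, "coding", "non-coding"),
            "housekeeping": housekeeping,
            "are_target": are_target,
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "tss_pos": tss,
        },
        index=gene_ids,
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    halflife: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix under the causal model.

    Log-expression of gene g in sample i is

        b_g + effect_size * dosage(causal SNP, i) * [g long-lived]
            + sex_effect * sex_i * [g long-lived]
            + pop_shift * pop_index_i * [g long-lived]
            + Normal(0, noise_sd)

    with per-gene baselines b_g ~ Normal(5, baseline_sd), emitted on the
    natural scale (exponentiated, hence strictly positive). When
    ``causal_snp_index`` is None the dosage term is omitted (global null).
    """
    sample_ids = genotypes.sample_ids
    expected = _sample_ids(config)
    if not sample_ids.equals(expected):
        raise ValueError("genotype sample identifiers do not match the config")
    rng = _rng(config, "expression")
    n_genes = len(halflife)
    n_samples = len(sample_ids)
    is_long = (halflife["half_life_h"].to_numpy() >= 4.0).astype(float)

    baseline = rng.normal(5.0, config.baseline_sd, size=n_genes)
    log_expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    shift = np.zeros(n_samples)
    if config.causal_snp_index is not None:
        dosage = genotypes.dosages.iloc[config.causal_snp_index].to_numpy(dtype=float)
        shift = shift + config.effect_size * dosage
    if config.sex_effect != 0.0:
        shift = shift + config.sex_effect * genotypes.samples["sex"].to_numpy(dtype=float)
    if config.pop_shift != 0.0:
        pop_index = (
            genotypes.samples["population"].str.removeprefix("pop").astype(int) - 1
        ).to_numpy(dtype=float)
        shift = shift + config.pop_shift * pop_index
    log_expr += is_long[:, None] * shift[None, :]

    expr = pd.DataFrame(np.exp(log_expr), index=halflife.index, columns=sample_ids)
    return validate_expression(expr)


def plant_cis_mediator(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    genotypes: GenotypeMatrix,
    snp_id: str,
    gene_id: str,
    alpha: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Turn one gene into a cis mediator of a SNP.

    Returns copies of ``expr`` and ``annot`` in which ``gene_id`` is moved
    next to ``snp_id`` (TSS 10 kb downstream) and its log-expression is
    rewritten as 5 + alpha * dosage + Normal(0, noise_sd) — the
    configuration in which a causal variant acts on the score through the
    expression of a nearby gene.
    """
    if gene_id not in expr.index or gene_id not in annot.index:
        raise KeyError(f"unknown gene {gene_id!r}")
    rng = np.random.default_rng(seed)
    snp = genotypes.snps.loc[snp_id]
    dosage = genotypes.dosages.loc[snp_id].to_numpy(dtype=float)
    expr = expr.copy()
    annot = annot.copy()
    annot.loc[gene_id, "chrom"] = snp["chrom"]
    annot.loc[gene_id, "tss_pos"] = int(snp["pos"]) + 10_000
    expr.loc[gene_id] = np.exp(
        5.0 + alpha * dosage + rng.normal(0.0, noise_sd, size=len(dosage))
    )
    return validate_expression(expr), annot


def simulate_knockdown(
    halflife: pd.DataFrame,
    n_reps: int,
    knockdown_shift: float,
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired control/knockdown expression replicates.

    Knocking down an RNA-stabilizing factor selectively destabilizes its
    long-lived targets: knockdown columns subtract ``knockdown_shift`` from
    the log-expression of long-lived genes only. Returns
    ``(control, knockdown)`` matrices whose columns are paired by position
    (``ctrl_rep1`` with ``kd_rep1``, ...).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = _rng(config, "knockdown")
    n_genes = len(halflife)
    is_long = (halflife["half_life_h"].to_numpy() >= 4.0).astype(float)
    baseline = rng.normal(5.0, config.baseline_sd, size=n_genes)

    ctrl = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_reps))
    kd = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_reps))
    kd -= knockdown_shift * is_long[:, None]

    control = pd.DataFrame(
        np.exp(ctrl), index=halflife.index,
        columns=[f"ctrl_rep{i + 1}" for i in range(n_reps)],
    )
    knockdown = pd.DataFrame(
        np.exp(kd), index=halflife.index,
        columns=[f"kd_rep{i + 1}" for i in range(n_reps)],
    )
    return validate_expression(control), validate_expression(knockdown)
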