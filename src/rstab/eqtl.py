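"""cis / trans eQTL mapping by Spearman rank correlation.

A SNP's minor-allele dosage is correlated against each gene's expression
with Spearman's rho (average-tie ranks, two-sided p via the t approximation
on n - 2 df). Multiplicity over genes is controlled with the
Benjamini-Hochberg step-up FDR; enrichment of gene sets among the
associated genes uses Fisher's exact test. A gene is in cis with a SNP when
it lies on the same chromosome within a window centered on the SNP
(default 1 Mb, i.e. TSS within +/-500 kb, boundary inclusive).
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def spearman_assoc(dosage, expression) -> Tuple[float, float]:
    """Spearman rho between dosage and one gene's expression, with the
    two-sided p-value from the t approximation on n - 2 df.

    Requires >= 4 shared observations; a constant vector makes rho
    undefined and returns (nan, nan).
    """
    g = np.asarray(dosage, dtype=float)
    e = np.asarray(expression, dtype=float)
    if len(g) != len(e):
        raise ValueError("dosage and expression lengths differ")
    if len(g) < 4:
        raise ValueError(f"need >= 4 samples, got {len(g)}")
    if np.ptp(g) == 0 or np.ptp(e) == 0:
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(g, e)
    return float(rho), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def _scan(dosage: np.ndarray, expr: pd.DataFrame) -> pd.DataFrame:
    """Vectorized Spearman of one dosage vector against every gene row."""
    n = expr.shape[1]
    g_rank = stats.rankdata(dosage)
    e_rank = np.apply_along_axis(stats.rankdata, 1, expr.to_numpy(dtype=float))
    g_c = g_rank - g_rank.mean()
    e_c = e_rank - e_rank.mean(axis=1, keepdims=True)
    denom = np.sqrt((g_c @ g_c) * np.einsum("ij,ij->i", e_c, e_c))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, e_c @ g_c / denom, np.nan)
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isinf(t)] = 0.0
    return pd.DataFrame({"rho": rho, "p_value": p}, index=expr.index)


def trans_eqtl_scan(
    dosage: pd.Series,
    expr: pd.DataFrame,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Correlate one SNP's dosages with every gene; flag FDR discoveries.

    ``dosage`` is indexed by sample_id; samples are aligned on the
    intersection with the expression columns. Returns a per-gene table
    with columns ``rho p_value fdr associated``; the sign of rho is kept so
    the genes positively correlated with the minor-allele count are
    recoverable.
    """
    if expr.shape[0] == 0:
        raise ValueError("empty expression matrix")
    shared = expr.columns.intersection(dosage.index)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, got {len(shared)}")
    g = dosage.loc[shared].to_numpy(dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("constant dosage; Spearman undefined")
    table = _scan(g, expr[shared])
    valid = ~table["p_value"].isna()
    fdr = np.full(len(table), np.nan)
    fdr[valid.to_numpy()] = bh_fdr(table.loc[valid, "p_value"].to_numpy())
    table["fdr"] = fdr
    table["associated"] = table["fdr"] < fdr_threshold
    return table.sort_values("p_value")


def cis_window_scan(
    snp: pd.Series,
    dosage: pd.Series,
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Spearman association for genes in cis with a SNP.

    ``snp`` is a SNP metadata record with ``chrom`` and ``pos``; a gene is
    in cis iff it is on the SNP's chromosome and |tss_pos - pos| <= window/2
    (window centered on the SNP, boundary inclusive). Returns the cis
    genes sorted by p ascending — the top row is the candidate cis target —
    or an empty table with a warning when the window holds no genes.
    """
    half = window / 2.0
    in_cis = (annot["chrom"] == snp["chrom"]) & (
        (annot["tss_pos"] - snp["pos"]).abs() <= half
    )
    cis_genes = annot.index[in_cis].intersection(expr.index)
    if len(cis_genes) == 0:
        logger.warning(
            "no genes within %d bp of %s:%s", window, snp["chrom"], snp["pos"]
        )
        return pd.DataFrame(columns=["rho", "p_value", "in_cis"])
    shared = expr.columns.intersection(dosage.index)
    g = dosage.loc[shared].to_numpy(dtype=float)
    table = _scan(g, expr.loc[cis_genes, shared])
    table["in_cis"] = True
    return table.sort_values("p_value")


def fisher_enrichment(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Returns the sample odds ratio a*d/(b*c) (inf when b*c = 0 and a*d > 0)
    and the conditional hypergeometric two-sided p-value.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)
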