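"""Genome-wide association of SNP dosage with a quantitative score.

The scan fits, per SNP, an ordinary least-squares model

    score_i = alpha + beta * dosage_i + gamma' covariates_i + e_i

and reports the two-sided t-test on beta. Population stratification is
corrected by including the top genotype principal components
(Patterson-normalized) as covariates; residual inflation is diagnosed by the
genomic inflation factor lambda, and genome-wide significance is assessed
both by Bonferroni adjustment and by a min-p phenotype-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, PermutationResult

_NULL_MEDIAN_CHI2 = stats.chi2.ppf(0.5, df=1)  # 0.45493642...


def maf_filter(genotypes: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency <= threshold in this cohort.

    The boundary is exclusive for retention (MAF exactly at the threshold is
    removed), and the frequency is computed from non-missing dosages within
    the analyzed sample set, so the filter is per analysis cohort.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError(f"threshold must be in [0, 0.5), got {threshold}")
    maf = genotypes.maf()
    keep = maf.index[maf > threshold]
    if len(keep) == 0:
        raise ValueError("MAF filter removed every SNP")
    return genotypes.subset_snps(keep)


def genotype_pca(genotypes: GenotypeMatrix, k: int = 5) -> pd.DataFrame:
    """Top-k sample coordinates of the normalized genotype matrix.

    Each SNP row is mean-centered (missing dosages mean-imputed) and scaled
    by sqrt(phat (1 - phat)) with the shrunken allele-frequency estimate
    phat = (1 + sum dosages) / (2 + 2n), the Patterson/Eigensoft convention.
    Components are ordered by decreasing eigenvalue; their signs are
    arbitrary. Monomorphic SNPs contribute nothing.

    Returns a DataFrame indexed by sample_id with columns ``pc1``..``pck``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_snps, n_samples = genotypes.dosages.shape
    if k > min(n_snps, n_samples):
        raise ValueError(f"k={k} exceeds min(n_snps={n_snps}, n_samples={n_samples})")

    d = genotypes.dosages.to_numpy(dtype=float)
    row_mean = np.nanmean(d, axis=1)
    d = np.where(np.isnan(d), row_mean[:, None], d)
    phat = (1.0 + d.sum(axis=1)) / (2.0 + 2.0 * n_samples)
    scale = np.sqrt(phat * (1.0 - phat))
    centered = d - row_mean[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(scale[:, None] > 0, centered / scale[:, None], 0.0)

    # SVD of samples x SNPs; sample coordinates are U * S
    u, s, _ = np.linalg.svd(normalized.T, full_matrices=False)
    coords = u[:, :k] * s[:k]
    return pd.DataFrame(
        coords,
        index=genotypes.sample_ids.rename("sample_id"),
        columns=[f"pc{i + 1}" for i in range(k)],
    )


class RegressionResult(NamedTuple):
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    flag: Optional[str] = None  # "constant_dosage" / "zero_residual"


def additive_regression(
    phenotype: np.ndarray | pd.Series,
    dosage: np.ndarray | pd.Series,
    covariates: Optional[np.ndarray | pd.DataFrame] = None,
) -> RegressionResult:
    """OLS of phenotype on dosage (plus intercept and covariates).

    Samples with missing dosage are dropped pairwise. The p-value is the
    two-sided t-test on the dosage coefficient with n - p residual degrees
    of freedom. Degenerate fits are flagged rather than silently reported:
    a constant dosage gives an undefined p (``flag="constant_dosage"``),
    and a perfect fit gives se = 0 (``flag="zero_residual"``).
    """
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if covariates is None:
        c = np.empty((len(y), 0))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
    if not (len(y) == len(g) == len(c)):
        raise ValueError("phenotype, dosage and covariates must align")

    keep = ~np.isnan(g) & ~np.isnan(y)
    y, g, c = y[keep], g[keep], c[keep]
    n = len(y)
    x = np.column_stack([np.ones(n), g, c])
    p = x.shape[1]
    df = n - p
    if df < 1:
        raise ValueError(f"insufficient residual degrees of freedom (n={n}, p={p})")
    if np.ptp(g) == 0:
        return RegressionResult(np.nan, np.nan, np.nan, np.nan, n, "constant_dosage")

    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss = float(resid @ resid)
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = float(coef[1])
    if rss <= max(1e-12 * float(y @ y), 0.0):
        return RegressionResult(beta, 0.0, np.inf if beta != 0 else 0.0, np.nan, n, "zero_residual")
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = beta / se
    p_val = 2.0 * stats.t.sf(abs(t), df)
    return RegressionResult(beta, se, t, float(p_val), n)


def _residualize(mat: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project the columns of ``mat`` off the covariate space (incl. intercept)."""
    q, _ = np.linalg.qr(covariates)
    return mat - q @ (q.T @ mat)


def gwas_scan(
    genotypes: GenotypeMatrix,
    phenotype: pd.DataFrame | pd.Series,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Additive association of every SNP with the score.

    Expects MAF-filtered genotypes. ``phenotype`` is an RS-score frame
    (column ``rs_score``) or a Series indexed by sample_id; ``covariates``
    is a frame indexed by sample_id (e.g. sex plus genotype PCs). Samples
    are aligned on the intersection of identifiers.

    SNPs with complete dosages are fit in a single vectorized pass via
    Frisch-Waugh-Lovell residualization (identical to the per-SNP OLS);
    SNPs with missing dosages fall back to per-SNP regression with pairwise
    deletion. Returns a per-SNP table sorted by p ascending with columns
    ``chrom pos maf beta se t p_value n_used bonferroni_p``.
    """
    if isinstance(phenotype, pd.DataFrame):
        phenotype = phenotype["rs_score"]
    shared = genotypes.sample_ids.intersection(phenotype.index)
    if covariates is not None:
        shared = shared.intersection(covariates.index)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between genotypes, phenotype and covariates")
    geno = genotypes.subset_samples(shared)
    y = phenotype.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    if covariates is not None:
        cmat = np.column_stack([np.ones(n), covariates.loc[shared].to_numpy(dtype=float)])
    else:
        cmat = np.ones((n, 1))
    n_cov = cmat.shape[1]

    d = geno.dosages.to_numpy(dtype=float)
    m = d.shape[0]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    t_stat = np.full(m, np.nan)
    p_val = np.full(m, np.nan)
    n_used = np.full(m, n, dtype=int)

    complete = ~np.isnan(d).any(axis=1)
    nonconst = np.ptp(d, axis=1) != 0
    fast = complete & nonconst

    if fast.any():
        g_res = _residualize(d[fast].T, cmat)  # samples x snps
        y_res = _residualize(y[:, None], cmat)[:, 0]
        gg = np.einsum("ij,ij->j", g_res, g_res)
        gy = g_res.T @ y_res
        df = n - n_cov - 1
        b = gy / gg
        rss = float(y_res @ y_res) - b * gy
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        s = np.sqrt(sigma2 / gg)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(s > 0, b / s, np.sign(b) * np.inf)
        beta[fast], se[fast] = b, s
        t_stat[fast] = t
        p_val[fast] = 2.0 * stats.t.sf(np.abs(t), df)

    for i in np.where(~fast)[0]:
        res = additive_regression(y, d[i], cmat[:, 1:] if n_cov > 1 else None)
        beta[i], se[i], t_stat[i], p_val[i], n_used[i] = (
            res.beta, res.se, res.t_stat, res.p_value, res.n_used,
        )

    table = pd.DataFrame(
        {
            "chrom": geno.snps["chrom"],
            "pos": geno.snps["pos"],
            "maf": geno.maf(),
            "beta": beta,
            "se": se,
            "t": t_stat,
            "p_value": p_val,
            "n_used": n_used,
        },
        index=geno.dosages.index,
    )
    table["bonferroni_p"] = np.minimum(table["p_value"] * m, 1.0)
    return table.sort_values("p_value")


def genomic_lambda(p_values: Sequence[float] | np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square over its null
    median (~0.455). Values near 1 indicate no systematic stratification."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _NULL_MEDIAN_CHI2)


def permutation_minp(
    genotypes: GenotypeMatrix,
    phenotype: pd.DataFrame | pd.Series,
    covariates: Optional[pd.DataFrame],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Min-p permutation test of genome-wide significance.

    Shuffles the phenotype values across samples (covariates stay attached
    to their samples), re-runs the scan, and records the lowest p-value of
    each permuted scan. The permutation p is the fraction of null minimum
    p-values at or below the observed minimum; 0 is possible and is shown
    as "< 1/n_perm" in human-readable summaries while the raw count is kept.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(phenotype, pd.DataFrame):
        phenotype = phenotype["rs_score"]
    observed = gwas_scan(genotypes, phenotype, covariates)
    observed_min_p = float(np.nanmin(observed["p_value"].to_numpy()))

    rng = np.random.default_rng(seed)
    null_min_p = np.empty(n_perm)
    values = phenotype.copy()
    for b in range(n_perm):
        shuffled = pd.Series(
            rng.permutation(values.to_numpy()), index=values.index
        )
        scan = gwas_scan(genotypes, shuffled, covariates)
        null_min_p[b] = np.nanmin(scan["p_value"].to_numpy())
    return PermutationResult(observed_min_p, null_min_p, n_perm, seed)
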