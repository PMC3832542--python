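"""In-memory containers shared across the pipeline.

Tabular objects (half-life tables, classifications, expression matrices,
association tables) are plain pandas objects with documented schemas;
genotypes carry enough metadata (positions, alleles, population labels) to
warrant a small wrapper.

Schemas
-------
HalfLifeTable : DataFrame indexed by ``gene_id`` with exactly one of the
    columns ``half_life_h`` (hours, > 0) or ``relative_decay_rate``
    (mean-centered, unitless), optionally ``source``, ``chrom``, ``tss_pos``,
    ``biotype`` ("coding"/"non-coding"), ``housekeeping`` (bool),
    ``are_target`` (bool).
GeneClassification : DataFrame indexed by ``gene_id`` with columns ``group``
    ("LONG"/"SHORT") and ``scheme``.
ExpressionMatrix : DataFrame, genes x samples, finite non-negative values,
    unique gene and sample identifiers.
RSScoreVector : DataFrame indexed by ``sample_id`` with columns ``rs_score``,
    ``n_long``, ``n_short``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """SNPs x samples minor-allele dosages with SNP and sample metadata.

    Attributes
    ----------
    dosages : DataFrame (SNPs x samples), values in {0, 1, 2} or NaN (missing).
    snps : DataFrame indexed by snp_id with columns ``chrom``, ``pos``
        (1-based), ``major``, ``minor``.
    samples : DataFrame indexed by sample_id with optional ``population`` and
        ``sex`` (0/1) columns.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate snp_ids")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate sample_ids")
        if not self.dosages.index.equals(self.snps.index):
            raise ValueError("dosage rows and SNP metadata disagree")
        if not self.dosages.columns.equals(self.samples.index):
            raise ValueError("dosage columns and sample metadata disagree")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if (self.snps["pos"] <= 0).any():
            raise ValueError("positions must be 1-based and positive")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    def maf(self) -> pd.Series:
        """Per-SNP minor-allele frequency from non-missing dosages."""
        d = self.dosages.to_numpy(dtype=float)
        n = np.sum(~np.isnan(d), axis=1)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(d, axis=1) / (2.0 * n)
        maf = np.minimum(freq, 1.0 - freq)
        return pd.Series(maf, index=self.dosages.index, name="maf")

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.loc[snp_ids], self.snps.loc[snp_ids], self.samples
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[list(sample_ids)], self.snps, self.samples.loc[list(sample_ids)]
        )


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an ExpressionMatrix schema; returns the frame unchanged."""
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if expr.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    vals = expr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression values must be finite")
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    return expr


@dataclass
class PermutationResult:
    """Outcome of a min-p phenotype-shuffling significance test."""

    observed_min_p: float
    null_min_p: np.ndarray
    n_perm: int
    seed: int

    @property
    def permutation_p(self) -> float:
        """Fraction of null minimum p-values at or below the observed one."""
        return float(np.sum(self.null_min_p <= self.observed_min_p)) / self.n_perm

    def summary(self) -> str:
        p = self.permutation_p
        shown = f"<{1.0 / self.n_perm:g}" if p == 0.0 else f"{p:g}"
        return (
            f"observed min p = {self.observed_min_p:.3g}; permutation p = {shown} "
            f"({int(round(p * self.n_perm))}/{self.n_perm} null scans at or below)"
        )
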