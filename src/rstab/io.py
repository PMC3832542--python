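"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: tab-separated tables with headers, and a
minimal GT-only VCF 4.x dialect for genotypes. Dosages are always counts of
the cohort minor allele; when reading a VCF the orientation is decided per
cohort (the allele with frequency < 0.5 among the read samples is counted),
and the chosen allele is recorded in the SNP metadata.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, validate_expression

logger = logging.getLogger(__name__)

_GT_TO_ALT_COUNT = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": None, ".|.": None, ".": None,
}


# ---------------------------------------------------------------------------
# expression

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene_id, header sample ids).

    Duplicate gene rows are collapsed by their mean with a logged count;
    negative or non-numeric values are rejected with the offending location.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.astype(float)
    except ValueError:
        for gene, row in df.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at gene {gene}, sample {col}"
                    ) from None
        raise
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.info("%s: collapsed %d duplicate gene rows by mean", path, n_dup)
        values = values.groupby(level=0, sort=False).mean()
    values.index.name = "gene_id"
    return validate_expression(values)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# half-life table and gene annotation

def read_halflife(path: str | Path) -> pd.DataFrame:
    """Read a half-life table: ``gene_id`` plus ``half_life_h`` or
    ``relative_decay_rate``, and any annotation columns present."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    has_hl = "half_life_h" in df.columns
    has_dr = "relative_decay_rate" in df.columns
    if has_hl == has_dr:
        raise ValueError(
            f"{path}: expected exactly one of 'half_life_h' or 'relative_decay_rate'"
        )
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene_ids")
    if has_hl and (df["half_life_h"] <= 0).any():
        raise ValueError(f"{path}: half-lives must be positive")
    for col in ("housekeeping", "are_target"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_halflife(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene annotation: ``gene_id chrom tss_pos biotype housekeeping
    are_target`` (flags parsed as booleans)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"chrom", "tss_pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    if (df["tss_pos"] <= 0).any():
        raise ValueError(f"{path}: tss_pos must be positive (1-based)")
    for col in ("housekeeping", "are_target"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "tss_pos", "biotype", "housekeeping", "are_target")
            if c in annot.columns]
    annot[cols].to_csv(path, sep="\t", index_label="gene_id")


def write_classification(cls: pd.DataFrame, path: str | Path) -> None:
    cls.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# covariates and scores

def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate TSV ``sample_id sex [pc1..pck]``; sex coded 0/1
    (0 = female, 1 = male). Samples with unknown sex are dropped with a
    logged count."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "sex" in df.columns:
        known = df["sex"].isin([0, 1])
        if not known.all():
            logger.info("%s: dropped %d samples with unknown sex", path, int((~known).sum()))
            df = df[known]
        df["sex"] = df["sex"].astype(int)
    return df


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample_id")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="sample_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# genotypes

def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """TSV dialect: ``snp_id chrom pos ref alt`` then one dosage column per
    sample; dosages are already minor-allele counts (empty cell = missing)."""
    df = pd.read_csv(path, sep="\t", index_col="snp_id")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dosages = df.drop(columns=meta_cols).astype(float)
    dosages.columns.name = "sample_id"
    snps = df[meta_cols].rename(columns={"ref": "major", "alt": "minor"})
    samples = pd.DataFrame(index=dosages.columns)
    return GenotypeMatrix(dosages, snps, samples)


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    out = genotypes.snps.rename(columns={"major": "ref", "minor": "alt"})
    out = pd.concat([out[["chrom", "pos", "ref", "alt"]], genotypes.dosages], axis=1)
    out.to_csv(path, sep="\t", index_label="snp_id")


def _read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Minimal VCF 4.x reader (biallelic sites, GT field only).

    ALT-allele counts are recoded to minor-allele dosages per cohort: when
    the ALT frequency among the read samples exceeds 0.5, REF is the minor
    allele and dosages flip to 2 - alt_count. Non-biallelic sites are
    skipped with a logged count; malformed records raise with their line
    number.
    """
    sample_ids: list[str] = []
    snp_ids, chroms, poss, refs, alts = [], [], [], [], []
    rows: list[list[float]] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise ValueError(f"{path}:{lineno}: VCF header has no sample columns")
                sample_ids = fields[9:]
                continue
            if not sample_ids:
                raise ValueError(f"{path}:{lineno}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(sample_ids):
                raise ValueError(
                    f"{path}:{lineno}: expected {9 + len(sample_ids)} columns, got {len(fields)}"
                )
            chrom, pos, snp_id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt or alt == "." or len(ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: no GT in FORMAT") from None
            try:
                pos_i = int(pos)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer POS {pos!r}") from None
            row = []
            for col, cell in enumerate(fields[9:], start=10):
                gt = cell.split(":")[gt_idx]
                if gt not in _GT_TO_ALT_COUNT:
                    raise ValueError(f"{path}:{lineno}: column {col}: malformed GT {gt!r}")
                count = _GT_TO_ALT_COUNT[gt]
                row.append(np.nan if count is None else float(count))
            snp_ids.append(snp_id)
            chroms.append(chrom)
            poss.append(pos_i)
            refs.append(ref)
            alts.append(alt)
            rows.append(row)
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic sites", path, n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic sites with genotypes found")

    dosage = np.array(rows, dtype=float)
    n_obs = np.sum(~np.isnan(dosage), axis=1)
    alt_freq = np.nansum(dosage, axis=1) / (2.0 * n_obs)
    flip = alt_freq > 0.5
    dosage[flip] = 2.0 - dosage[flip]
    major = np.where(flip, alts, refs)
    minor = np.where(flip, refs, alts)

    index = pd.Index(snp_ids, name="snp_id")
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "major": major, "minor": minor}, index=index
    )
    columns = pd.Index(sample_ids, name="sample_id")
    return GenotypeMatrix(
        pd.DataFrame(dosage, index=index, columns=columns),
        snps,
        pd.DataFrame(index=columns),
    )


_DOSAGE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a GT-only VCF 4.2 with ALT as the recorded minor allele."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        d = genotypes.dosages.to_numpy(dtype=float)
        for i, (snp_id, meta) in enumerate(genotypes.snps.iterrows()):
            gts = [
                "./." if np.isnan(x) else _DOSAGE_TO_GT[x] for x in d[i]
            ]
            fh.write(
                f"{meta['chrom']}\t{meta['pos']}\t{snp_id}\t{meta['major']}\t"
                f"{meta['minor']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_association(table: pd.DataFrame, path: str | Path) -> None:
    """Association TSV: snp_id chrom pos maf beta se t p bonferroni_p."""
    out = table.copy()
    out = out.rename(columns={"p_value": "p"})
    cols = ["chrom", "pos", "maf", "beta", "se", "t", "p", "bonferroni_p"]
    out[cols].to_csv(path, sep="\t", index_label="snp_id", float_format="%.6g")


def write_manhattan_table(table: pd.DataFrame, path: str | Path) -> None:
    """Companion plot table: chrom, pos, -log10 p per SNP."""
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["pos"],
            "neg_log10_p": -np.log10(table["p_value"]),
        },
        index=table.index,
    )
    out.to_csv(path, sep="\t", index_label="snp_id", float_format="%.6g")


def write_eqtl(table: pd.DataFrame, snp_id: str, path: str | Path) -> None:
    """eQTL TSV: snp_id gene_id rho p fdr in_cis."""
    out = table.copy()
    out.insert(0, "snp_id", snp_id)
    if "in_cis" not in out.columns:
        out["in_cis"] = False
    out = out.rename(columns={"p_value": "p"})
    keep = ["snp_id", "rho", "p"] + (["fdr"] if "fdr" in out.columns else []) + ["in_cis"]
    out[keep].to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
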