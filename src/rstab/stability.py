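"""RNA stability score (RS-score).

The RS-score of a sample is the difference between the mean expression rank
of genes expressing long-lived RNAs and the mean expression rank of genes
expressing short-lived RNAs, with genes ranked 1..N ascending in expression
within the sample. A higher score means stable transcripts are relatively
more highly expressed — the signature of stronger trans-acting RNA
stabilization. Because it is rank-based, the score is invariant to any
strictly increasing transformation of a sample's expression values and is
bounded by N/2 in absolute value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import validate_expression

logger = logging.getLogger(__name__)

SCHEMES = ("half_life_threshold", "decay_rate_mean", "housekeeping", "coding")


def classify_genes(
    halflife: pd.DataFrame,
    scheme: str = "half_life_threshold",
    threshold: float = 4.0,
    long_when_below_mean: bool = True,
) -> pd.DataFrame:
    """Partition genes into LONG / SHORT groups.

    Schemes
    -------
    half_life_threshold
        LONG iff ``half_life_h >= threshold`` (threshold in hours; the
        boundary value itself counts as long-lived).
    decay_rate_mean
        LONG iff the relative decay rate is below the mean across genes
        (slower decay means a longer-lived transcript). Set
        ``long_when_below_mean=False`` to flip the sign convention.
    housekeeping
        LONG := housekeeping flag set.
    coding
        LONG := protein-coding biotype.

    Genes with a missing classifying value are dropped with a logged count.
    Raises if every gene lands in one group (the score is then undefined).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if halflife.index.has_duplicates:
        raise ValueError("duplicate gene_ids in half-life table")

    if scheme == "half_life_threshold":
        col = halflife["half_life_h"]
        values = col.dropna()
        long_mask = values >= threshold
    elif scheme == "decay_rate_mean":
        col = halflife["relative_decay_rate"]
        values = col.dropna()
        centered = values - values.mean()
        long_mask = centered < 0 if long_when_below_mean else centered > 0
    elif scheme == "housekeeping":
        values = halflife["housekeeping"].dropna()
        long_mask = values.astype(bool)
    else:  # coding
        values = halflife["biotype"].dropna()
        long_mask = values == "coding"

    n_dropped = len(halflife) - len(values)
    if n_dropped:
        logger.info("classify_genes: dropped %d genes with missing values", n_dropped)

    groups = np.where(long_mask, "LONG", "SHORT")
    cls = pd.DataFrame({"group": groups, "scheme": scheme}, index=values.index)
    counts = cls["group"].value_counts()
    if counts.get("LONG", 0) == 0 or counts.get("SHORT", 0) == 0:
        raise ValueError(
            f"scheme {scheme!r} puts all {len(cls)} genes in one group; score undefined"
        )
    return cls


def rank_expression(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rank one sample's expression vector 1..N ascending, average ties."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty expression vector")
    if not np.isfinite(arr).all():
        raise ValueError("expression values must be finite for ranking")
    return stats.rankdata(arr, method="average")


def rs_score(expr: pd.DataFrame, cls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample RS-score: mean rank of LONG genes minus mean rank of SHORT.

    Only classified genes present in the expression matrix participate in
    the ranking, so the score depends solely on the two groups and
    |score| <= N/2 exactly, where N = n_long + n_short. Duplicate probe rows
    for the same gene must have been collapsed beforehand (the readers do
    this by mean).

    Returns a DataFrame indexed by sample_id with columns ``rs_score``,
    ``n_long``, ``n_short``.
    """
    validate_expression(expr)
    shared = expr.index.intersection(cls.index)
    sub = cls.loc[shared, "group"]
    long_ids = shared[sub == "LONG"]
    short_ids = shared[sub == "SHORT"]
    if len(long_ids) == 0:
        raise ValueError("no LONG genes present in the expression matrix")
    if len(short_ids) == 0:
        raise ValueError("no SHORT genes present in the expression matrix")

    sub_expr = expr.loc[shared]
    ranks = np.apply_along_axis(rank_expression, 0, sub_expr.to_numpy(dtype=float))
    is_long = sub.to_numpy() == "LONG"
    mean_long = ranks[is_long].mean(axis=0)
    mean_short = ranks[~is_long].mean(axis=0)
    out = pd.DataFrame(
        {
            "rs_score": mean_long - mean_short,
            "n_long": int(is_long.sum()),
            "n_short": int((~is_long).sum()),
        },
        index=expr.columns.rename("sample_id"),
    )
    return out


def score_agreement(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Spearman correlation between two RS-score vectors over shared samples.

    Used to compare scores computed from different half-life sources or
    grouping schemes; requires at least 3 shared samples.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    rho, _ = stats.spearmanr(a.loc[shared, "rs_score"], b.loc[shared, "rs_score"])
    return float(rho)
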