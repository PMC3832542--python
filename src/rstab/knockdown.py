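"""Perturbation analyses: does knocking down an RNA-stabilizing factor
lower the RS-score, and do score levels differ across genotype classes?

Replicate-level score comparisons use paired and pooled two-sample t tests;
gene-level shifts between matched conditions use a Wilcoxon rank-sum test on
per-gene log expression ratios of the LONG versus SHORT groups; genotype
classes (dosage 0/1/2) are compared by one-way fixed-effects ANOVA.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class PairedScoreTest(NamedTuple):
    mean_difference: float
    t_stat: float
    p_value: float
    n_reps: int
    flag: str | None = None


def paired_score_test(
    control_scores: Sequence[float],
    treated_scores: Sequence[float],
) -> PairedScoreTest:
    """Two-sided paired t test on treated - control score differences.

    Scores are paired by replicate position. Zero-variance differences
    (e.g. treated identical to control) leave the p-value undefined and
    are flagged.
    """
    c = np.asarray(control_scores, dtype=float)
    t = np.asarray(treated_scores, dtype=float)
    if len(c) != len(t):
        raise ValueError("one control and one treated score per replicate required")
    if len(c) < 2:
        raise ValueError("need >= 2 replicates for a paired test")
    diff = t - c
    mean_diff = float(diff.mean())
    if np.ptp(diff) == 0:
        return PairedScoreTest(mean_diff, np.nan, np.nan, len(c), "zero_variance")
    stat, p = stats.ttest_rel(t, c)
    return PairedScoreTest(mean_diff, float(stat), float(p), len(c))


def two_sample_score_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided pooled-variance t test between two groups of scores."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x.mean() == y.mean():
            return (0.0, np.nan)
        raise ValueError("zero variance in both groups; t undefined")
    stat, p = stats.ttest_ind(x, y, equal_var=True)
    return float(stat), float(p)


class GroupShiftTest(NamedTuple):
    statistic: float
    p_value: float
    direction: str  # which group shifted down: "LONG" / "SHORT" / "none"
    median_log_ratio_long: float
    median_log_ratio_short: float
    flag: str | None = None


def group_shift_test(
    treated: pd.Series,
    control: pd.Series,
    cls: pd.DataFrame,
) -> GroupShiftTest:
    """Wilcoxon rank-sum test of LONG vs SHORT per-gene expression shifts.

    Computes the natural-log ratio treated/control per gene over the matched
    gene set, then compares the log-ratio distributions of the LONG and
    SHORT groups (two-sided; exact null distribution for small groups,
    normal approximation with continuity correction otherwise). The
    reported direction names the group whose median log-ratio is lower.
    """
    shared = treated.index.intersection(control.index).intersection(cls.index)
    groups = cls.loc[shared, "group"]
    long_ids = shared[groups == "LONG"]
    short_ids = shared[groups == "SHORT"]
    if len(long_ids) < 2 or len(short_ids) < 2:
        raise ValueError("each group needs >= 2 genes for a rank-sum test")
    log_ratio = np.log(treated.loc[shared].to_numpy(dtype=float)) - np.log(
        control.loc[shared].to_numpy(dtype=float)
    )
    lr = pd.Series(log_ratio, index=shared)
    lr_long = lr.loc[long_ids].to_numpy()
    lr_short = lr.loc[short_ids].to_numpy()
    med_long = float(np.median(lr_long))
    med_short = float(np.median(lr_short))
    if np.ptp(log_ratio) == 0:
        return GroupShiftTest(np.nan, np.nan, "none", med_long, med_short, "degenerate")
    use_exact = max(len(lr_long), len(lr_short)) <= 20
    stat, p = stats.mannwhitneyu(
        lr_long, lr_short, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
    )
    if med_long < med_short:
        direction = "LONG"
    elif med_short < med_long:
        direction = "SHORT"
    else:
        direction = "none"
    return GroupShiftTest(float(stat), float(p), direction, med_long, med_short)


def anova_by_genotype(values, dosage) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA of a score across genotype classes.

    Groups samples by dosage (0/1/2); classes that are absent are simply
    not part of the comparison. Requires at least two non-empty classes.
    With exactly two classes F equals the square of the equal-variance
    two-sample t statistic.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if len(v) != len(g):
        raise ValueError("values and dosage must align")
    keep = ~np.isnan(g) & ~np.isnan(v)
    v, g = v[keep], g[keep]
    classes = [v[g == level] for level in np.unique(g)]
    classes = [c for c in classes if len(c) > 0]
    if len(classes) < 2:
        raise ValueError("need >= 2 genotype classes")
    f, p = stats.f_oneway(*classes)
    return float(f), float(p)
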