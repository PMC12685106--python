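"""Univariate feature statistics and cohort demographic tests.

Per-feature discrimination uses one-way ANOVA on PQN-normalized
intensities with Benjamini-Hochberg FDR control; fold change is the ratio
of group means.  Demographic contrasts use Fisher's exact test (two-sided,
point-probability rule) on 2x2 tables and a two-sample t test (Welch by
default) for continuous variables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import FittingError, ValidationError
from .preprocess import PeakMatrix


def anova_feature(values_by_group: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA (F, p). Zero total variance with equal means -> p = 1."""
    groups = [np.asarray(g, dtype=np.float64) for g in values_by_group]
    if len(groups) < 2:
        raise FittingError("anova_feature needs at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise FittingError("each ANOVA group needs n >= 2")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    F, p = sps.f_oneway(*groups)
    if not np.isfinite(F):  # zero within-group variance, unequal means
        return float("inf"), 0.0
    return float(F), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of group means A/B; NaN flags an undefined ratio (B = 0)."""
    if mean_b == 0:
        return float("nan")
    return mean_a / mean_b


def feature_table(
    matrix: PeakMatrix,
    labels,
    group_a: str,
    group_b: str,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-feature ANOVA p, BH q, fold change (A/B) and direction.

    ``labels`` aligns with matrix rows; only rows labeled ``group_a`` or
    ``group_b`` enter the comparison.
    """
    labels = np.asarray(labels)
    X = matrix.intensities
    ia = labels == group_a
    ib = labels == group_b
    if ia.sum() < 2 or ib.sum() < 2:
        raise FittingError("each comparison group needs n >= 2 samples")
    Xa, Xb = X[ia], X[ib]
    rows = []
    for j, mz in enumerate(matrix.consensus_mz):
        a, b = Xa[:, j], Xb[:, j]
        ta, tb = (np.log10(a + 1e-12), np.log10(b + 1e-12)) if log_transform else (a, b)
        _F, p = anova_feature([ta, tb])
        ma, mb = float(a.mean()), float(b.mean())
        fc = fold_change(ma, mb)
        rows.append(
            {
                "mz": float(mz),
                "p_value": p,
                "mean_a": ma,
                "mean_b": mb,
                "fold_change": fc,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df["direction"] = np.select(
        [df["fold_change"] > 1, df["fold_change"] < 1],
        ["up_in_a", "up_in_b"],
        default="none",
    )
    return df


def select_discriminatory(stats_df: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Features with q below threshold, ranked by ascending q."""
    if stats_df.empty:
        return stats_df
    sel = stats_df[stats_df["q_value"] < q_threshold]
    return sel.sort_values(["q_value", "mz"], kind="stable").reset_index(drop=True)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p by the point-probability rule."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValidationError("fisher_exact_2x2 needs a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("degenerate table: a margin is zero")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def welch_t(group_a, group_b, pooled: bool = False) -> tuple[float, float]:
    """Two-sample t test; Welch degrees of freedom by default."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise FittingError("welch_t needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    res = sps.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def demographic_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Fisher p per categorical variable from a (variable, level, cancer, benign) table."""
    rows = []
    for var, sub in counts.groupby("variable", sort=False):
        if len(sub) != 2:
            continue  # only 2x2-reproducible variables are tested
        t = sub[["cancer", "benign"]].to_numpy()
        rows.append({"variable": var, "p_value": fisher_exact_2x2(t)})
    return pd.DataFrame(rows)
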