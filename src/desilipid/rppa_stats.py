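"""Protein-level differential analysis of RPPA-style expression tables.

Each protein is related to tissue status (benign vs. cancer) by a
univariate logistic regression with a binomial link; odds ratios are
exponentiated coefficients with Wald 95% intervals, and q-values come from
Benjamini-Hochberg FDR control across the panel.  Complete separation is
detected and flagged rather than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FittingError
from .feature_stats import bh_fdr

_MAX_ABS_BETA = 15.0   # |beta| on the per-SD scale beyond this marks separation
_MAX_REL_SE = 100.0    # Wald SE this many times |beta| marks a degenerate fit


@dataclass
class LogisticFit:
    beta: float
    se: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    separated: bool


def fit_logistic_univariate(expression, labels, positive_label: str = "cancer") -> LogisticFit:
    """ML fit of status ~ intercept + expression via IRLS.

    Returns the slope, its Wald standard error and p-value, the odds ratio
    exp(beta) and its 95% CI exp(beta +/- 1.96 se).  A (quasi-)separated fit
    is returned with ``separated=True`` and non-finite interval markers.
    """
    x = np.asarray(expression, dtype=np.float64)
    y = (np.asarray(labels) == positive_label).astype(float)
    if len(set(y.tolist())) < 2:
        raise FittingError("both classes must be present")
    if x.std() == 0:
        raise FittingError("expression has zero variance")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
        beta = float(res.params[1])
        se = float(res.bse[1])
        p = float(res.pvalues[1])
    except Exception:
        return LogisticFit(np.nan, np.nan, np.nan, np.inf, np.nan, np.nan, True)
    separated = (
        not np.isfinite(se)
        or abs(beta) * x.std() > _MAX_ABS_BETA
        or (abs(beta) > 0 and se > _MAX_REL_SE * abs(beta))
    )
    if separated:
        return LogisticFit(beta, se, np.nan, np.inf if beta > 0 else 0.0, np.nan, np.nan, True)
    return LogisticFit(
        beta=beta,
        se=se,
        p_value=p,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        separated=False,
    )


def summarize_groups(expression, labels, positive_label: str = "cancer") -> dict:
    """Mean and sample SD per group plus the dysregulation direction in cancer."""
    x = np.asarray(expression, dtype=np.float64)
    y = np.asarray(labels)
    pos = x[y == positive_label]
    neg = x[y != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise FittingError("summarize_groups: empty group")
    out = {
        "mean_cancer": float(pos.mean()),
        "sd_cancer": float(pos.std(ddof=1)) if pos.size > 1 else np.nan,
        "mean_benign": float(neg.mean()),
        "sd_benign": float(neg.std(ddof=1)) if neg.size > 1 else np.nan,
    }
    if out["mean_cancer"] > out["mean_benign"]:
        out["direction"] = "Increased"
    elif out["mean_cancer"] < out["mean_benign"]:
        out["direction"] = "Decreased"
    else:
        out["direction"] = "Tie"
    return out


def rppa_pipeline(
    table: pd.DataFrame,
    labels,
    q_threshold: float = 0.05,
    per_sd: bool = False,
) -> pd.DataFrame:
    """Per-protein logistic fit + group summary + BH q across the panel.

    ``table`` is patients x proteins; ``labels`` aligns with its rows.
    ``per_sd=True`` reports odds ratios per SD of expression rather than per
    unit.  Failed or separated fits are flagged and excluded from the FDR
    denominator; the run continues.
    """
    if table.shape[1] == 0:
        return pd.DataFrame(
            columns=["protein", "odds_ratio", "ci_low", "ci_high", "p_value",
                     "q_value", "separated", "significant"]
        )
    labels = np.asarray(labels)
    rows = []
    for name in table.columns:
        x = table[name].to_numpy(dtype=np.float64)
        if per_sd:
            x = x / x.std(ddof=1)
        try:
            fit = fit_logistic_univariate(x, labels)
        except FittingError:
            fit = LogisticFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, True)
        row = {"protein": name, "odds_ratio": fit.odds_ratio,
               "ci_low": fit.ci_low, "ci_high": fit.ci_high,
               "p_value": fit.p_value, "separated": fit.separated}
        row.update(summarize_groups(table[name].to_numpy(), labels))
        rows.append(row)
    df = pd.DataFrame(rows)
    ok = ~df["separated"] & df["p_value"].notna()
    df["q_value"] = np.nan
    if ok.any():
        df.loc[ok, "q_value"] = bh_fdr(df.loc[ok, "p_value"].to_numpy())
    df["significant"] = df["q_value"] < q_threshold
    return df
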