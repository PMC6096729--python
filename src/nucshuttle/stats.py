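"""Group comparison of derived measurements.

Per-group summaries are mean ± SEM (sample SD, n−1 denominator); group means
are compared by one-way fixed-effects ANOVA with post hoc Tukey HSD on the
studentized range distribution (Tukey–Kramer for unbalanced groups), with
significance at P < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupTable", "summarize", "anova_tukey", "AnovaTukeyResult"]


def _as_group_table(df: pd.DataFrame) -> pd.DataFrame:
    if not {"value", "group"}.issubset(df.columns):
        raise ValueError("expected columns 'value' and 'group'")
    out = df[["value", "group"]].copy()
    out["value"] = out["value"].astype(float)
    out["group"] = out["group"].astype(str)
    if not np.all(np.isfinite(out["value"])):
        raise ValueError("values must be finite")
    if (out["group"].str.len() == 0).any():
        raise ValueError("group labels must be non-empty")
    return out


# alias for the domain vocabulary: observations as (value, group) pairs
GroupTable = pd.DataFrame


def summarize(groups: pd.DataFrame) -> pd.DataFrame:
    """Per-group n, mean, SD and SEM (SEM = SD/√n, sample SD).

    Groups with n < 2 get NaN SD/SEM and ``sem_defined = False``.
    """
    df = _as_group_table(groups)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        n = len(v)
        sd = float(np.std(v, ddof=1)) if n >= 2 else np.nan
        rows.append(
            {
                "group": g,
                "n": n,
                "mean": float(v.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(n) if n >= 2 else np.nan,
                "sem_defined": n >= 2,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA omnibus test plus the pairwise Tukey HSD table."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    alpha: float

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA: F = {self.f_statistic:.4g}, p = {self.p_value:.4g} "
            f"(alpha = {self.alpha})",
            self.tukey.to_string(index=False),
        ]
        return "\n".join(lines)


def anova_tukey(groups: pd.DataFrame, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with post hoc Tukey HSD.

    Requires at least two groups with at least two observations each.  Zero
    within-group variance with equal means leaves F undefined and raises.
    """
    df = _as_group_table(groups)
    arrays = [sub["value"].to_numpy() for _, sub in df.groupby("group", sort=True)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    means = [a.mean() for a in arrays]
    if within == 0 and np.ptp(means) == 0:
        raise ValueError("zero within-group variance with equal means: F undefined")
    f_stat, p = sps.f_oneway(*arrays)
    tk = pairwise_tukeyhsd(df["value"].to_numpy(), df["group"].to_numpy(), alpha=alpha)
    table = pd.DataFrame(
        tk.summary().data[1:],
        columns=["group1", "group2", "meandiff", "p_adj", "lower", "upper", "reject"],
    )
    for col in ("meandiff", "p_adj", "lower", "upper"):
        table[col] = table[col].astype(float)
    table["reject"] = table["reject"].astype(bool)
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p), tukey=table, alpha=alpha
    )
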