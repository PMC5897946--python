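"""Cohort-level summaries: variance shares, fold differences, group tests.

These are the descriptive analyses that surround the genetic work: how much
of the spot-density variance sits between strains and between families
within strains, how many times spottier one group is than another, and the
standard two- and k-sample comparisons (Welch t, Mann-Whitney,
Kruskal-Wallis, one-way ANOVA R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import fit_vc_model

__all__ = [
    "VarianceShares",
    "strain_family_shares",
    "fold_difference",
    "render_fold",
    "group_summaries",
    "group_tests",
]

_WORDS = {
    2: "twofold", 3: "threefold", 4: "fourfold", 5: "fivefold", 6: "sixfold",
    7: "sevenfold", 8: "eightfold", 9: "ninefold", 10: "tenfold",
    11: "elevenfold", 12: "twelvefold",
}


@dataclass(frozen=True)
class VarianceShares:
    """Fractions of the total phenotypic variance (sum to 1)."""

    share_strain: float
    share_family: float
    share_residual: float

    def __post_init__(self) -> None:
        total = self.share_strain + self.share_family + self.share_residual
        if abs(total - 1.0) > 1e-9:
            raise ValueError("variance shares must sum to 1")
        if min(self.share_strain, self.share_family, self.share_residual) < 0:
            raise ValueError("variance shares must be non-negative")


def strain_family_shares(
    table: pd.DataFrame, trait: str = "spot_density"
) -> VarianceShares:
    """Split trait variance into strain, family-within-strain and residual.

    Both strain and family enter as *random* intercepts (family nested within
    strain) in a REML mixed model with an intercept-only fixed part; the
    shares are each component divided by their sum.  Single-member families
    should be filtered beforehand (see ``apply_exclusions``).
    """
    for col in (trait, "strain", "family"):
        if col not in table.columns:
            raise KeyError(f"table lacks column {col!r}")
    if table["strain"].nunique() < 2 or table["family"].nunique() < 2:
        raise ValueError("need at least 2 strains and 2 families")

    y = table[trait].to_numpy(dtype=float)
    n = len(y)
    strain = table["strain"].to_numpy()
    family = table["family"].to_numpy()
    S_strain = (strain[:, None] == strain[None, :]).astype(float)
    S_family = (family[:, None] == family[None, :]).astype(float)
    vc = fit_vc_model(y, np.ones((n, 1)), {"strain": S_strain, "family": S_family},
                      validate=False)
    s, f, e = vc.sigma2["strain"], vc.sigma2["family"], vc.sigma2_e
    total = s + f + e
    return VarianceShares(s / total, f / total, e / total)


def fold_difference(mean_a: float, mean_b: float) -> float:
    """Ratio mean_a / mean_b; the denominator must be positive."""
    if mean_b <= 0:
        raise ValueError("denominator mean must be positive")
    return mean_a / mean_b


def render_fold(ratio: float, decimals: int = 1) -> str:
    """Human-readable "k-fold" label.

    Rounds to ``decimals`` places; when the rounded value is a whole number
    it collapses to an integer, and small integers are spelled out
    ("sevenfold"); otherwise the numeric form is used ("6.5-fold").
    """
    r = round(ratio, decimals)
    if float(r).is_integer():
        k = int(r)
        return _WORDS.get(k, f"{k}-fold")
    return f"{r:g}-fold"


def group_summaries(
    table: pd.DataFrame, by: str, value: str = "spot_count"
) -> pd.DataFrame:
    """n, mean, median and sd (n-1 denominator) per group.

    Groups with a single observation report a missing sd.
    """
    if by not in table.columns:
        raise KeyError(f"grouping column {by!r} not in table")
    if value not in table.columns:
        raise KeyError(f"value column {value!r} not in table")
    if table.empty:
        raise ValueError("empty table")
    out = (
        table.groupby(by)[value]
        .agg(n="size", mean="mean", median="median", sd="std")
        .reset_index()
        .rename(columns={by: "group"})
    )
    return out


def group_tests(
    table: pd.DataFrame, response: str, group: str, kind: str = "t"
) -> dict:
    """Standard group-comparison tests.

    ``kind``:
      * ``"t"`` — Welch two-sample t test (fractional df),
      * ``"mann_whitney"`` — two-sample Mann-Whitney U,
      * ``"kruskal_wallis"`` — k-sample rank test,
      * ``"anova_r2"`` — one-way ANOVA with the grouping factor's R^2.

    Returns a dict with ``statistic``, ``p`` and, where defined, ``df`` and
    ``r2``.
    """
    groups = [g[response].to_numpy(dtype=float) for _, g in table.groupby(group)]
    if any(len(g) == 0 for g in groups) or not groups:
        raise ValueError("every group must contain at least one observation")

    if kind == "t":
        if len(groups) != 2:
            raise ValueError("t test requires exactly 2 groups")
        a, b = groups
        res = stats.ttest_ind(a, b, equal_var=False)
        df = _welch_df(a, b)
        return {"statistic": float(res.statistic), "df": df, "p": float(res.pvalue)}
    if kind == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("Mann-Whitney requires exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return {"statistic": float(res.statistic), "p": float(res.pvalue)}
    if kind == "kruskal_wallis":
        res = stats.kruskal(*groups)
        return {
            "statistic": float(res.statistic),
            "df": len(groups) - 1,
            "p": float(res.pvalue),
        }
    if kind == "anova_r2":
        y = table[response].to_numpy(dtype=float)
        grand = y.mean()
        ss_total = float(np.sum((y - grand) ** 2))
        ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
        res = stats.f_oneway(*groups)
        return {
            "statistic": float(res.statistic),
            "df": (len(groups) - 1, len(y) - len(groups)),
            "p": float(res.pvalue),
            "r2": ss_between / ss_total if ss_total > 0 else np.nan,
        }
    raise ValueError(f"unknown test kind {kind!r}")


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return float(
        (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    )
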