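"""Group-comparison machinery: two-way ANOVA, Tukey HSD, letter displays.

The fixed-effects island x forest-type ANOVA (with interaction) and
the Tukey studentized-range post hoc are delegated to statsmodels;
compact letter displays are assigned with the insert-and-absorb
algorithm so that two groups share a letter iff their pairwise
comparison is non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "tukey_hsd",
    "letter_display",
    "cell_summary",
    "compare_metric",
]


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA table: one row per term (A, B, A:B, Residual)."""

    table: pd.DataFrame

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    names: tuple[str, str] = ("A", "B"),
) -> AnovaResult:
    """Crossed fixed-effects ANOVA with interaction.

    Uses Type-II sums of squares, which coincide with the classical
    decomposition for the balanced designs produced here.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": np.asarray(values, float), "fa": list(factor_a), "fb": list(factor_b)}
    )
    if df["fa"].nunique() < 2 or df["fb"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby(["fa", "fb"]).size()
    if counts.min() < 1 or len(counts) < df["fa"].nunique() * df["fb"].nunique():
        raise ValueError("design has an empty factor cell")
    if df["y"].nunique() == 1:
        warnings.warn("all responses identical: F undefined, p set to 1", stacklevel=2)
        n = len(df)
        a, b = df["fa"].nunique() - 1, df["fb"].nunique() - 1
        table = pd.DataFrame(
            {
                "df": [a, b, a * b, n - 1 - a - b - a * b],
                "SS": 0.0,
                "MS": 0.0,
                "F": [0.0, 0.0, 0.0, np.nan],
                "p": [1.0, 1.0, 1.0, np.nan],
            },
            index=[names[0], names[1], f"{names[0]}:{names[1]}", "Residual"],
        )
        return AnovaResult(table)
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov.index = [names[0], names[1], f"{names[0]}:{names[1]}", "Residual"]
    table = pd.DataFrame(
        {
            "df": aov["df"].astype(int),
            "SS": aov["sum_sq"],
            "MS": aov["sum_sq"] / aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
        }
    )
    return AnovaResult(table)


def tukey_hsd(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Tukey HSD on group means with pooled residual variance.

    Returns one row per unordered pair: difference in means, adjusted
    p, and the significance flag at ``alpha``.  Groups with a single
    observation are excluded with a warning.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame({"y": np.asarray(values, float), "g": list(groups)})
    sizes = df.groupby("g").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding single-observation group(s) {singletons}", stacklevel=2)
        df = df[~df["g"].isin(singletons)]
    if df["g"].nunique() < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    import itertools

    res = pairwise_tukeyhsd(df["y"], df["g"], alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group_i": [p[0] for p in pairs],
            "group_j": [p[1] for p in pairs],
            "difference": np.asarray(res.meandiffs, float),
            "p_adjusted": np.asarray(res.pvalues, float),
            "significant": np.asarray(res.reject, bool),
        }
    )


def letter_display(
    pairwise: pd.DataFrame, means: pd.Series | None = None
) -> dict[str, str]:
    """Compact letter display from a pairwise significance table.

    ``pairwise`` needs columns group_i, group_j, significant.  Letters
    are assigned by insert-and-absorb: start from one set holding all
    groups; for each significant pair split every set containing both;
    drop sets that became subsets of others.  Two groups share a letter
    iff their comparison is non-significant.  Letters are ordered by
    ascending group mean when ``means`` is given, else by group name.
    """
    groups = sorted(set(pairwise["group_i"]) | set(pairwise["group_j"]))
    sets: list[set[str]] = [set(groups)]
    for _, row in pairwise.iterrows():
        if not row["significant"]:
            continue
        i, j = row["group_i"], row["group_j"]
        new_sets: list[set[str]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend([s - {i}, s - {j}])
            else:
                new_sets.append(s)
        # absorb: keep only maximal sets, deduplicated
        sets = []
        for s in new_sets:
            if not s or any(s < t for t in new_sets):
                continue
            if s not in sets:
                sets.append(s)

    if means is not None:
        order = list(means.sort_values().index)
        key = lambda s: min(order.index(g) for g in s)  # noqa: E731
    else:
        key = lambda s: min(groups.index(g) for g in s)  # noqa: E731
    sets.sort(key=key)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in s:
            display[g] += letter
    return {g: "".join(sorted(v)) for g, v in display.items()}


def cell_summary(
    values: Sequence[float], factor_a: Sequence[str], factor_b: Sequence[str]
) -> pd.DataFrame:
    """Mean and standard error (sd / sqrt(n)) per factor-A x factor-B cell."""
    df = pd.DataFrame(
        {"y": np.asarray(values, float), "fa": list(factor_a), "fb": list(factor_b)}
    )

    def se(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = df.groupby(["fa", "fb"])["y"].agg(mean="mean", se=se, n="size").reset_index()
    return out.rename(columns={"fa": "factor_a", "fb": "factor_b"})


def compare_metric(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
    alpha: float = 0.05,
    names: tuple[str, str] = ("island", "forest_type"),
) -> dict:
    """Full comparison of one metric: two-way ANOVA, 9-cell Tukey HSD,
    letter display joined to the cell means."""
    anova = two_way_anova(values, factor_a, factor_b, names=names)
    cells = [f"{a}|{b}" for a, b in zip(factor_a, factor_b)]
    summary = cell_summary(values, factor_a, factor_b)
    summary["cell"] = summary["factor_a"] + "|" + summary["factor_b"]
    try:
        pairs = tukey_hsd(values, cells, alpha=alpha)
        means = summary.set_index("cell")["mean"]
        letters = letter_display(pairs, means=means)
    except ValueError:
        pairs = pd.DataFrame(
            columns=["group_i", "group_j", "difference", "p_adjusted", "significant"]
        )
        letters = {c: "a" for c in summary["cell"]}
    summary["letters"] = summary["cell"].map(letters)
    return {"anova": anova, "tukey": pairs, "summary": summary}
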