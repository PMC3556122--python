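"""Summary statistics and the clade-comparison ANOVA for methylation tables.

The scientific question is whether interindividual methylation variability
at LTR loci tracks phylogeny: per-locus summaries (mean, range, sd across
isogenic mice) are aggregated per clade, and the clade means are compared
with one-way ANOVA followed by Tukey HSD.  The unit of analysis for the
clade comparison is the per-locus mean (one value per locus), which avoids
pseudo-replicating across mice.

Tukey-adjusted p-values come from the studentized range distribution with
the Tukey-Kramer standard error for unequal group sizes; the distribution's
CDF is evaluated numerically (scipy's studentized_range).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quant import MethylationTable

__all__ = [
    "locus_summaries",
    "mouse_summaries",
    "grand_mean",
    "clade_statistics",
    "anova_tukey",
    "AnovaResult",
    "clade_anova",
]


def locus_summaries(table: MethylationTable, rounded: bool = False) -> pd.DataFrame:
    """Per-locus mean/median/sd/min/max/range/IQR over present cells.

    Standard deviation uses the n-1 (sample) denominator.  ``rounded=True``
    rounds every statistic to the nearest integer, matching how gel-derived
    tables are printed; unrounded values should feed any downstream test.
    """
    v = table.values
    out = pd.DataFrame({
        "n": v.notna().sum(),
        "mean": v.mean(),
        "median": v.median(),
        "sd": v.std(ddof=1),
        "min": v.min(),
        "max": v.max(),
        "range": v.max() - v.min(),
        "iqr": v.quantile(0.75) - v.quantile(0.25),
    })
    out.index.name = "locus"
    if rounded:
        out = out.round(0)
    return out


def mouse_summaries(table: MethylationTable) -> pd.DataFrame:
    """Per-mouse mean methylation across loci (present cells only)."""
    v = table.values
    out = pd.DataFrame({"n": v.notna().sum(axis=1), "mean": v.mean(axis=1)})
    out.index.name = "mouse"
    return out


def grand_mean(table: MethylationTable) -> float:
    """Mean over all present cells of the matrix."""
    return float(table.values.stack().mean())


def clade_statistics(table: MethylationTable,
                     clade_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-clade aggregation of (unrounded) locus statistics.

    clade mean = mean of the clade's locus means; clade mean range = mean of
    its locus ranges; pooled sd pools within-locus variances weighted by
    their degrees of freedom.
    """
    clades = pd.Series(clade_map) if clade_map is not None else table.clades
    if clades is None:
        raise ValueError("no locus -> clade mapping available")
    per_locus = locus_summaries(table)
    per_locus = per_locus.join(clades.rename("clade"))
    if per_locus["clade"].isna().any():
        missing = per_locus.index[per_locus["clade"].isna()].tolist()
        raise ValueError(f"loci without clade assignment: {missing}")
    rows = {}
    for clade, grp in per_locus.groupby("clade"):
        dfs = grp["n"] - 1
        pooled = np.sqrt((grp["sd"] ** 2 * dfs).sum() / dfs.sum())
        rows[clade] = {
            "n_loci": len(grp),
            "mean": grp["mean"].mean(),
            "mean_range": grp["range"].mean(),
            "pooled_sd": pooled,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "clade"
    out["n_loci"] = out["n_loci"].astype(int)
    return out


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_omnibus: float
    pairwise: pd.DataFrame  # group1, group2, diff, se, q, p_adj, reject
    group_means: pd.Series
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            "One-way ANOVA with Tukey HSD",
            f"F({self.df_between}, {self.df_within}) = {self.F:.4g}, "
            f"p = {self.p_omnibus:.4g}",
            "",
            "group means:",
        ]
        for g, m in self.group_means.items():
            lines.append(f"  {g}: {m:.3f}")
        lines.append("")
        lines.append(self.pairwise.to_string(index=False,
                                             float_format=lambda x: f"{x:.4g}"))
        return "\n".join(lines)


def anova_tukey(groups: Mapping[str, Sequence[float]],
                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise comparisons.

    F = MS_between / MS_within from the standard sums of squares.  Each pair
    (i, j) gets q = |mean_i - mean_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))
    (Tukey-Kramer) and an adjusted p from the studentized range distribution
    with (k, df_within).  Degenerate input with zero within-group variance
    yields F = 0 / p = 1 when all means are equal, F = inf / p = 0 otherwise.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(names)
    ns = {g: len(v) for g, v in data.items()}
    N = sum(ns.values())
    means = {g: v.mean() for g, v in data.items()}
    grand = sum(v.sum() for v in data.values()) / N
    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    ss_within = sum(((v - means[g]) ** 2).sum() for g, v in data.items())
    df_b, df_w = k - 1, N - k
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        equal = np.isclose(ss_between, 0.0)
        F = 0.0 if equal else np.inf
        p = 1.0 if equal else 0.0
    else:
        F = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            diff = means[gj] - means[gi]
            if ms_w == 0.0:
                se = 0.0
                q = 0.0 if diff == 0 else np.inf
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(ms_w / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
                q = abs(diff) / se
                p_adj = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0, 1))
            rows.append((gi, gj, diff, se, q, p_adj, p_adj < alpha))
    pairwise = pd.DataFrame(
        rows, columns=["group1", "group2", "diff", "se", "q", "p_adj", "reject"])
    return AnovaResult(float(F), df_b, df_w, p, pairwise,
                       pd.Series(means), alpha)


def clade_anova(table: MethylationTable,
                clade_map: Mapping[str, str] | None = None,
                alpha: float = 0.05) -> AnovaResult:
    """Clade comparison on per-locus means (one value per locus)."""
    clades = pd.Series(clade_map) if clade_map is not None else table.clades
    if clades is None:
        raise ValueError("no locus -> clade mapping available")
    locus_means = table.values.mean()
    groups = {
        str(clade): locus_means[idx.index].to_numpy()
        for clade, idx in clades.groupby(clades)
    }
    return anova_tukey(groups, alpha=alpha)


def boxplot_by_locus(table: MethylationTable, ax=None,
                     clade_colors: Mapping[str, str] | None = None):
    """Boxplot of per-locus methylation, loci grouped/coloured by clade."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    clades = table.clades
    loci = list(table.loci)
    if clades is not None:
        loci = sorted(loci, key=lambda l: (str(clades.get(l)), l))
    data = [table.values[l].dropna().to_numpy() for l in loci]
    bp = ax.boxplot(data, tick_labels=loci, patch_artist=True)
    if clades is not None:
        colors = clade_colors or {}
        for patch, locus in zip(bp["boxes"], loci):
            patch.set_facecolor(colors.get(str(clades.get(locus)), "lightgray"))
    ax.set_ylabel("percent methylation")
    ax.tick_params(axis="x", rotation=90)
    return ax
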