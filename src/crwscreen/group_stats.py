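"""Group-comparison machinery behind the summary tables.

Continuous variables are compared across the concordance groups with a
normality-gated pipeline: every group must pass a Kolmogorov-Smirnov
normality check (Lilliefors correction by default, since the reference
normal's parameters are estimated from the sample) for the variable to
be treated parametrically.  Parametric variables get one-way ANOVA with
Tukey-Kramer pairwise comparisons and are displayed as mean +/- SD;
otherwise Kruskal-Wallis with Bonferroni-adjusted pairwise rank tests
and a median (IQR) display.  Pairwise significance is condensed into a
compact letter display: groups that share no letter differ
significantly at the chosen level.

Categorical variables are compared with Pearson's chi-square test of
independence on the r x c contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupSummary",
    "ks_normality",
    "compare_numeric",
    "compare_categorical",
    "compact_letter_display",
    "category_table",
    "format_summary_table",
]


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    letters: str = ""


@dataclass(frozen=True)
class GroupSummary:
    """One variable's comparison across groups.

    ``display_mode`` records which branch the normality gate took:
    ``mean_sd`` (ANOVA + Tukey-Kramer) or ``median_iqr`` (Kruskal-Wallis
    + Bonferroni rank tests).  ``pairwise_p`` holds the post hoc
    p-values keyed by group pair; ``letters`` on each group satisfy:
    two groups share a letter iff their pairwise comparison is not
    significant at ``alpha``.
    """

    variable: str
    groups: dict[str, GroupStats]
    display_mode: str
    omnibus_p: float
    test_used: str
    alpha: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def ks_normality(values, variant: str = "lilliefors") -> float:
    """p-value of a Kolmogorov-Smirnov normality check.

    ``variant="lilliefors"`` (default) corrects for estimating the
    normal's mean and SD from the sample; ``variant="uncorrected"`` is
    the plain one-sample KS test against N(mean, sd) with the same
    estimates plugged in (anti-conservative, provided for comparison).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality check undefined")
    if variant == "lilliefors":
        _, p = lilliefors(x, dist="norm")
    elif variant == "uncorrected":
        _, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError("variant must be 'lilliefors' or 'uncorrected'")
    return float(p)


def compact_letter_display(
    group_names: Sequence[str],
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float,
) -> dict[str, str]:
    """Assign significance letters from a pairwise p-value matrix.

    Builds the graph whose edges join non-significantly-different
    groups; each maximal clique gets one letter, so two groups share a
    letter exactly when their comparison is non-significant.  Letters
    are ordered by the first group they cover.
    """
    g = nx.Graph()
    g.add_nodes_from(group_names)
    for (i, j), p in pairwise_p.items():
        if p >= alpha:
            g.add_edge(i, j)
    order = {name: k for k, name in enumerate(group_names)}
    cliques = sorted(nx.find_cliques(g), key=lambda c: min(order[m] for m in c))
    letters: dict[str, list[str]] = {name: [] for name in group_names}
    for k, clique in enumerate(cliques):
        letter = chr(ord("a") + k)
        for member in clique:
            letters[member].append(letter)
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


def _describe(x: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear (type-7) quartiles
    return dict(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def compare_numeric(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    variable: str = "",
    normality_variant: str = "lilliefors",
) -> GroupSummary:
    """Compare a continuous variable across labelled groups.

    The normality gate is per variable: all groups must pass for the
    parametric branch, matching a single display mode per table row.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {name: np.asarray(v, dtype=float) for name, v in groups.items()}
    for name, x in arrays.items():
        if x.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    names = list(arrays)
    samples = [arrays[n] for n in names]

    # groups too small for a meaningful normality check fall through to
    # the rank-based branch
    normal = all(x.size >= 4 and ks_normality(x, normality_variant) > alpha for x in samples)
    pairs = list(combinations(names, 2))
    pairwise: dict[tuple[str, str], float] = {}
    if normal:
        _, omnibus_p = stats.f_oneway(*samples)
        tukey = stats.tukey_hsd(*samples)
        for i, j in combinations(range(len(names)), 2):
            pairwise[(names[i], names[j])] = float(tukey.pvalue[i, j])
        mode, test = "mean_sd", "anova_tukey"
    else:
        _, omnibus_p = stats.kruskal(*samples)
        m = len(pairs)
        for i, j in pairs:
            _, p = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            pairwise[(i, j)] = min(1.0, float(p) * m)  # Bonferroni over the family
        mode, test = "median_iqr", "kruskal_bonferroni"

    letters = compact_letter_display(names, pairwise, alpha)
    stats_by_group = {
        name: GroupStats(letters=letters[name], **_describe(arrays[name])) for name in names
    }
    return GroupSummary(
        variable=variable,
        groups=stats_by_group,
        display_mode=mode,
        omnibus_p=float(omnibus_p),
        test_used=test,
        alpha=alpha,
        pairwise_p=pairwise,
    )


def compare_categorical(table) -> float:
    """Pearson chi-square p-value for independence on an r x c count
    table (rows: groups, columns: categories)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if t.min() < 0 or t.sum() <= 0:
        raise ValueError("cells must be nonnegative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero-margin row or column")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.pvalue)


def category_table(
    labels_by_group: Mapping[str, Sequence[str]],
    categories: Sequence[str],
) -> pd.DataFrame:
    """Counts and within-group percentages of a categorical variable.

    Rows are groups; for each category there is a ``<cat>_count`` and a
    ``<cat>_pct`` column (percent of the group's n, one decimal).
    """
    rows = {}
    for group, labels in labels_by_group.items():
        labels = list(labels)
        n = len(labels)
        row = {"n": n}
        for cat in categories:
            count = labels.count(cat)
            row[f"{cat}_count"] = count
            row[f"{cat}_pct"] = round(100.0 * count / n, 1) if n else 0.0
        rows[group] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def _num(x: float) -> str:
    s = f"{x:.1f}"
    return s[:-2] if s.endswith(".0") else s


def _p_str(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_summary_table(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Render comparisons as a display table, one row per variable.

    Parametric rows read ``mean +/- sd ^letters^``, nonparametric rows
    ``median (q1-q3) ^letters^``, with the omnibus p in the last column.
    """
    if not summaries:
        return pd.DataFrame()
    group_names = list(summaries[0].groups)
    rows = []
    for s in summaries:
        row = {"variable": s.variable}
        for name in group_names:
            g = s.groups[name]
            if s.display_mode == "mean_sd":
                cell = f"{_num(g.mean)} ± {_num(g.sd)} ^{g.letters}^"
            else:
                cell = f"{_num(g.median)} ({_num(g.q1)}–{_num(g.q3)}) ^{g.letters}^"
            row[name] = cell
        row["p"] = _p_str(s.omnibus_p)
        rows.append(row)
    return pd.DataFrame(rows, columns=["variable", *group_names, "p"])
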