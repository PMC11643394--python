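import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crwscreen.group_stats import (
    category_table,
    compact_letter_display,
    compare_categorical,
    compare_numeric,
    format_summary_table,
    ks_normality,
)

NAMES = ("N", "P-M", "D")
SIZES = (37, 75, 36)


def _groups(seed, means, sds, sizes=SIZES):
    rng = np.random.default_rng(seed)
    return {nm: rng.normal(mu, sd, n) for nm, mu, sd, n in zip(NAMES, means, sds, sizes)}


def test_ks_normality_discriminates():
    rng = np.random.default_rng(3)
    assert ks_normality(rng.normal(10, 2, 500)) > 0.05
    assert ks_normality(rng.exponential(2, 500)) < 0.05
    with pytest.raises(ValueError):
        ks_normality([5.0, 5.0, 5.0])
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0])


def test_uncorrected_variant_less_conservative():
    # plugging in estimated parameters without the correction inflates
    # the p-value relative to the corrected check
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 200)
    assert ks_normality(x, "uncorrected") >= ks_normality(x, "lilliefors")


def test_null_groups_share_a_letter():
    rng = np.random.default_rng(0)
    summary = compare_numeric({nm: rng.normal(10, 2, 50) for nm in NAMES})
    letters = {g.letters for g in summary.groups.values()}
    assert letters == {"a"}
    assert summary.omnibus_p > 0.05


def test_three_separated_normal_groups_get_distinct_letters():
    # group means/SDs mirroring the published BMI row
    summary = compare_numeric(_groups(0, (23.8, 21.5, 18.7), (2.7, 3.2, 2.7)))
    assert summary.test_used == "anova_tukey"
    assert summary.display_mode == "mean_sd"
    assert [summary.groups[nm].letters for nm in NAMES] == ["a", "b", "c"]
    assert summary.omnibus_p < 0.001


def test_two_close_one_low_group_pattern():
    # mirroring the published albumin row: the two healthier groups tie
    summary = compare_numeric(_groups(0, (3.7, 3.5, 3.1), (0.4, 0.5, 0.7)))
    assert [summary.groups[nm].letters for nm in NAMES] == ["a", "a", "b"]
    assert summary.omnibus_p < 0.001


def test_nonnormal_variable_takes_rank_branch():
    rng = np.random.default_rng(2)
    groups = {
        "N": rng.exponential(10, 60),
        "P-M": rng.exponential(10, 60),
        "D": rng.exponential(2, 60),
    }
    summary = compare_numeric(groups)
    assert summary.test_used == "kruskal_bonferroni"
    assert summary.display_mode == "median_iqr"
    assert summary.groups["N"].letters == summary.groups["P-M"].letters
    assert summary.groups["D"].letters not in (summary.groups["N"].letters,)


def test_compare_numeric_contract():
    with pytest.raises(ValueError):
        compare_numeric({"only": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError):
        compare_numeric({"a": [1.0], "b": [1.0, 2.0]})


@given(
    kps=st.integers(3, 6).flatmap(
        lambda k: st.tuples(
            st.just(k),
            st.lists(st.floats(0.0, 1.0), min_size=k * (k - 1) // 2, max_size=k * (k - 1) // 2),
        )
    ),
    alpha=st.sampled_from([0.01, 0.05, 0.1]),
)
@settings(max_examples=150, derandomize=True)
def test_letters_encode_the_significance_matrix(kps, alpha):
    """Two groups share a letter exactly when their pairwise comparison
    is non-significant, for arbitrary p-value matrices."""
    from itertools import combinations

    k, ps = kps
    names = [f"g{i}" for i in range(k)]
    pairs = list(combinations(names, 2))
    pairwise = dict(zip(pairs, ps))
    letters = compact_letter_display(names, pairwise, alpha)
    for (i, j), p in pairwise.items():
        shared = set(letters[i]) & set(letters[j])
        assert bool(shared) == (p >= alpha)


def test_quartiles_ordered(small_cohort):
    ages = {
        "young": [r.age for r in small_cohort if r.age < 80],
        "old": [r.age for r in small_cohort if r.age >= 80],
    }
    summary = compare_numeric(ages)
    for g in summary.groups.values():
        assert g.q1 <= g.median <= g.q3


def test_familywise_error_controlled_under_null():
    """With identically distributed groups, some pairwise difference is
    declared significant in at most ~alpha of families."""
    rng = np.random.default_rng(99)
    hits = 0
    reps = 600
    for _ in range(reps):
        groups = {nm: rng.normal(0, 1, 25) for nm in NAMES}
        s = compare_numeric(groups)
        hits += any(p < s.alpha for p in s.pairwise_p.values())
    assert hits / reps <= 0.05 + 0.025


def test_compare_categorical():
    assert compare_categorical([[50, 0], [0, 50]]) < 0.001
    assert compare_categorical([[30, 20], [30, 20], [60, 40]]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compare_categorical([[5, 5]])
    with pytest.raises(ValueError):
        compare_categorical([[5, 0], [5, 0]])


def test_category_table_percentages():
    table = category_table(
        {"N": ["none"] * 29 + ["severe"] * 2 + ["moderate"] * 6},
        ("none", "moderate", "severe"),
    )
    assert table.loc["N", "none_count"] == 29
    assert table.loc["N", "none_pct"] == 78.4
    assert table.loc["N", "severe_pct"] == 5.4


def test_format_summary_table_styles():
    parametric = compare_numeric(_groups(0, (23.8, 21.5, 18.7), (2.7, 3.2, 2.7)), variable="bmi")
    rng = np.random.default_rng(2)
    nonparam = compare_numeric(
        {nm: rng.exponential(5, 50) for nm in NAMES}, variable="intake"
    )
    out = format_summary_table([parametric, nonparam])
    assert list(out.columns) == ["variable", "N", "P-M", "D", "p"]
    bmi_cell = out.loc[out["variable"] == "bmi", "N"].item()
    assert "±" in bmi_cell and "^a^" in bmi_cell
    intake_cell = out.loc[out["variable"] == "intake", "N"].item()
    assert "(" in intake_cell and "–" in intake_cell
    assert format_summary_table([]).empty
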