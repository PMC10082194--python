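"""Association statistics: Fisher exact, diagnostics, rank tests, survival."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hrdkit.stats import (
    ContingencyTable,
    build_contingency,
    classify_methylation,
    diagnostic_metrics,
    fisher_exact_two_sided,
    km_and_gbw,
    mann_whitney_two_tailed,
    pearson_r,
)


def table(a, b, c, d):
    return ContingencyTable(a, b, c, d)


# ------------------------------------------------------------ Fisher exact

@pytest.mark.parametrize(
    "cells,printed,digits",
    [
        ((21, 8, 9, 17), 0.007, 3),
        ((10, 19, 3, 23), 0.06, 2),
        ((9, 20, 5, 21), 0.37, 2),
        ((15, 14, 6, 20), 0.0507, 4),
        ((14, 1, 6, 11), 0.001, 3),
    ],
)
def test_fisher_reproduces_printed_study_pvalues(cells, printed, digits):
    p = fisher_exact_two_sided(table(*cells))
    assert round(p, digits) == printed


def test_fisher_symmetric_small_tables():
    assert fisher_exact_two_sided(table(2, 1, 1, 2)) == pytest.approx(1.0)
    assert fisher_exact_two_sided(table(5, 0, 0, 5)) == pytest.approx(2 / 252)


def test_fisher_zero_margin_convention():
    with pytest.warns(UserWarning, match="zero margin"):
        assert fisher_exact_two_sided(table(0, 0, 3, 4)) == 1.0


def test_fisher_matches_scipy_on_random_tables():
    rng = np.random.default_rng(1)
    for _ in range(300):
        cells = rng.integers(0, 25, 4)
        if (cells[0] + cells[1] == 0) or (cells[2] + cells[3] == 0):
            continue
        if (cells[0] + cells[2] == 0) or (cells[1] + cells[3] == 0):
            continue
        t = table(*map(int, cells))
        assert fisher_exact_two_sided(t) == pytest.approx(
            sps.fisher_exact(t.as_array()).pvalue, rel=1e-9
        )


def test_fisher_invariant_under_transpose_and_swaps():
    t = table(12, 3, 5, 9)
    p = fisher_exact_two_sided(t)
    assert fisher_exact_two_sided(table(12, 5, 3, 9)) == pytest.approx(p)  # transpose
    assert fisher_exact_two_sided(table(5, 9, 12, 3)) == pytest.approx(p)  # row swap + col swap
    assert fisher_exact_two_sided(table(9, 5, 3, 12)) == pytest.approx(p)


# ------------------------------------------------------- contingency build

def annotations_55():
    """55 records reproducing the study's printed marginals.

    30 HRD / 25 HRP; 15 CR+PR (14 HRD), 14 SD (7 HRD), 26 PD (9 HRD);
    29 responders incl. SD, of which 21 HRD.
    """
    rows = []
    rows += [("HRD", "CR")] * 9 + [("HRD", "PR")] * 5 + [("HRD", "SD")] * 7 + [("HRD", "PD")] * 9
    rows += [("HRP", "CR")] * 1 + [("HRP", "SD")] * 7 + [("HRP", "PD")] * 17
    df = pd.DataFrame(rows, columns=["hrd_class", "response_category"])
    df["hrd_positive"] = (df["hrd_class"] == "HRD").astype(int)
    return df


def test_build_contingency_groupings():
    df = annotations_55()
    t, excluded = build_contingency(df, "hrd_positive", "cr_pr_sd_vs_pd")
    assert t.as_array().tolist() == [[21, 9], [8, 17]]
    assert excluded == 0
    m = diagnostic_metrics(t)
    assert round(100 * m.sensitivity) == 72 and round(100 * m.specificity) == 65
    t2, _ = build_contingency(df, "hrd_positive", "cr_pr_vs_rest")
    assert (t2.a + t2.c, t2.b + t2.d) == (15, 40)
    assert (t2.a, t2.c) == (14, 1)


def test_build_contingency_excludes_missing():
    df = annotations_55()
    df.loc[0, "response_category"] = "unknown"
    _, excluded = build_contingency(df, "hrd_positive", "cr_pr_sd_vs_pd")
    assert excluded == 1


def test_build_contingency_rejects_unknown_grouping():
    with pytest.raises(ValueError, match="grouping"):
        build_contingency(annotations_55(), "hrd_positive", "nope")


# -------------------------------------------------------------- diagnostics

def test_diagnostic_metrics_printed_values():
    # rows biomarker +/- , columns responder / non-responder:
    # 29 responders (21 HRD), 26 non-responders (17 HRP)
    m = diagnostic_metrics(table(21, 9, 8, 17))
    assert m.sensitivity == pytest.approx(21 / 29)
    assert m.specificity == pytest.approx(17 / 26)
    assert round(100 * m.sensitivity) == 72
    assert round(100 * m.specificity) == 65


def test_diagnostic_metrics_perfect_and_undefined():
    m = diagnostic_metrics(table(15, 0, 0, 40))
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)
    u = diagnostic_metrics(table(0, 3, 0, 4))
    assert u.sensitivity is None  # no responders: undefined, not zero


def test_sensitivity_plus_fnr_is_one():
    t = table(14, 1, 6, 11)
    m = diagnostic_metrics(t)
    fnr = t.c / (t.a + t.c)
    assert m.sensitivity + fnr == pytest.approx(1.0)
    assert m.sensitivity == pytest.approx(0.7)


# -------------------------------------------------------------- methylation

@pytest.mark.parametrize("pct,expected", [(95, "complete"), (90, "complete"),
                                          (50, "partial"), (40, "partial"), (0, "unmethylated")])
def test_methylation_bands(pct, expected):
    assert classify_methylation(pct) == expected


def test_methylation_between_bands_warns():
    with pytest.warns(UserWarning, match="between"):
        assert classify_methylation(75) == "partial"
    with pytest.raises(ValueError):
        classify_methylation(101)


# -------------------------------------------------------------- correlation

def test_pearson_known_values():
    x = np.array([1.0, 2, 3])
    assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    assert pearson_r([1, 2, 3], [1, 2, 4]) == pytest.approx(np.sqrt(27 / 28))


def test_pearson_degenerate():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])


# ------------------------------------------------------------- Mann-Whitney

def test_mann_whitney_complete_separation_exact():
    u, p, method = mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
    assert u == 0 and method == "exact"
    assert p == pytest.approx(0.1)


def test_mann_whitney_identical_samples():
    _, p, _ = mann_whitney_two_tailed([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_mann_whitney_matches_label_permutation_oracle():
    rng = np.random.default_rng(6)
    for _ in range(10):
        n, m = int(rng.integers(3, 7)), int(rng.integers(3, 7))
        pooled = rng.permutation(np.arange(1, n + m + 1)).astype(float)  # tie-free
        x, y = pooled[:n], pooled[n:]
        u_obs, p_obs, method = mann_whitney_two_tailed(x, y)
        assert method == "exact"
        # enumerate all label assignments
        stats = []
        for idx in itertools.combinations(range(n + m), n):
            xs = pooled[list(idx)]
            u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in np.delete(pooled, list(idx)))
            stats.append(u)
        stats = np.asarray(stats)
        mean_u = n * m / 2
        extreme = np.abs(stats - mean_u) >= abs(u_obs - mean_u) - 1e-9
        assert p_obs == pytest.approx(extreme.mean(), abs=1e-9)


# ----------------------------------------------------------------- survival

def test_km_median_uncensored():
    res = km_and_gbw([1, 2, 3, 10, 20, 30], [1] * 6, ["g"] * 3 + ["h"] * 3)
    assert res.medians["g"] == 2.0
    assert res.medians["h"] == 20.0


def test_km_reduces_to_empirical_survival_without_censoring():
    times = [2, 4, 4, 7, 9]
    res = km_and_gbw(times + [1, 2, 3], [1] * 5 + [1] * 3, ["a"] * 5 + ["b"] * 3)
    tab = res.km_tables["a"].set_index("time")["survival"]
    assert tab.loc[4.0] == pytest.approx(2 / 5)
    assert tab.loc[9.0] == pytest.approx(0.0)


def test_gbw_identical_groups_null():
    res = km_and_gbw([1, 2, 3, 1, 2, 3], [1] * 6, ["a"] * 3 + ["b"] * 3)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def gbw_statistic(t1, t2):
    """Independent Gehan-Breslow-Wilcoxon numerator/variance (no censoring helpers)."""
    times = np.concatenate([t1, t2])
    groups = np.array([0] * len(t1) + [1] * len(t2))
    obs = 0.0
    var = 0.0
    for t in np.unique(times):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 0)).sum()
        d = (times == t).sum()
        d1 = ((times == t) & (groups == 0)).sum()
        w = n  # number at risk: the Gehan-Breslow weight
        obs += w * (d1 - d * n1 / n)
        if n > 1:
            var += w**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs**2 / var


def test_gbw_matches_permutation_oracle():
    rng = np.random.default_rng(12)
    t1 = rng.exponential(1.0, 20).round(3) + 0.001
    t2 = rng.exponential(1.8, 20).round(3) + 0.001
    res = km_and_gbw(
        np.concatenate([t1, t2]), np.ones(40, dtype=int), ["a"] * 20 + ["b"] * 20
    )
    # permutation reference on the same weighted statistic
    pooled = np.concatenate([t1, t2])
    obs = gbw_statistic(t1, t2)
    n_perm = 4000
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += gbw_statistic(perm[:20], perm[20:]) >= obs - 1e-12
    p_perm = count / n_perm
    mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
    assert abs(res.p_value - p_perm) <= mc_err + 0.02


def test_gbw_requires_two_groups():
    with pytest.raises(ValueError):
        km_and_gbw([1, 2, 3], [1, 1, 1], ["a", "a", "a"])
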