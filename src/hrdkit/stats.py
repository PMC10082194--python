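"""Biomarker association statistics: contingency assembly, Fisher exact,
diagnostic metrics, methylation banding, correlation, rank tests and
Kaplan-Meier survival with the Gehan-Breslow-Wilcoxon test.

The two-sided Fisher exact test is computed by direct enumeration of the
hypergeometric distribution over all tables consistent with the observed
margins, summing the probabilities of tables no more probable than the
observed one (probability-mass ordering, the convention of standard
statistical software, with a small relative tolerance for ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

RESPONSE_GROUPINGS = {
    "cr_pr_sd_vs_pd": ({"CR", "PR", "SD"}, {"PD"}),
    "cr_pr_vs_rest": ({"CR", "PR"}, {"SD", "PD"}),
}

TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows biomarker +/-, columns responder/non-responder."""

    a: int  # biomarker+, responder
    b: int  # biomarker+, non-responder
    c: int  # biomarker-, responder
    d: int  # biomarker-, non-responder
    row_labels: tuple[str, str] = ("biomarker+", "biomarker-")
    col_labels: tuple[str, str] = ("responder", "non-responder")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def build_contingency(
    annotations: pd.DataFrame,
    biomarker: str,
    grouping: str = "cr_pr_sd_vs_pd",
    response_col: str = "response_category",
) -> tuple[ContingencyTable, int]:
    """Cross-classify a 0/1 biomarker column against a response grouping.

    ``grouping`` names the responder definition (no silent default is a
    deliberate non-choice: callers must pick one of
    ``cr_pr_sd_vs_pd`` or ``cr_pr_vs_rest``).  Records with missing
    biomarker or response values are excluded; their count is returned.
    """
    if annotations.empty:
        raise ValueError("empty annotation table")
    if grouping not in RESPONSE_GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; use one of {sorted(RESPONSE_GROUPINGS)}")
    responders, non_responders = RESPONSE_GROUPINGS[grouping]
    df = annotations[[biomarker, response_col]].copy()
    valid = df[biomarker].notna() & df[response_col].isin(responders | non_responders)
    excluded = int((~valid).sum())
    df = df[valid]
    flag = df[biomarker].astype(bool)
    resp = df[response_col].isin(responders)
    table = ContingencyTable(
        a=int((flag & resp).sum()),
        b=int((flag & ~resp).sum()),
        c=int((~flag & resp).sum()),
        d=int((~flag & ~resp).sum()),
        row_labels=(f"{biomarker}+", f"{biomarker}-"),
        col_labels=("responder", "non-responder"),
    )
    return table, excluded


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration.

    p = sum over all margin-consistent tables of hypergeometric
    probabilities <= the observed table's probability (relative tie
    tolerance 1e-7).  A zero margin returns p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = table.n
    if 0 in (r1, r2, c1, c2):
        warnings.warn("degenerate contingency table (zero margin): p = 1", stacklevel=2)
        return 1.0
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    # log hypergeometric pmf for cell (0,0) = k given the margins
    logp = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - (c1 - ks) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logp)
    p_obs = pmf[ks == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    return min(p, 1.0)


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV of biomarker+ for responder status.

    Metrics with a zero denominator are reported as None, never as 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d

    def frac(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return DiagnosticMetrics(
        sensitivity=frac(a, a + c),
        specificity=frac(d, b + d),
        ppv=frac(a, a + b),
        npv=frac(d, c + d),
    )


def classify_methylation(
    percent: float,
    complete_min: float = 90.0,
    partial_range: tuple[float, float] = (40.0, 60.0),
    detection_floor: float = 10.0,
) -> str:
    """Band a promoter-methylation percentage: unmethylated/partial/complete.

    Bands follow the observed separation between residual-expression
    tumours (~40-60% methylated) and fully silenced tumours (90-100%);
    values between bands classify as partial with a warning since the
    observed data leave them uncalibrated.
    """
    if not (0.0 <= percent <= 100.0):
        raise ValueError("methylation percent must be in [0, 100]")
    if percent >= complete_min:
        return "complete"
    lo, hi = partial_range
    if lo <= percent <= hi:
        return "partial"
    if percent < detection_floor:
        return "unmethylated"
    warnings.warn(
        f"methylation {percent}% falls between calibration bands; classifying as partial",
        stacklevel=2,
    )
    return "partial"


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    return float(sps.pearsonr(x, y).statistic)


def mann_whitney_two_tailed(x, y) -> tuple[float, float, str]:
    """Two-tailed Mann-Whitney U; exact for small tie-free samples.

    Exact enumeration when min(n, m) <= 10 and there are no ties across
    the pooled sample; normal approximation with tie correction
    otherwise.  Returns (U, p, method).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


@dataclass
class SurvivalResult:
    km_tables: dict[str, pd.DataFrame]  # per group: time, survival
    medians: dict[str, float]  # KM median (nan if never reached)
    statistic: float  # Gehan-Breslow-Wilcoxon chi-square (1 df)
    p_value: float


def km_and_gbw(
    times, events, groups, test_groups: tuple[str, str] | None = None
) -> SurvivalResult:
    """Kaplan-Meier curves per group and the Gehan-Breslow-Wilcoxon test.

    The GBW statistic is the log-rank family statistic with weights equal
    to the number at risk at each event time (Wilcoxon/Breslow
    weighting), chi-square on 1 df between two groups.
    """
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    labels = list(dict.fromkeys(df["group"]))
    km_tables, medians = {}, {}
    for g in labels:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        tab = kmf.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        km_tables[str(g)] = tab
        medians[str(g)] = float(kmf.median_survival_time_)
    if test_groups is None:
        if len(labels) != 2:
            raise ValueError("need exactly two groups for the GBW test")
        test_groups = (str(labels[0]), str(labels[1]))
    g1 = df[df["group"].astype(str) == test_groups[0]]
    g2 = df[df["group"].astype(str) == test_groups[1]]
    if g1.empty or g2.empty:
        raise ValueError("both test groups must be non-empty")
    res = logrank_test(
        g1["time"], g2["time"],
        event_observed_A=g1["event"], event_observed_B=g2["event"],
        weightings="wilcoxon",
    )
    return SurvivalResult(km_tables, medians, float(res.test_statistic), float(res.p_value))
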