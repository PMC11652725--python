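"""Descriptive layer: group summary tables, Welch two-sample t-tests, the
mixed-type Pearson correlation matrix, and intraclass correlation for repeat
scans.

Dichotomous variables (sex, scanner) enter the correlation matrix as 0/1
codes and the ordinal severity as its 0-3 code, so every entry is an ordinary
Pearson product-moment correlation (point-biserial correlations are
mathematically the same quantity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .schema import SEVERITY_GROUPS, Cohort

#: default variable order of the correlation matrix (mirrors the study's
#: demography -> smoking -> lung function -> severity -> CT metrics layout)
CORRELATION_VARIABLES = (
    "age",
    "sex",
    "bmi",
    "log_lung_size",
    "pack_years",
    "fev1_fvc",
    "fev1_pct_pred",
    "severity",
    "scanner",
    "log_wt",
    "log_tac",
    "log_tac_p",
)


@dataclass
class TTestResult:
    group1: str
    group2: str
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    n1: int
    n2: int
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class CorrelationMatrix:
    variables: tuple
    r: pd.DataFrame
    degenerate: tuple = ()  # zero-variance columns whose entries are undefined


@dataclass
class ICCResult:
    icc: float
    var_between: float
    var_within: float
    var_rater: float
    n: int
    k: int = 2
    variant: str = "icc2,1"


def group_summary(cohort: Cohort, variables) -> pd.DataFrame:
    """Per-severity-group mean/SD/count table.

    Rows are variables plus a leading ``participants`` row of counts and
    percentages (percentages sum to 100 across groups). SD for a
    single-participant group is reported as NaN, not 0. Binary variables
    additionally get within-group counts and percentages.
    """
    df = cohort.data
    for v in variables:
        if v not in df.columns:
            raise KeyError(f"unknown variable {v!r}")
    total = len(df)
    rows = {}
    counts = df.groupby("severity").size()
    rows[("participants", "count")] = {}
    rows[("participants", "percent")] = {}
    for level, gname in enumerate(SEVERITY_GROUPS):
        c = int(counts.get(level, 0))
        rows[("participants", "count")][gname] = c
        rows[("participants", "percent")][gname] = 100.0 * c / total if total else np.nan
    for v in variables:
        is_binary = set(np.unique(df[v])) <= {0, 1}
        for level, gname in enumerate(SEVERITY_GROUPS):
            vals = df.loc[df["severity"] == level, v].to_numpy(dtype=float)
            rows.setdefault((v, "mean"), {})[gname] = vals.mean() if len(vals) else np.nan
            rows.setdefault((v, "sd"), {})[gname] = (
                vals.std(ddof=1) if len(vals) > 1 else np.nan
            )
            rows.setdefault((v, "n"), {})[gname] = len(vals)
            if is_binary:
                rows.setdefault((v, "count"), {})[gname] = int(vals.sum())
                rows.setdefault((v, "percent"), {})[gname] = (
                    100.0 * vals.mean() if len(vals) else np.nan
                )
    out = pd.DataFrame(rows).T
    out.index = pd.MultiIndex.from_tuples(out.index, names=["variable", "stat"])
    return out[list(SEVERITY_GROUPS)]


def welch_ttest(x, y, group1: str = "group1", group2: str = "group2") -> TTestResult:
    """Welch (unequal-variance) two-sample t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(
                group1, group2, x.mean(), y.mean(), 0.0, 0.0, len(x), len(y), 0.0,
                float(len(x) + len(y) - 2), 1.0,
            )
        raise DegenerateDataError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(
        group1,
        group2,
        float(x.mean()),
        float(y.mean()),
        float(np.std(x, ddof=1)),
        float(np.std(y, ddof=1)),
        len(x),
        len(y),
        float(res.statistic),
        float(res.df),
        float(res.pvalue),
    )


def welch_ttest_summary(
    mean1, sd1, n1, mean2, sd2, n2, group1: str = "group1", group2: str = "group2"
) -> TTestResult:
    """Welch test from printed summary statistics (mean, SD, n per group)."""
    if n1 < 2 or n2 < 2:
        raise DegenerateDataError("each sample needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise DegenerateDataError("summary SDs must be positive")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    se2 = sd1**2 / n1 + sd2**2 / n2
    df = se2**2 / ((sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1))
    return TTestResult(
        group1, group2, float(mean1), float(mean2), float(sd1), float(sd2),
        int(n1), int(n2), float(t), float(df), float(p),
    )


def pairwise_group_tests(cohort: Cohort, variable: str) -> pd.DataFrame:
    """All six pairwise Welch comparisons of a variable across severity groups."""
    df = cohort.data
    out = []
    for i in range(4):
        for j in range(i + 1, 4):
            x = df.loc[df["severity"] == i, variable]
            y = df.loc[df["severity"] == j, variable]
            r = welch_ttest(x, y, SEVERITY_GROUPS[i], SEVERITY_GROUPS[j])
            out.append(
                {
                    "variable": variable,
                    "group1": r.group1,
                    "group2": r.group2,
                    "mean1": r.mean1,
                    "mean2": r.mean2,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "significant": r.significant,
                }
            )
    return pd.DataFrame(out)


def correlation_matrix(cohort: Cohort, variables=None) -> CorrelationMatrix:
    """Pearson correlation matrix with binary/ordinal columns as numeric codes.

    Zero-variance columns yield NaN entries and are reported in
    ``degenerate`` rather than silently coerced to 0.
    """
    df = cohort.data
    variables = tuple(variables) if variables is not None else tuple(
        v for v in CORRELATION_VARIABLES if v in df.columns
    )
    if len(df) < 3:
        raise DegenerateDataError("need at least 3 rows for correlations")
    sub = df[list(variables)].astype(float)
    sds = sub.std(ddof=1)
    degenerate = tuple(sds.index[sds == 0])
    r = sub.corr()  # pandas leaves zero-variance entries as NaN
    np.fill_diagonal(r.values, [np.nan if v in degenerate else 1.0 for v in variables])
    return CorrelationMatrix(variables=variables, r=r, degenerate=degenerate)


def icc(scan1, scan2, variant: str = "icc2,1") -> ICCResult:
    """Intraclass correlation of paired measurements.

    Default is ICC(2,1): two-way random effects, absolute agreement, single
    measurement; ``variant="icc1,1"`` gives the one-way random-effects form.
    Equals 1 exactly when the within-pair variance is 0.
    """
    x = np.asarray(scan1, dtype=float)
    y = np.asarray(scan2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("scan1/scan2 must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise DegenerateDataError("need at least 2 pairs")
    k = 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ms_rows = ss_rows / (n - 1)
    if variant == "icc1,1":
        ms_within = (ss_total - ss_rows) / (n * (k - 1))
        denom = ms_rows + (k - 1) * ms_within
        value = (ms_rows - ms_within) / denom if denom > 0 else np.nan
        return ICCResult(
            float(value), float(max(ms_rows - ms_within, 0.0) / k), float(ms_within), 0.0, n, k,
            variant,
        )
    if variant != "icc2,1":
        raise ValueError(f"unknown ICC variant {variant!r}")
    ss_err = ss_total - ss_rows - ss_cols
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_cols = ss_cols / (k - 1)
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    value = (ms_rows - ms_err) / denom if denom > 0 else np.nan
    return ICCResult(
        icc=float(value),
        var_between=float(max(ms_rows - ms_err, 0.0) / k),
        var_within=float(ms_err),
        var_rater=float(max(ms_cols - ms_err, 0.0) / n),
        n=n,
        k=k,
        variant=variant,
    )


def icc_report(repeats, variant: str = "icc2,1") -> pd.DataFrame:
    """ICC per metric for a :class:`~aircausal.simulate.RepeatMeasures` table."""
    rows = []
    for metric in repeats.data["metric"].unique():
        s1, s2 = repeats.pairs(metric)
        r = icc(s1, s2, variant=variant)
        rows.append(
            {
                "metric": metric,
                "icc": r.icc,
                "var_between": r.var_between,
                "var_within": r.var_within,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)
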