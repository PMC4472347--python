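"""Diagnostic accuracy metrics and association tests.

Benign-vs-cancer classification of methylation markers: confusion tables
at a percent-methylation cutoff, sensitivity/specificity/PPV/NPV, the
empirical ROC AUC, and thin wrappers around the standard nonparametric
association tests (Mann-Whitney, Kruskal-Wallis, Fisher exact, Pearson,
Spearman) returning a uniform result record. A sample is called positive
when its marker value is >= the cutoff.

Undefined metrics (zero denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ConfusionTable",
    "TestResult",
    "confusion_at_cutoff",
    "sens_spec_ppv_npv",
    "roc_auc",
    "mann_whitney",
    "kruskal_wallis",
    "fisher_exact",
    "pearson_r",
    "spearman_rho",
    "allred_classify",
    "diagnostics_report",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 classification counts; missing-value counts kept for audit."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_missing_cases: int = 0
    n_missing_controls: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass(frozen=True)
class TestResult:
    """Uniform container for a hypothesis-test outcome."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    return a[~np.isnan(a)]


def confusion_at_cutoff(case_values, control_values, cutoff: float) -> ConfusionTable:
    """Classify values against a cutoff: positive iff value >= cutoff.

    Missing (NaN) values are excluded from the table and counted.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("need at least one case and one control")
    c_ok, k_ok = _clean(cases), _clean(controls)
    if c_ok.size == 0 and k_ok.size == 0:
        raise ValidationError("all values missing")
    return ConfusionTable(
        tp=int(np.sum(c_ok >= cutoff)),
        fn=int(np.sum(c_ok < cutoff)),
        fp=int(np.sum(k_ok >= cutoff)),
        tn=int(np.sum(k_ok < cutoff)),
        n_missing_cases=int(np.isnan(cases).sum()),
        n_missing_controls=int(np.isnan(controls).sum()),
    )


def sens_spec_ppv_npv(t: ConfusionTable) -> tuple[float, float, float, float]:
    """Return (sensitivity, specificity, PPV, NPV); NaN where undefined."""

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return (
        ratio(t.tp, t.tp + t.fn),
        ratio(t.tn, t.tn + t.fp),
        ratio(t.tp, t.tp + t.fp),
        ratio(t.tn, t.tn + t.fn),
    )


def roc_auc(case_values, control_values) -> float:
    """Empirical ROC area: P(case > control) + 0.5*P(tie) over all pairs.

    Computed via midranks (equivalent to the trapezoidal area under the
    empirical ROC curve, and to the Mann-Whitney U statistic scaled by
    the number of case x control pairs). Missing values are excluded.
    """
    cases, controls = _clean(case_values), _clean(control_values)
    if cases.size == 0 or controls.size == 0:
        raise ValidationError("need at least one non-missing case and control")
    pooled = np.concatenate([cases, controls])
    ranks = stats.rankdata(pooled)
    r_cases = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    u = r_cases - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, midrank ties, tie-corrected normal
    approximation."""
    x, y = _clean(x), _clean(y)
    if x.size < 1 or y.size < 1:
        raise ValidationError("each group needs at least one observation")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups (tie-corrected chi-square)."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2 or any(g.size < 1 for g in cleaned):
        raise ValidationError("need >= 2 non-empty groups")
    res = stats.kruskal(*cleaned)
    return TestResult(
        "kruskal_wallis", float(res.statistic), float(res.pvalue), df=len(cleaned) - 1
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    p = sum of hypergeometric probabilities of tables (with the observed
    margins) no more probable than the observed one.
    """
    a = np.asarray(table)
    if a.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    if np.any(a < 0) or not np.issubdtype(a.dtype, np.integer):
        if np.any(a != np.floor(a)) or np.any(a < 0):
            raise ValidationError("counts must be non-negative integers")
    odds, p = stats.fisher_exact(a, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p))


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with two-sided p via the t-transform (n-2 df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return TestResult("pearson_r", float(res.statistic), float(res.pvalue), df=x.size - 2)


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation, two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return TestResult("spearman_rho", float(res.statistic), float(res.pvalue), df=x.size - 2)


def allred_classify(proportion_score: int, intensity_score: int) -> tuple[int, str]:
    """Allred immunohistochemistry score: proportion (0-5) + intensity (0-3).

    Total 0-2 is called negative, 3-8 positive.
    """
    if proportion_score not in range(6):
        raise ValidationError("proportion score must be an integer in 0-5")
    if intensity_score not in range(4):
        raise ValidationError("intensity score must be an integer in 0-3")
    total = proportion_score + intensity_score
    return total, ("negative" if total <= 2 else "positive")


def diagnostics_report(
    benign: pd.DataFrame,
    tumor: pd.DataFrame,
    genes,
    cutoffs=(1.0, 2.0),
) -> pd.DataFrame:
    """Per-gene AUC and operating characteristics at each requested cutoff.

    ``benign`` and ``tumor`` hold one methylation-percent column per gene.
    Returns one row per gene x cutoff with AUC, sens, spec, PPV, NPV and
    the Mann-Whitney p-value for the tumor-vs-benign shift.
    """
    rows = []
    for gene in genes:
        cases = tumor[gene].to_numpy(dtype=float)
        controls = benign[gene].to_numpy(dtype=float)
        auc = roc_auc(cases, controls)
        mw = mann_whitney(cases, controls)
        for cut in cutoffs:
            tab = confusion_at_cutoff(cases, controls, cut)
            sens, spec, ppv, npv = sens_spec_ppv_npv(tab)
            rows.append(
                {
                    "gene": gene,
                    "cutoff": cut,
                    "auc": auc,
                    "sensitivity": sens,
                    "specificity": spec,
                    "ppv": ppv,
                    "npv": npv,
                    "mann_whitney_p": mw.p_value,
                    "n_cases": tab.tp + tab.fn,
                    "n_controls": tab.tn + tab.fp,
                }
            )
    return pd.DataFrame(rows)
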