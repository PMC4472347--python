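"""Marker-to-risk modeling: functional form, optimal cutpoints, models.

The workflow mirrors how an explorative survival analysis treats a
continuous biomarker:

1. *Functional form.* Fit Cox models with linear, linear+quadratic, and
   restricted-cubic-spline terms in the marker and compare by likelihood
   ratio test; declare nonlinearity when either comparison rejects.
2. *Cutpoints.* When the relationship is nonlinear, search all possible
   dichotomizations (candidates are midpoints between consecutive
   distinct marker values) ranking by Cox partial log-likelihood; then
   fix the first cut and search all trichotomizations, modeling the
   low+high-vs-moderate indicator. Group-size and event floors exclude
   degenerate candidates. The full likelihood profile is returned so the
   selection is auditable; no multiplicity correction is applied over
   candidates (maximally-selected statistics are biased and the profile
   output documents this).
3. *Classification and models.* Trichotomize patients (low < cut1 <=
   moderate <= cut2 < high; boundaries belong to the moderate class) and
   build univariate plus multivariate Cox models over the methylation
   indicator and clinico-pathological covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import TestResult
from .errors import CutpointError, UnderpoweredError, ValidationError
from .survival import CoxFit, cox_fit, hazard_ratio, likelihood_ratio_test

__all__ = [
    "TrichotomyRule",
    "CutpointResult",
    "FunctionalFormResult",
    "spline_basis",
    "functional_form_scan",
    "dichotomize_search",
    "trichotomize_search",
    "two_stage_search",
    "classify",
    "classify_series",
    "build_table4_models",
]

#: Harrell-style knot placements (percentiles) by knot count
_KNOT_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


@dataclass(frozen=True)
class TrichotomyRule:
    """Two cuts defining low / moderate / high marker classes."""

    cut1: float
    cut2: float
    labels: tuple[str, str, str] = ("LM", "MM", "HM")

    def __post_init__(self) -> None:
        if not 0.0 < self.cut1 < self.cut2 < 100.0:
            raise ValidationError("cuts must satisfy 0 < cut1 < cut2 < 100")


@dataclass
class CutpointResult:
    """Discovered cutoff(s) with the likelihood profile that selected them."""

    cut1: float
    cut2: float | None
    profile: pd.DataFrame  # columns: cut, loglik, n_low/high (or per class), converged
    min_group_frac: float
    min_events: int


@dataclass
class FunctionalFormResult:
    verdict: str  # "linear" or "nonlinear"
    quadratic_vs_linear: TestResult
    spline_vs_linear: TestResult
    n: int
    n_events: int


def spline_basis(x, n_knots: int = 3, knots=None) -> np.ndarray:
    """Restricted (natural) cubic spline basis.

    Knots default to marker percentiles (10/50/90 for three knots). The
    basis has ``n_knots - 1`` columns: the marker itself plus
    ``n_knots - 2`` nonlinear terms that are exactly linear beyond the
    boundary knots (zero second derivative outside them).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots not in _KNOT_PERCENTILES:
            raise ValidationError(f"unsupported knot count {n_knots}; use 3, 4 or 5")
        finite = x[~np.isnan(x)]
        if np.unique(finite).size < n_knots:
            raise ValidationError(
                f"need >= {n_knots} distinct marker values for {n_knots} knots"
            )
        knots = np.percentile(finite, _KNOT_PERCENTILES[n_knots])
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValidationError("knots must be distinct (marker too concentrated)")
    k = knots.size
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    denom = (tk - t1) ** 2

    def plus3(v):
        return np.where(v > 0, v**3, 0.0)

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        col = (
            plus3(x - tj)
            - plus3(x - tk1) * (tk - tj) / (tk - tk1)
            + plus3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / denom
        cols.append(col)
    return np.column_stack(cols)


def _prep(records: pd.DataFrame, marker: str, time_col: str, event_col: str):
    if marker not in records.columns:
        raise ValidationError(f"marker column {marker!r} not in records")
    df = records.loc[records[marker].notna(), [time_col, event_col, marker]].copy()
    df = df.rename(columns={time_col: "time", event_col: "event"})
    df["event"] = df["event"].astype(int)
    return df.reset_index(drop=True)


def functional_form_scan(
    records: pd.DataFrame,
    marker: str,
    time_col: str = "followup_years",
    event_col: str = "cf_event",
    min_n: int = 30,
    min_events: int = 10,
    alpha: float = 0.05,
    n_knots: int = 3,
) -> FunctionalFormResult:
    """Test the marker-hazard relationship for departure from linearity.

    Cox fits with (a) a linear term, (b) linear+quadratic, (c) a
    restricted cubic spline are compared by LRT of (b) and (c) against
    (a); the verdict is "nonlinear" iff either test rejects at ``alpha``.
    Refuses underpowered inputs rather than fitting silently.
    """
    df = _prep(records, marker, time_col, event_col)
    n, n_events = len(df), int(df["event"].sum())
    if n < min_n or n_events < min_events:
        raise UnderpoweredError(
            f"functional-form scan needs >= {min_n} records and >= {min_events} "
            f"events; got n={n}, events={n_events}"
        )
    x = df[marker].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise ValidationError("marker must take >= 3 distinct values")

    base = df[["time", "event"]].copy()
    base["m"] = x
    fit_lin = cox_fit(base, ["m"])

    quad = base.copy()
    quad["m2"] = (x / 100.0) ** 2 * 100.0  # same percent scale, better conditioning
    fit_quad = cox_fit(quad, ["m", "m2"])

    sb = spline_basis(x, n_knots=n_knots)
    spl = df[["time", "event"]].copy()
    spline_cols = []
    for j in range(sb.shape[1]):
        col = f"s{j}"
        spl[col] = sb[:, j]
        spline_cols.append(col)
    fit_spl = cox_fit(spl, spline_cols)

    lrt_quad = likelihood_ratio_test(fit_lin, fit_quad)
    lrt_spl = likelihood_ratio_test(fit_lin, fit_spl)
    verdict = (
        "nonlinear"
        if (lrt_quad.p_value < alpha or lrt_spl.p_value < alpha)
        else "linear"
    )
    return FunctionalFormResult(verdict, lrt_quad, lrt_spl, n, n_events)


class _BinaryCoxScanner:
    """Fast univariate Cox fits on binary indicators over one dataset.

    The cutpoint search fits hundreds of single-indicator Cox models on
    the same (time, event) data; this solver pre-sorts once and exploits
    that for a binary covariate the Breslow risk-set sums reduce to
    suffix counts of the two groups. Its partial log-likelihood agrees
    with the generic :func:`~methrisk.survival.cox_fit` (Breslow ties).
    """

    def __init__(self, times: np.ndarray, events: np.ndarray):
        order = np.argsort(times, kind="stable")
        self.order = order
        ts = times[order]
        es = events[order].astype(bool)
        self.ev = es
        uniq, inv = np.unique(ts[es], return_inverse=True)
        self.starts = np.searchsorted(ts, uniq, side="left")
        self.d = np.bincount(inv).astype(float)
        self.n = len(ts)

    def fit(self, indicator: np.ndarray, tol: float = 1e-8, max_iter: int = 40):
        """Return (loglik, beta, converged) for the given 0/1 covariate."""
        z = indicator[self.order].astype(float)
        c1 = np.cumsum(z[::-1])[::-1]
        c1 = c1[self.starts]
        c0 = (self.n - self.starts) - c1
        m1 = float(z[self.ev].sum())
        d = self.d
        b = 0.0

        def parts(beta):
            eb = math.exp(beta)
            r0 = c0 + eb * c1
            q = eb * c1 / r0
            ll = beta * m1 - float((d * np.log(r0)).sum())
            g = m1 - float((d * q).sum())
            h = -float((d * q * (1.0 - q)).sum())
            return ll, g, h

        ll, g, h = parts(b)
        converged = False
        for _ in range(max_iter):
            if abs(g) < tol:
                converged = True
                break
            if h >= 0:
                break
            delta = -g / h
            step = 1.0
            while True:
                cand = b + step * delta
                new = parts(cand)
                if new[0] >= ll - 1e-12 or step < 1e-10:
                    break
                step *= 0.5
            b, (ll, g, h) = cand, new
            if abs(b) > 10.0 and abs(g) > tol:
                break  # monotone likelihood
        return ll, b, converged


def _admissible(ind: np.ndarray, events: np.ndarray, n_total: int,
                min_group_frac: float, min_events: int) -> bool:
    n1 = int(ind.sum())
    n0 = n_total - n1
    floor = min_group_frac * n_total
    if n1 < floor or n0 < floor:
        return False
    e1 = int(events[ind].sum())
    e0 = int(events.sum()) - e1
    return e1 >= min_events and e0 >= min_events


def dichotomize_search(
    records: pd.DataFrame,
    marker: str,
    time_col: str = "followup_years",
    event_col: str = "cf_event",
    min_group_frac: float = 0.10,
    min_events: int = 5,
) -> CutpointResult:
    """Exhaustive first-cut search ranked by Cox partial log-likelihood.

    Candidates are midpoints between consecutive distinct marker values;
    a candidate is admissible when both sides satisfy the group-size and
    event floors. Returns the maximizing cut with the full profile.
    """
    df = _prep(records, marker, time_col, event_col)
    x = df[marker].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    if np.unique(x).size < 2:
        raise CutpointError("marker is constant: no dichotomization possible")
    if events.sum() < 2 * min_events:
        raise CutpointError(
            f"need >= {2 * min_events} events for the event floor of {min_events}"
        )
    distinct = np.unique(x)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(df)
    scanner = _BinaryCoxScanner(
        df["time"].to_numpy(dtype=float), events.astype(float)
    )
    rows = []
    best = (-math.inf, None)
    sizes_short = events_short = 0
    for cut in candidates:
        ind = x > cut
        if not _admissible(ind, events, n, min_group_frac, min_events):
            n1 = int(ind.sum())
            if min(n1, n - n1) < min_group_frac * n:
                sizes_short += 1
            else:
                events_short += 1
            continue
        loglik, beta, converged = scanner.fit(ind.astype(float))
        rows.append(
            {
                "cut": cut,
                "loglik": loglik,
                "n_low": int(n - ind.sum()),
                "n_high": int(ind.sum()),
                "converged": converged,
            }
        )
        if converged and loglik > best[0]:
            best = (loglik, cut)
    if best[1] is None:
        raise CutpointError(
            "no admissible dichotomization: "
            f"{sizes_short} candidates failed the group-size floor, "
            f"{events_short} the event floor"
            + ("" if rows else " (and none converged)")
        )
    return CutpointResult(
        cut1=float(best[1]),
        cut2=None,
        profile=pd.DataFrame(rows),
        min_group_frac=min_group_frac,
        min_events=min_events,
    )


def trichotomize_search(
    records: pd.DataFrame,
    marker: str,
    fixed_cut1: float,
    time_col: str = "followup_years",
    event_col: str = "cf_event",
    min_group_frac: float = 0.10,
    min_events: int = 5,
) -> CutpointResult:
    """Second-cut search with the first cut fixed.

    Scans all midpoint candidates above ``fixed_cut1``; the model is a
    univariate Cox on the indicator (low or high) vs moderate induced by
    the candidate pair; floors apply to the indicator's two sides.
    """
    df = _prep(records, marker, time_col, event_col)
    x = df[marker].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    distinct = np.unique(x)
    above = distinct[distinct > fixed_cut1]
    if above.size < 2:
        raise CutpointError(
            f"fixed first cut {fixed_cut1} leaves < 2 distinct values above it"
        )
    candidates = (above[:-1] + above[1:]) / 2.0
    n = len(df)
    scanner = _BinaryCoxScanner(
        df["time"].to_numpy(dtype=float), events.astype(float)
    )
    rows = []
    best = (-math.inf, None)
    lm = x < fixed_cut1
    for cut2 in candidates:
        hm = x > cut2
        ind = lm | hm
        if not _admissible(ind, events, n, min_group_frac, min_events):
            continue
        loglik, beta, converged = scanner.fit(ind.astype(float))
        rows.append(
            {
                "cut": cut2,
                "loglik": loglik,
                "n_lm": int(lm.sum()),
                "n_mm": int(n - ind.sum()),
                "n_hm": int(hm.sum()),
                "converged": converged,
            }
        )
        if converged and loglik > best[0]:
            best = (loglik, cut2)
    if best[1] is None:
        raise CutpointError(
            f"no admissible second cut above {fixed_cut1} under the "
            f"group-size ({min_group_frac:.0%}) and event ({min_events}) floors"
        )
    return CutpointResult(
        cut1=float(fixed_cut1),
        cut2=float(best[1]),
        profile=pd.DataFrame(rows),
        min_group_frac=min_group_frac,
        min_events=min_events,
    )


def two_stage_search(
    records: pd.DataFrame,
    marker: str,
    **kwargs,
) -> TrichotomyRule:
    """First search all dichotomizations, then all trichotomizations with
    the first cut fixed; returns the resulting trichotomy rule."""
    first = dichotomize_search(records, marker, **kwargs)
    second = trichotomize_search(records, marker, first.cut1, **kwargs)
    return TrichotomyRule(cut1=second.cut1, cut2=second.cut2)


def classify(value: float, rule: TrichotomyRule) -> str | None:
    """Assign one marker value to a class: low (< cut1), moderate
    ([cut1, cut2], closed at both ends), or high (> cut2). Missing
    values propagate as None."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if not 0.0 <= value <= 100.0:
        raise ValidationError(f"methylation percent {value} outside [0, 100]")
    lm, mm, hm = rule.labels
    if value < rule.cut1:
        return lm
    if value > rule.cut2:
        return hm
    return mm


def classify_series(values: pd.Series, rule: TrichotomyRule) -> pd.Series:
    """Vectorized :func:`classify`; missing stays missing."""
    return pd.Series(
        [classify(v, rule) for v in values.astype(float)],
        index=values.index,
        dtype="string",
    )


def _indicator_columns(records: pd.DataFrame, rule: TrichotomyRule, marker: str):
    """Derive the model covariates used in the prognostic tables."""
    lm, mm, hm = rule.labels
    groups = classify_series(records[marker], rule)
    out = pd.DataFrame(index=records.index)
    out["lm_hm"] = pd.array(
        [pd.NA if pd.isna(g) else float(g != mm) for g in groups], dtype="Float64"
    )
    out["pt_3b_4"] = pd.array(
        [
            pd.NA if pd.isna(v) else float(v in ("pT3b", "pT4"))
            for v in records["pt_group"]
        ],
        dtype="Float64",
    )
    out["gleason_8_10"] = pd.array(
        [pd.NA if pd.isna(v) else float(v == "8-10") for v in records["gleason_group"]],
        dtype="Float64",
    )
    out["psa"] = records["psa"].astype("Float64")
    return out


#: human-readable contrast per model row
_CONTRASTS = {
    "lm_hm": "trichotomized marker: MM vs LM+HM",
    "pt_3b_4": "pathological T stage 2-3a vs 3b-4",
    "gleason_8_10": "Gleason score 2-7 vs 8-10",
    "psa": "preoperative PSA continuous",
}


def build_table4_models(
    records: pd.DataFrame,
    rule: TrichotomyRule,
    marker: str = "GSTP1",
    time_col: str = "followup_years",
    event_col: str = "cf_event",
    tie_method: str = "breslow",
) -> tuple[pd.DataFrame, dict]:
    """Univariate and multivariate Cox models for the prognostic table.

    Variables: the low+high-vs-moderate methylation indicator, the
    pathological-stage indicator (pT3b-4 vs pT2-3a), the Gleason
    indicator (8-10 vs 2-7), and continuous PSA. Missing covariates are
    handled complete-case per model; dropped-record counts are returned
    in the log. Non-converged models yield flagged rows with NaN
    estimates, never silent omission.
    """
    ind = _indicator_columns(records, rule, marker)
    base = pd.DataFrame(
        {
            "time": records[time_col].to_numpy(dtype=float),
            "event": records[event_col].to_numpy(dtype=int),
        },
        index=records.index,
    )
    variables = ["lm_hm", "pt_3b_4", "gleason_8_10", "psa"]
    rows = []
    log: dict[str, object] = {"n_total": len(records), "dropped": {}}

    uni_results = {}
    for var in variables:
        keep = ind[var].notna() & base["time"].notna()
        log["dropped"][f"univariate_{var}"] = int((~keep).sum())
        sub = base.loc[keep].copy()
        sub[var] = ind.loc[keep, var].astype(float)
        try:
            fit = cox_fit(sub, [var], tie_method=tie_method)
            if fit.converged:
                uni_results[var] = hazard_ratio(fit, var) + (int(keep.sum()), True)
            else:
                uni_results[var] = (np.nan,) * 4 + (int(keep.sum()), False)
        except ValidationError:
            uni_results[var] = (np.nan,) * 4 + (int(keep.sum()), False)

    keep_all = ind.notna().all(axis=1)
    log["dropped"]["multivariate"] = int((~keep_all).sum())
    multi = base.loc[keep_all].copy()
    for var in variables:
        multi[var] = ind.loc[keep_all, var].astype(float)
    multi_fit = None
    try:
        multi_fit = cox_fit(multi, variables, tie_method=tie_method)
    except ValidationError:
        pass
    log["multivariate_n"] = int(keep_all.sum())
    log["multivariate_converged"] = bool(multi_fit is not None and multi_fit.converged)

    for var in variables:
        hr_u, lo_u, hi_u, p_u, n_u, ok_u = uni_results[var]
        if multi_fit is not None and multi_fit.converged:
            hr_m, lo_m, hi_m, p_m = hazard_ratio(multi_fit, var)
            ok_m = True
        else:
            hr_m = lo_m = hi_m = p_m = np.nan
            ok_m = False
        rows.append(
            {
                "variable": var,
                "contrast": _CONTRASTS[var],
                "n_univariate": n_u,
                "hr_univariate": hr_u,
                "ci_low_univariate": lo_u,
                "ci_high_univariate": hi_u,
                "p_univariate": p_u,
                "univariate_converged": ok_u,
                "hr_multivariate": hr_m,
                "ci_low_multivariate": lo_m,
                "ci_high_multivariate": hi_m,
                "p_multivariate": p_m,
                "multivariate_converged": ok_m,
            }
        )
    return pd.DataFrame(rows), log
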