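"""Survival substrate: Kaplan-Meier, log-rank, and Cox proportional hazards.

The Cox fitter maximises the partial likelihood by Newton-Raphson with
step-halving, Breslow tie handling by default (Efron available), a
gradient-norm convergence tolerance of 1e-8, and explicit detection of
monotone-likelihood divergence (coefficients growing without bound, as
happens when a covariate perfectly separates event order). The partial
log-likelihood is exposed because the optimal-cutpoint search ranks
candidate dichotomizations by it.

Records are plain pandas DataFrames with a positive ``time`` column
(years), a 0/1 ``event`` column, and one column per covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import TestResult
from .errors import ConvergenceError, ValidationError

__all__ = [
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "hazard_ratio",
    "likelihood_ratio_test",
]

_GRAD_TOL = 1e-8
_MAX_ITER = 50
_BETA_DIVERGENCE = 10.0


def _extract(records: pd.DataFrame, time_col: str, event_col: str):
    t = records[time_col].to_numpy(dtype=float)
    e = records[event_col].to_numpy(dtype=float)
    if np.any(np.isnan(t)) or np.any(t <= 0):
        raise ValidationError("all survival times must be positive and non-missing")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValidationError("event indicator must be 0 or 1")
    return t, e.astype(int)


def km_estimate(
    records: pd.DataFrame, time_col: str = "time", event_col: str = "event"
) -> pd.DataFrame:
    """Product-limit estimate of the survival function.

    Returns one row per distinct observed time with the risk-set size,
    event count, censoring count and right-continuous survival estimate
    S(t) = prod_{t_i <= t} (1 - d_i/n_i). Subjects censored at an event
    time remain in the risk set for that time (events precede censorings
    at ties).
    """
    if len(records) == 0:
        raise ValidationError("need at least one record")
    t, e = _extract(records, time_col, event_col)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    times, first = np.unique(ts, return_index=True)
    n = len(ts)
    rows = []
    surv = 1.0
    for u, k in zip(times, first):
        at_risk = n - k
        mask = ts == u
        d = int(es[mask].sum())
        c = int(mask.sum() - d)
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append(
            {
                "time": u,
                "n_risk": at_risk,
                "n_events": d,
                "n_censored": c,
                "survival": surv,
            }
        )
    return pd.DataFrame(rows)


def logrank_test(
    groups, time_col: str = "time", event_col: str = "event"
) -> TestResult:
    """k-sample log-rank test (observed minus expected, hypergeometric
    variance), chi-square with k-1 degrees of freedom."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    ts, es, gs = [], [], []
    for gi, g in enumerate(groups):
        if len(g) == 0:
            raise ValidationError("groups must be non-empty")
        t, e = _extract(g, time_col, event_col)
        ts.append(t)
        es.append(e)
        gs.append(np.full(len(t), gi))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    if e.sum() == 0:
        raise ValidationError("log-rank test undefined with zero events")
    k = len(groups)
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for u in event_times:
        at_risk = t >= u
        n_i = at_risk.sum()
        d_i = int(((t == u) & (e == 1)).sum())
        n_ij = np.array([(at_risk & (g == j)).sum() for j in range(k)], dtype=float)
        d_ij = np.array(
            [((t == u) & (e == 1) & (g == j)).sum() for j in range(k)], dtype=float
        )
        observed += d_ij
        expected += d_i * n_ij / n_i
        if n_i > 1:
            frac = d_i * (n_i - d_i) / (n_i - 1.0)
            p = n_ij / n_i
            var += frac * (np.diag(p) - np.outer(p, p))
    diff = (observed - expected)[: k - 1]
    v = var[: k - 1, : k - 1]
    if np.allclose(diff, 0.0) or np.allclose(v, 0.0):
        stat = 0.0
    else:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    df = k - 1
    return TestResult("logrank", stat, float(stats.chi2.sf(stat, df)), df=df)


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model."""

    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    covariate_names: list[str]
    n: int
    n_events: int
    converged: bool
    tie_method: str
    n_iter: int
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """x'beta on new records (columns looked up by covariate name)."""
        missing = [c for c in self.covariate_names if c not in records.columns]
        if missing:
            raise ValidationError(f"records lack covariate columns: {missing}")
        X = records[self.covariate_names].to_numpy(dtype=float)
        if np.any(np.isnan(X)):
            raise ValidationError("missing covariate values in records")
        return X @ self.coef


def _pl_derivatives(ts, es, Xs, beta, tie_method):
    """Partial log-likelihood, gradient and Hessian at beta.

    Inputs must be pre-sorted by ascending time. The risk set at an event
    time includes subjects censored at that same time. Shifting the linear
    predictor by its maximum leaves the partial likelihood unchanged and
    keeps the exponentials finite.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.max()
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]
    # suffix (risk-set) sums: index k holds sums over all times >= ts[k]
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev = es == 1
    uniq_times, inv = np.unique(ts[ev], return_inverse=True)
    starts = np.searchsorted(ts, uniq_times, side="left")
    d_counts = np.bincount(inv)

    ll = float(eta[ev].sum())
    grad = Xs[ev].sum(axis=0).astype(float)
    hess = np.zeros((p, p))

    # event times handled by the plain (Breslow-style) risk-set term:
    # all of them under Breslow, the untied ones under Efron.
    simple = (
        np.ones(len(uniq_times), dtype=bool)
        if tie_method == "breslow"
        else d_counts == 1
    )
    if simple.any():
        k = starts[simple]
        dd = d_counts[simple].astype(float)
        r0 = s0[k]
        r1 = s1[k]
        r2 = s2[k]
        q1 = r1 / r0[:, None]
        ll -= float((dd * np.log(r0)).sum())
        grad -= (dd[:, None] * q1).sum(axis=0)
        hess -= (
            dd[:, None, None]
            * (r2 / r0[:, None, None] - q1[:, :, None] * q1[:, None, :])
        ).sum(axis=0)
    for ut, k, d in zip(uniq_times[~simple], starts[~simple], d_counts[~simple]):
        r0, r1, r2 = s0[k], s1[k], s2[k]
        in_tie = ev & (ts == ut)
        d0 = w[in_tie].sum()
        d1 = wx[in_tie].sum(axis=0)
        d2 = wxx[in_tie].sum(axis=0)
        for j in range(d):
            f = j / d
            a0 = r0 - f * d0
            a1 = r1 - f * d1
            a2 = r2 - f * d2
            ll -= np.log(a0)
            grad -= a1 / a0
            hess -= a2 / a0 - np.outer(a1 / a0, a1 / a0)
    return ll, grad, hess


def cox_fit(
    records: pd.DataFrame,
    covariate_names,
    tie_method: str = "breslow",
    time_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Maximise the Cox partial likelihood by Newton-Raphson.

    Raises on constant covariates or zero events. Monotone-likelihood
    divergence (|beta| exceeding 10 with the gradient still far from
    zero) is reported via ``converged=False``, not an exception, so the
    caller can flag rather than lose the row.
    """
    covariate_names = list(covariate_names)
    if tie_method not in ("breslow", "efron"):
        raise ValidationError("tie_method must be 'breslow' or 'efron'")
    t, e = _extract(records, time_col, event_col)
    X = records[list(covariate_names)].to_numpy(dtype=float)
    if np.any(np.isnan(X)):
        raise ValidationError("missing covariate values; drop incomplete records first")
    if e.sum() == 0:
        raise ValidationError("cannot fit a Cox model with zero events")
    sds = X.std(axis=0)
    constant = [name for name, s in zip(covariate_names, sds) if s == 0]
    if constant:
        raise ValidationError(f"constant covariates: {constant}")

    # standardise internally for conditioning; back-transform afterwards
    means, scales = X.mean(axis=0), sds
    Z = (X - means) / scales

    order = np.argsort(t, kind="stable")
    ts, es, Zs = t[order], e[order], Z[order]

    p = Z.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _pl_derivatives(ts, es, Zs, beta, tie_method)
    loglik_null = ll
    converged = False
    message = ""
    it = 0
    for it in range(1, _MAX_ITER + 1):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < _GRAD_TOL:
            converged = True
            break
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            # collinear covariates: take the minimum-norm Newton step
            delta = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        step = 1.0
        while True:
            cand = beta + step * delta
            new = _pl_derivatives(ts, es, Zs, cand, tie_method)
            if new[0] >= ll - 1e-12 or step < 1e-10:
                break
            step *= 0.5
        beta, (ll, grad, hess) = cand, new
        # scale-free divergence check: standardised coefficients
        if np.abs(beta).max() > _BETA_DIVERGENCE and np.linalg.norm(grad) > _GRAD_TOL:
            message = "monotone partial likelihood: coefficient diverging"
            break
    else:
        message = "maximum iterations reached"

    info = -hess
    try:
        cov_z = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_z = np.full((p, p), np.nan)
        converged = False
        message = message or "singular information matrix at optimum"

    # back-transform: beta_x = beta_z / scale; cov scales accordingly.
    inv_s = 1.0 / scales
    coef = beta * inv_s
    cov = cov_z * np.outer(inv_s, inv_s)
    return CoxFit(
        coef=coef,
        cov=cov,
        loglik=float(ll),
        loglik_null=float(loglik_null),
        covariate_names=covariate_names,
        n=len(t),
        n_events=int(e.sum()),
        converged=converged,
        tie_method=tie_method,
        n_iter=it,
        message=message,
    )


def hazard_ratio(fit: CoxFit, name: str) -> tuple[float, float, float, float]:
    """(HR, 95% CI low, CI high, two-sided Wald p) for one covariate."""
    if not fit.converged:
        raise ConvergenceError(f"fit did not converge: {fit.message}")
    if name not in fit.covariate_names:
        raise ValidationError(f"unknown covariate {name!r}")
    i = fit.covariate_names.index(name)
    b, se = fit.coef[i], fit.se[i]
    if se == 0:
        return float(np.exp(b)), float(np.exp(b)), float(np.exp(b)), 0.0 if b else 1.0
    z = b / se
    return (
        float(np.exp(b)),
        float(np.exp(b - 1.959963984540054 * se)),
        float(np.exp(b + 1.959963984540054 * se)),
        float(2.0 * stats.norm.sf(abs(z))),
    )


def likelihood_ratio_test(fit_null: CoxFit, fit_full: CoxFit) -> TestResult:
    """LRT of nested Cox fits on identical records: 2*(ll_full - ll_null),
    chi-square with df = difference in coefficient counts."""
    if fit_null.n != fit_full.n or fit_null.n_events != fit_full.n_events:
        raise ValidationError("models must be fitted on identical records")
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    if stat < -1e-6:
        raise ValidationError(
            "full model has lower likelihood than null: models not nested"
        )
    stat = max(stat, 0.0)
    df = len(fit_full.covariate_names) - len(fit_null.covariate_names)
    if df < 0:
        raise ValidationError("full model has fewer coefficients than null")
    if df == 0:
        p = 1.0 if stat <= 1e-6 else 0.0
    else:
        p = float(stats.chi2.sf(stat, df))
    return TestResult("likelihood_ratio", float(stat), p, df=df)
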