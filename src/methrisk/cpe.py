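"""Concordance Probability Estimate and repeated-subsampling validation.

For a proportional-hazards model with linear predictors eta_i, the
probability that the subject with the lower predictor outlives the other
is 1/(1 + exp(-|eta_i - eta_j|)). Averaging this over all unordered
subject pairs gives the concordance probability estimate (CPE)

    K = 2/(n(n-1)) * sum_{i<j} 1 / (1 + exp(-|eta_i - eta_j|)),

a model-based analogue of the ROC AUC for time-to-event models: 0.5 when
the model carries no predictive value (all predictors equal) and
approaching 1 for perfect separation. Because it is computed from the
fitted predictors alone it needs no event/censoring indicators and is
well suited to small test sets.

Model comparison uses repeated random sub-sampling cross-validation:
many independent train/test splits; any methylation categorization is
re-tuned on the training subset only; Cox weights are fitted on train
and the CPE evaluated on the test subjects; per-split CPE pairs are
compared by a paired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .diagnostics import TestResult
from .errors import ValidationError
from .stratify import TrichotomyRule, classify_series, two_stage_search
from .survival import CoxFit, cox_fit

__all__ = [
    "CPEResult",
    "CVComparison",
    "ModelSpec",
    "cpe",
    "model_cpe",
    "paired_t_test",
    "cv_compare",
]


@dataclass(frozen=True)
class CPEResult:
    estimate: float
    n_pairs: int


@dataclass(frozen=True)
class ModelSpec:
    """Covariates of one Cox model; if ``methylation_marker`` is set the
    low/moderate/high categorization of that marker is tuned on each
    training subset and its low+high indicator enters the model."""

    name: str
    covariates: tuple[str, ...]
    methylation_marker: str | None = None
    fixed_rule: TrichotomyRule | None = None  # transfer a rule instead of tuning


@dataclass
class CVComparison:
    per_split: pd.DataFrame  # columns: cpe_a, cpe_b
    mean_a: float
    mean_b: float
    halfwidth_a: float
    halfwidth_b: float
    paired_t: TestResult
    n_splits: int
    train_frac: float
    seed: int
    n_failed_splits: int


def cpe(linear_predictors) -> CPEResult:
    """Concordance probability estimate over all unordered pairs.

    Tied predictors contribute exactly 0.5; the |difference| form bounds
    the estimate in [0.5, 1].
    """
    eta = np.asarray(linear_predictors, dtype=float)
    if eta.ndim != 1 or eta.size < 2:
        raise ValidationError("need >= 2 linear predictors")
    if np.any(np.isnan(eta)):
        raise ValidationError("linear predictors contain NaN")
    n = eta.size
    total = 0.0
    # chunked pairwise |differences|; O(n^2) time, bounded memory
    chunk = max(1, int(4_000_000 // max(n, 1)))
    for start in range(0, n - 1, chunk):
        stop = min(start + chunk, n - 1)
        block = eta[start:stop, None] - eta[None, start + 1 :]
        # keep strictly upper-triangular part of this block
        rows = np.arange(start, stop)[:, None]
        cols = np.arange(start + 1, n)[None, :]
        mask = cols > rows
        total += float(expit(np.abs(block[mask])).sum())
    n_pairs = n * (n - 1) // 2
    return CPEResult(estimate=total / n_pairs, n_pairs=n_pairs)


def model_cpe(fit: CoxFit, records: pd.DataFrame) -> CPEResult:
    """CPE of a fitted Cox model evaluated on (possibly new) records.

    Linear predictors are computed with the fit's coefficients on the
    supplied records, enabling train-fitted / test-evaluated use.
    """
    from .errors import ConvergenceError

    if not fit.converged:
        raise ConvergenceError(f"fit did not converge: {fit.message}")
    return cpe(fit.linear_predictor(records))


def paired_t_test(a, b) -> TestResult:
    """Two-sided paired t-test; identical vectors give t = 0, p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need >= 2 pairs")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult("paired_t", 0.0, 1.0, df=n - 1)
        return TestResult("paired_t", math.inf if d.mean() > 0 else -math.inf, 0.0, df=n - 1)
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TestResult("paired_t", float(t), p, df=n - 1)


def _split_features(
    train: pd.DataFrame,
    test: pd.DataFrame,
    spec: ModelSpec,
    time_col: str,
    event_col: str,
    search_kwargs: dict,
):
    """Assemble model columns for one split; tunes the marker rule on train."""
    cov = list(spec.covariates)
    frames = []
    for part in (train, test):
        f = pd.DataFrame(
            {
                "time": part[time_col].to_numpy(dtype=float),
                "event": part[event_col].to_numpy(dtype=int),
            }
        )
        for c in spec.covariates:
            vals = part[c]
            f[c] = np.asarray(vals, dtype=float)
        frames.append(f)
    if spec.methylation_marker is not None:
        rule = spec.fixed_rule
        if rule is None:
            rule = two_stage_search(
                train,
                spec.methylation_marker,
                time_col=time_col,
                event_col=event_col,
                **search_kwargs,
            )
        mm = rule.labels[1]
        for f, part in zip(frames, (train, test)):
            groups = classify_series(part[spec.methylation_marker], rule)
            f["lm_hm"] = np.asarray(
                [np.nan if pd.isna(g) else float(g != mm) for g in groups], dtype=float
            )
        cov.append("lm_hm")
    tr, te = frames
    tr = tr.dropna()
    te = te.dropna()
    return tr.reset_index(drop=True), te.reset_index(drop=True), cov


def cv_compare(
    records: pd.DataFrame,
    model_a: ModelSpec,
    model_b: ModelSpec,
    n_splits: int = 200,
    train_frac: float = 0.80,
    seed: int = 0,
    time_col: str = "followup_years",
    event_col: str = "cf_event",
    tie_method: str = "breslow",
    max_failure_frac: float = 0.10,
    stratify_events: bool = False,
    **search_kwargs,
) -> CVComparison:
    """Repeated random sub-sampling comparison of two Cox model specs.

    For each of ``n_splits`` splits the cohort is divided into a
    ``train_frac`` training and complementary test subset without
    replacement; methylation categorization (when a spec requests it) is
    re-run on the training subset only; both models are fitted on train
    and their CPE computed on the test subjects. Reports per-split CPE
    pairs, means, 1.96 x SD halfwidths across splits, and the paired
    t-test of the per-split differences. Failed splits (non-convergence,
    no admissible cutpoint, too few test subjects) are resampled and
    counted; systematic failure (> ``max_failure_frac`` of n_splits)
    aborts with diagnostics. Splits are uniform by default;
    ``stratify_events=True`` preserves the event fraction in each
    training subset.
    """
    if n_splits < 2:
        raise ValidationError("need >= 2 splits")
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must be in (0, 1)")
    n = len(records)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 2:
        raise ValidationError("cohort too small for the requested split")
    rng = np.random.default_rng(seed)
    max_failures = max(1, int(math.ceil(max_failure_frac * n_splits)))
    pairs = []
    failures: list[str] = []
    events_mask = records[event_col].to_numpy(dtype=float) == 1
    while len(pairs) < n_splits:
        if stratify_events:
            ev_idx = rng.permutation(np.flatnonzero(events_mask))
            ce_idx = rng.permutation(np.flatnonzero(~events_mask))
            k_ev = int(round(train_frac * len(ev_idx)))
            k_ce = n_train - k_ev
            train_idx = np.concatenate([ev_idx[:k_ev], ce_idx[:k_ce]])
            test_idx = np.concatenate([ev_idx[k_ev:], ce_idx[k_ce:]])
        else:
            idx = rng.permutation(n)
            train_idx, test_idx = idx[:n_train], idx[n_train:]
        train = records.iloc[train_idx]
        test = records.iloc[test_idx]
        try:
            split_cpes = []
            for spec in (model_a, model_b):
                tr, te, cov = _split_features(
                    train, test, spec, time_col, event_col, search_kwargs
                )
                if len(te) < 2:
                    raise ValidationError("fewer than 2 complete test records")
                fit = cox_fit(tr, cov, tie_method=tie_method)
                if not fit.converged:
                    from .errors import ConvergenceError

                    raise ConvergenceError(fit.message)
                split_cpes.append(model_cpe(fit, te).estimate)
            pairs.append(split_cpes)
        except Exception as exc:  # noqa: BLE001 - resample failed split
            failures.append(f"{type(exc).__name__}: {exc}")
            if len(failures) > max_failures:
                raise RuntimeError(
                    f"systematic fit failure: {len(failures)} failed splits "
                    f"(> {max_failure_frac:.0%} of {n_splits}); last errors: "
                    + "; ".join(failures[-3:])
                ) from exc
    per_split = pd.DataFrame(pairs, columns=["cpe_a", "cpe_b"])
    a = per_split["cpe_a"].to_numpy()
    b = per_split["cpe_b"].to_numpy()
    return CVComparison(
        per_split=per_split,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        halfwidth_a=float(1.959963984540054 * a.std(ddof=1)),
        halfwidth_b=float(1.959963984540054 * b.std(ddof=1)),
        paired_t=paired_t_test(a, b),
        n_splits=n_splits,
        train_frac=train_frac,
        seed=seed,
        n_failed_splits=len(failures),
    )
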