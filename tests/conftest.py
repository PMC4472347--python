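"""Shared fixtures: simulation configs with known generating truths."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import methrisk as mr
from methrisk.cohort import GeneMarginal

#: marginal with balanced low/moderate/high arms at cuts (15, 50):
#: Beta(0.765, 1.392) has 30% mass below 0.15 and 30% above 0.50.
BALANCED_MARGINAL = GeneMarginal(zero_mass=0.0, alpha=0.765, beta=1.392)

#: "strong effect" for structure-recovery demonstrations
STRONG_LOG_HR = float(np.log(4.0))


def ushape_config(n: int, seed: int, log_hr: float = STRONG_LOG_HR) -> mr.CohortConfig:
    """Tumor cohort with a U-shaped hazard over GSTP1: the low (<15%) and
    high (>50%) methylation arms share an elevated hazard vs moderate."""
    cfg = mr.pca1_config(n, seed=seed)
    marg = dict(cfg.marginal_params)
    marg["GSTP1"] = BALANCED_MARGINAL
    return replace(
        cfg,
        marginal_params=marg,
        group_cuts=(15.0, 50.0),
        log_hazard={"lm_hm": log_hr},
        missing_rates={},
    )


def step_config(n: int, seed: int, change_point: float = 30.0,
                log_hr: float = STRONG_LOG_HR) -> mr.CohortConfig:
    """Tumor cohort whose hazard steps at one GSTP1 change point (the
    'high' group is empty because the second cut sits at 100)."""
    cfg = mr.pca1_config(n, seed=seed)
    marg = dict(cfg.marginal_params)
    marg["GSTP1"] = BALANCED_MARGINAL
    return replace(
        cfg,
        marginal_params=marg,
        group_cuts=(change_point, 100.0),
        log_hazard={"lm_hm": log_hr},
        missing_rates={},
    )


def linear_config(n: int, seed: int, per_percent: float = 0.01) -> mr.CohortConfig:
    """Tumor cohort with a purely log-linear hazard in GSTP1 percent."""
    cfg = ushape_config(n, seed)
    return replace(cfg, log_hazard={"GSTP1": per_percent})


def full_ushape_config(n: int, seed: int, log_hr: float = float(np.log(3.0))):
    """U-shaped methylation effect plus the default clinical effects —
    the cohort used for cross-validated model-comparison checks."""
    cfg = mr.pca1_config(n, seed=seed)
    marg = dict(cfg.marginal_params)
    marg["GSTP1"] = BALANCED_MARGINAL
    lh = dict(cfg.log_hazard)
    if log_hr == 0.0:
        lh.pop("lm_hm")
    else:
        lh["lm_hm"] = log_hr
    return replace(cfg, marginal_params=marg, log_hazard=lh, missing_rates={})


def add_clinical_indicators(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fixed clinical codings used by the multivariate models."""
    df = cohort.copy()
    df["pt_3b_4"] = [
        np.nan if pd.isna(v) else float(v in ("pT3b", "pT4")) for v in df["pt_group"]
    ]
    df["gleason_8_10"] = [
        np.nan if pd.isna(v) else float(v == "8-10") for v in df["gleason_group"]
    ]
    return df


@pytest.fixture(scope="session")
def tumor_cohort() -> pd.DataFrame:
    """Mid-size default tumor cohort shared by read-only tests."""
    return mr.generate_cohort(mr.pca1_config(400, seed=20260101))


@pytest.fixture(scope="session")
def benign_cohort() -> pd.DataFrame:
    return mr.generate_cohort(mr.bph_config(42, seed=20260102))
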