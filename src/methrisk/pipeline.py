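"""End-to-end orchestration: config, stages, report bundle.

The pipeline sequences the analysis stages over one tumor cohort (plus an
optional benign cohort and plate export):

    simulate -> quantify -> diagnose -> functional form -> cutpoints ->
    prognostic models -> KM/log-rank -> CV comparison

Each stage writes delimited text tables (floats at 6 significant digits)
into the output directory, and a machine-readable run log records every
parameter and seed so each report value is traceable to a logged stage
invocation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as ch
from . import diagnostics as dx
from . import qmmsp
from .cpe import ModelSpec, cv_compare
from .errors import ConfigurationError, MethriskError
from .stratify import (
    TrichotomyRule,
    build_table4_models,
    classify_series,
    dichotomize_search,
    functional_form_scan,
    trichotomize_search,
)
from .survival import km_estimate, logrank_test

ALL_STAGES = (
    "simulate",
    "quantify",
    "diagnose",
    "functional_form",
    "cutpoints",
    "models",
    "km",
    "validate",
)

_FLOAT_FMT = "%.6g"

#: every addressable flat config key -> (type, default)
_KNOWN_KEYS = {
    "seed": (int, 0),
    "out_dir": (str, "methrisk_out"),
    "stages": (list, list(ALL_STAGES)),
    "cohort_path": (str, None),
    "benign_path": (str, None),
    "plate_path": (str, None),
    "simulate.cohort_label": (str, "PCa1-like"),
    "simulate.n_patients": (int, 147),
    "simulate.n_benign": (int, 42),
    "quantify.qc_threshold": (float, qmmsp.QC_COPY_THRESHOLD),
    "diagnose.cutoffs": (list, [1.0, 2.0]),
    "stratify.marker": (str, "GSTP1"),
    "stratify.min_group_frac": (float, 0.10),
    "stratify.min_events": (int, 5),
    "stratify.min_n": (int, 30),
    "stratify.min_scan_events": (int, 10),
    "stratify.fixed_cut1": (float, None),
    "stratify.fixed_cut2": (float, None),
    "validate.n_splits": (int, 200),
    "validate.train_frac": (float, 0.80),
    "validate.tie_method": (str, "breslow"),
}


@dataclass
class RunConfig:
    """Validated flat-key run configuration."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        if key not in _KNOWN_KEYS:
            raise KeyError(key)
        return self.values.get(key, _KNOWN_KEYS[key][1])

    @property
    def seed(self) -> int:
        return int(self["seed"])


def _flatten(mapping: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in mapping.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (flat or nested keys); unknown keys rejected."""
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must contain a mapping")
        values.update(_flatten(raw))
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(values) - set(_KNOWN_KEYS))
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")
    for key, val in values.items():
        typ, _ = _KNOWN_KEYS[key]
        if val is None:
            continue
        if typ is list:
            if not isinstance(val, (list, tuple)):
                raise ConfigurationError(f"config key {key!r} must be a list")
        elif typ in (int, float):
            if isinstance(val, bool) or not isinstance(val, (int, float)):
                raise ConfigurationError(f"config key {key!r} must be numeric")
            values[key] = typ(val)
        elif typ is str and not isinstance(val, str):
            raise ConfigurationError(f"config key {key!r} must be a string")
    cfg = RunConfig(values)
    bad = [s for s in cfg["stages"] if s not in ALL_STAGES]
    if bad:
        raise ConfigurationError(f"unknown stages: {bad}; valid: {list(ALL_STAGES)}")
    for key in ("cohort_path", "benign_path", "plate_path"):
        p = cfg[key]
        if p is not None and not Path(p).exists():
            raise ConfigurationError(f"{key} does not exist: {p}")
    return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, na_rep="NA")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run log (also written
    to ``run_log.json``). A stage failure aborts with the stage named;
    tables already written are retained."""
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config["stages"])
    seed = config.seed
    from . import __version__

    log: dict = {
        "version": __version__,
        "seed": seed,
        "stages": {},
        "parameters": dict(config.values),
    }
    current = None
    try:
        tumor = benign = None
        if "simulate" in stages:
            current = "simulate"
            label = config["simulate.cohort_label"]
            maker = {"PCa1-like": ch.pca1_config, "PCa2-like": ch.pca2_config}.get(label)
            if maker is None:
                raise ConfigurationError(
                    f"simulate.cohort_label must be PCa1-like or PCa2-like, got {label!r}"
                )
            tumor = ch.generate_cohort(maker(config["simulate.n_patients"], seed=seed))
            benign = ch.generate_cohort(ch.bph_config(config["simulate.n_benign"], seed=seed + 1))
            ch.write_cohort(tumor, out / "cohort.csv")
            ch.write_cohort(benign, out / "benign.csv")
            log["stages"]["simulate"] = {
                "cohort_label": label,
                "n_patients": len(tumor),
                "n_benign": len(benign),
                "seed": seed,
            }
        if tumor is None and config["cohort_path"]:
            tumor = ch.read_cohort(config["cohort_path"])
        if benign is None and config["benign_path"]:
            benign = ch.read_cohort(config["benign_path"])

        if "quantify" in stages and config["plate_path"]:
            current = "quantify"
            wells = qmmsp.read_plate(config["plate_path"])
            calls = qmmsp.quantify_plate(wells, config["quantify.qc_threshold"])
            table = qmmsp.calls_to_frame(calls)
            _write(table, out / "methylation_calls.csv")
            log["stages"]["quantify"] = {
                "n_wells": len(calls),
                "n_rejected": int((~table["qc_pass"]).sum()),
                "qc_threshold": config["quantify.qc_threshold"],
            }

        if any(s in stages for s in ("diagnose", "functional_form", "cutpoints",
                                     "models", "km", "validate")) and tumor is None:
            raise ConfigurationError(
                "no tumor cohort available: enable 'simulate' or set cohort_path"
            )

        if "diagnose" in stages:
            current = "diagnose"
            if benign is None:
                raise ConfigurationError(
                    "diagnose stage needs a benign cohort (simulate or benign_path)"
                )
            rep = dx.diagnostics_report(
                benign, tumor, ch.GENES, cutoffs=config["diagnose.cutoffs"]
            )
            _write(rep, out / "diagnostics.csv")
            log["stages"]["diagnose"] = {"cutoffs": list(config["diagnose.cutoffs"])}

        marker = config["stratify.marker"]
        if "functional_form" in stages:
            current = "functional_form"
            ff = functional_form_scan(
                tumor,
                marker,
                min_n=config["stratify.min_n"],
                min_events=config["stratify.min_scan_events"],
            )
            _write(
                pd.DataFrame(
                    [
                        {
                            "marker": marker,
                            "verdict": ff.verdict,
                            "quad_vs_linear_stat": ff.quadratic_vs_linear.statistic,
                            "quad_vs_linear_p": ff.quadratic_vs_linear.p_value,
                            "spline_vs_linear_stat": ff.spline_vs_linear.statistic,
                            "spline_vs_linear_p": ff.spline_vs_linear.p_value,
                            "n": ff.n,
                            "n_events": ff.n_events,
                        }
                    ]
                ),
                out / "functional_form.csv",
            )
            log["stages"]["functional_form"] = {"marker": marker, "verdict": ff.verdict}

        rule = None
        if config["stratify.fixed_cut1"] is not None and config["stratify.fixed_cut2"] is not None:
            rule = TrichotomyRule(config["stratify.fixed_cut1"], config["stratify.fixed_cut2"])
        if "cutpoints" in stages:
            current = "cutpoints"
            kw = dict(
                min_group_frac=config["stratify.min_group_frac"],
                min_events=config["stratify.min_events"],
            )
            if rule is None:
                first = dichotomize_search(tumor, marker, **kw)
                second = trichotomize_search(tumor, marker, first.cut1, **kw)
                rule = TrichotomyRule(second.cut1, second.cut2)
                profile = pd.concat(
                    [
                        first.profile.assign(stage="dichotomize"),
                        second.profile.assign(stage="trichotomize"),
                    ]
                )
                _write(profile, out / "cutpoint_profile.csv")
            _write(
                pd.DataFrame([{"marker": marker, "cut1": rule.cut1, "cut2": rule.cut2}]),
                out / "cutpoints.csv",
            )
            log["stages"]["cutpoints"] = {
                "marker": marker,
                "cut1": rule.cut1,
                "cut2": rule.cut2,
                "note": (
                    "cutpoints selected by maximum Cox partial log-likelihood over "
                    "all admissible candidates; no multiplicity correction applied "
                    "(maximally selected statistics are optimistically biased)"
                ),
            }
        if rule is None:
            rule = TrichotomyRule(15.0, 50.0)

        if "models" in stages:
            current = "models"
            table, mlog = build_table4_models(tumor, rule, marker=marker)
            _write(table, out / "prognostic_models.csv")
            log["stages"]["models"] = {"rule": (rule.cut1, rule.cut2), **mlog}

        if "km" in stages:
            current = "km"
            groups = classify_series(tumor[marker], rule)
            frames = []
            for label in rule.labels:
                sub = tumor[groups == label]
                if len(sub) == 0:
                    continue
                km = km_estimate(sub, time_col="followup_years", event_col="cf_event")
                frames.append(km.assign(group=label))
            _write(pd.concat(frames), out / "km_curves.csv")
            present = [tumor[groups == lab] for lab in rule.labels
                       if (groups == lab).sum() > 0]
            lr3 = logrank_test(present, time_col="followup_years", event_col="cf_event")
            mm = rule.labels[1]
            lr2 = logrank_test(
                [tumor[groups == mm], tumor[(groups != mm) & groups.notna()]],
                time_col="followup_years",
                event_col="cf_event",
            )
            _write(
                pd.DataFrame(
                    [
                        {"comparison": "LM vs MM vs HM", "chi_square": lr3.statistic,
                         "df": lr3.df, "p_value": lr3.p_value},
                        {"comparison": "MM vs LM+HM", "chi_square": lr2.statistic,
                         "df": lr2.df, "p_value": lr2.p_value},
                    ]
                ),
                out / "logrank.csv",
            )
            log["stages"]["km"] = {"groups": list(rule.labels)}

        if "validate" in stages:
            current = "validate"
            df = tumor.copy()
            df["pt_3b_4"] = pd.array(
                [pd.NA if pd.isna(v) else float(v in ("pT3b", "pT4"))
                 for v in df["pt_group"]],
                dtype="Float64",
            ).astype(float)
            df["gleason_8_10"] = pd.array(
                [pd.NA if pd.isna(v) else float(v == "8-10")
                 for v in df["gleason_group"]],
                dtype="Float64",
            ).astype(float)
            clinical = ("pt_3b_4", "gleason_8_10", "psa")
            comp = cv_compare(
                df,
                ModelSpec("clinical", clinical),
                ModelSpec("clinical+methylation", clinical, methylation_marker=marker),
                n_splits=config["validate.n_splits"],
                train_frac=config["validate.train_frac"],
                seed=seed,
                tie_method=config["validate.tie_method"],
                min_group_frac=config["stratify.min_group_frac"],
                min_events=config["stratify.min_events"],
            )
            _write(comp.per_split, out / "cpe_per_split.csv")
            _write(
                pd.DataFrame(
                    [
                        {"model": "three clinical variables", "cpe": comp.mean_a,
                         "halfwidth": comp.halfwidth_a},
                        {"model": f"three clinical variables + {marker}",
                         "cpe": comp.mean_b, "halfwidth": comp.halfwidth_b},
                    ]
                ),
                out / "cpe_comparison.csv",
            )
            log["stages"]["validate"] = {
                "n_splits": comp.n_splits,
                "train_frac": comp.train_frac,
                "n_failed_splits": comp.n_failed_splits,
                "cpe_clinical": comp.mean_a,
                "cpe_with_marker": comp.mean_b,
                "paired_t_p": comp.paired_t.p_value,
                "halfwidth_note": "halfwidth = 1.96 x SD of per-split test-set CPE",
            }
    except MethriskError as exc:
        log["failed_stage"] = current
        log["error"] = str(exc)
        with open(out / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log
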