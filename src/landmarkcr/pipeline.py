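"""Experiment configuration and orchestration.

An experiment is fully described by a plain-text (YAML/JSON) config: either
generator settings or paths to episode/trajectory CSVs, the prediction
window and landmark grid, the model roster, feature/imputation/RMTL
settings, the number of train-test repetitions and a master seed.  Running
it executes simulate -> landmark -> impute -> fit -> evaluate and writes the
tidy metric records, the summary, the resolved config and a log; two runs
with the same config produce identical outputs (modulo timestamps in the
log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, impute, landmark, rmtl, simulate

log = logging.getLogger("landmarkcr")

_DEFAULTS = {
    "n_admissions": 2000,
    "preset": "default",          # default (8 predictors) | table1 (21)
    "episodes_csv": None,         # alternatively: load data from CSVs
    "trajectories_csv": None,
    "w": 7,
    "landmark_grid": None,        # default 0..30
    "roster": list(evaluation.ALL_MODELS),
    "n_repetitions": 100,
    "train_fraction": 2 / 3,
    "interaction_mode": "per-split",
    "interaction_candidates": ["icu"],
    "interaction_alpha": 0.05,
    "tune_rmtl": True,
    "rmtl_lambda_grid": None,     # default log-spaced 1e-3..1e2
    "apply_missingness": True,
    "master_seed": 0,
    "out_dir": "results",
}


class ConfigurationError(ValueError):
    pass


def validate_config(source) -> dict:
    """Resolve a config mapping / YAML path to a full settings dict.

    Unknown keys are rejected; every omitted key gets its documented default
    (prediction window 7 days, landmark grid 0..30, 2:1 split, 100
    repetitions).
    """
    if isinstance(source, (str, pathlib.Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    errors = [f"unknown config key: {k}" for k in raw if k not in _DEFAULTS]
    cfg = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}
    if cfg["landmark_grid"] is None:
        cfg["landmark_grid"] = list(range(31))
    if cfg["w"] is None or cfg["w"] <= 0:
        errors.append(f"w: must be a positive number of days (got {cfg['w']})")
    if cfg["n_repetitions"] <= 0:
        errors.append("n_repetitions: must be positive")
    if not 0 < cfg["train_fraction"] < 1:
        errors.append("train_fraction: must be in (0,1)")
    unknown_models = [m for m in cfg["roster"]
                      if m not in evaluation.ALL_MODELS]
    if unknown_models:
        errors.append(f"roster: unknown models {unknown_models}")
    if cfg["preset"] not in ("default", "table1"):
        errors.append(f"preset: unknown preset {cfg['preset']!r}")
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


def run_experiment(config, out_dir=None) -> evaluation.PerformanceReport:
    """Execute a full experiment; returns the PerformanceReport and writes
    report.csv, summary.csv, resolved_config.yaml and failures.json."""
    cfg = validate_config(config)
    out = pathlib.Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    if cfg["episodes_csv"]:
        log.info("stage simulate: skipped (loading CSVs)")
        episodes = pd.read_csv(cfg["episodes_csv"])
        trajectories = pd.read_csv(cfg["trajectories_csv"])
        sim_cfg = None
    else:
        log.info("stage simulate: generating %d admissions", cfg["n_admissions"])
        make = simulate.default_config if cfg["preset"] == "default" \
            else simulate.table1_config
        sim_cfg = make(n_admissions=cfg["n_admissions"],
                       seed=cfg["master_seed"])
        episodes, trajectories, _ = simulate.generate_cohort(sim_cfg)
        if cfg["apply_missingness"]:
            trajectories = simulate.apply_missingness(trajectories, sim_cfg)

    pred_cfg = landmark.PredictionConfig(
        w=cfg["w"], landmark_grid=tuple(cfg["landmark_grid"]))
    if sim_cfg is not None:
        cov_spec = features.default_covariate_spec(sim_cfg.predictors)
        lookback = {p.name: p.lookback for p in sim_cfg.predictors}
        schema = impute.schema_from_predictors(sim_cfg.predictors)
    else:
        covs = [c for c in trajectories.columns
                if c not in ("episode_id", "day")]
        cov_spec = {c: "identity" for c in covs}
        lookback = {}
        schema = [impute.ColumnSchema(c, "continuous") for c in covs
                  if trajectories[c].isna().any()]

    rmtl_cfg = rmtl.RMTLConfig()
    if cfg["rmtl_lambda_grid"]:
        rmtl_cfg = dataclasses.replace(
            rmtl_cfg, lambda_grid=tuple(cfg["rmtl_lambda_grid"]))
    hcfg = evaluation.HarnessConfig(
        prediction=pred_cfg,
        covariate_spec=cov_spec,
        lookback=lookback,
        imputer_schema=schema if any(trajectories[c].isna().any()
                                     for c in cov_spec) else [],
        n_repetitions=cfg["n_repetitions"],
        train_fraction=cfg["train_fraction"],
        interaction_mode=(cfg["interaction_mode"]
                          if cfg["interaction_mode"] != "per-split"
                          else "per-split"),
        interaction_candidates=tuple(cfg["interaction_candidates"]),
        interaction_alpha=cfg["interaction_alpha"],
        rmtl_config=rmtl_cfg,
        tune_rmtl=cfg["tune_rmtl"],
        master_seed=cfg["master_seed"],
    )

    dynamic = [m for m in cfg["roster"] if m in evaluation.DYNAMIC_MODELS]
    if not dynamic:
        log.info("stage landmark-stacking: skipped (static-only roster)")
    log.info("stage evaluate: roster=%s repetitions=%d", cfg["roster"],
             cfg["n_repetitions"])
    report = evaluation.repeated_split_evaluate(
        episodes, trajectories, cfg["roster"], hcfg)

    report.to_csv(out / "report.csv")
    report.summary().to_csv(out / "summary.csv", index=False)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg))
    (out / "failures.json").write_text(json.dumps(
        [list(map(str, f)) for f in report.failures], indent=2))
    log.info("wrote report to %s", out)
    return report
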