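"""Iterative random-forest imputation for prediction settings.

The imputer is learned exclusively on training records and then replayed,
frozen, on any table with the same schema (the bedside situation: a new
patient's missing labs must be filled using models learned during
development).  Procedure: initial mean/mode fill, then a fixed number of
iterations in which each variable with missing training values is regressed
on all other covariates with a random forest and its missing entries are
re-predicted.  Variables are visited in order of increasing training
missingness.  Outcome columns are never predictors nor targets.

Low-missingness categorical variables can be flagged mode-only (filled with
the training mode, no forest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

N_ITERATIONS = 5  # fixed; no early stopping
N_TREES = 100


@dataclass
class ColumnSchema:
    """role: continuous | categorical | mode_only"""

    name: str
    role: str


class ImputerModel:
    """Frozen imputation model (see module docstring)."""

    def __init__(self, schema, fills, visit_order, forests, seed,
                 feature_columns=None):
        self.schema = schema            # list[ColumnSchema], covariates only
        self.fills = fills              # name -> initial fill value
        self.visit_order = visit_order  # names with forests, by missingness
        self.forests = forests          # (iteration, name) -> fitted forest
        self.seed = seed
        # numeric columns usable as forest features (non-numeric mode-only
        # columns are filled but never fed to a forest)
        self.feature_columns = feature_columns if feature_columns is not None \
            else [c.name for c in schema]

    @property
    def columns(self):
        return [c.name for c in self.schema]

    def _feature_frame(self, table, target):
        cols = [c for c in self.feature_columns if c != target]
        return table[cols].to_numpy(dtype=float)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        """Complete a table.  Observed cells are never altered; the fill of a
        missing cell is deterministic given the frozen forests."""
        out = table.copy()
        na = {c: out[c].isna().to_numpy() for c in self.columns}
        for c in self.columns:
            if na[c].any():
                out[c] = out[c].fillna(self.fills[c])
        for it in range(N_ITERATIONS):
            for name in self.visit_order:
                mask = na[name]
                if not mask.any():
                    continue
                forest = self.forests[(it, name)]
                Xmis = self._feature_frame(out.loc[mask], name)
                out.loc[mask, name] = forest.predict(Xmis)
        return out

    # convenience alias matching the op name
    __call__ = transform


def fit_imputer(train_table: pd.DataFrame, schema, seed=0) -> ImputerModel:
    """Learn an ImputerModel from training records.

    schema: list of ColumnSchema for the covariate columns (outcome and id
    columns are simply not listed and therefore never touched).
    """
    schema = list(schema)
    names = [c.name for c in schema]
    numeric = [c.name for c in schema
               if pd.api.types.is_numeric_dtype(train_table[c.name])]
    for c in schema:
        if c.name not in numeric and c.role != "mode_only":
            raise ValueError(
                f"non-numeric column {c.name} must be flagged mode_only")
    miss = {}
    fills = {}
    for c in schema:
        col = train_table[c.name]
        if col.isna().all():
            raise ValueError(f"column {c.name} is entirely missing")
        miss[c.name] = float(col.isna().mean())
        if c.role == "continuous":
            fills[c.name] = float(col.mean())
        else:  # categorical / mode_only
            fills[c.name] = col.mode(dropna=True).iloc[0]
    forest_cols = [c for c in schema
                   if c.role != "mode_only" and miss[c.name] > 0]
    visit_order = [c.name for c in
                   sorted(forest_cols, key=lambda c: miss[c.name])]

    # iteratively refit forests on the currently completed training data,
    # storing every (iteration, variable) model for exact replay
    completed = train_table[names].copy()
    na = {n: completed[n].isna().to_numpy() for n in names}
    for c in schema:
        col = completed[c.name]
        completed[c.name] = col.fillna(fills[c.name])
    roles = {c.name: c.role for c in schema}
    forests = {}
    for it in range(N_ITERATIONS):
        for j, name in enumerate(visit_order):
            rf_seed = (seed * 1000003 + it * 101 + j) % (2**31)
            cls = RandomForestClassifier if roles[name] == "categorical" \
                else RandomForestRegressor
            forest = cls(n_estimators=N_TREES, random_state=rf_seed, n_jobs=1)
            obs = ~na[name]
            feat_cols = [c for c in numeric if c != name]
            forest.fit(completed.loc[obs, feat_cols].to_numpy(dtype=float),
                       completed.loc[obs, name].to_numpy())
            mask = na[name]
            if mask.any():
                completed.loc[mask, name] = forest.predict(
                    completed.loc[mask, feat_cols].to_numpy(dtype=float))
            forests[(it, name)] = forest
    return ImputerModel(schema, fills, visit_order, forests, seed,
                        feature_columns=numeric)


def transform_impute(imputer: ImputerModel, table: pd.DataFrame) -> pd.DataFrame:
    return imputer.transform(table)


def schema_from_predictors(predictors, mode_only=("admission_from_home",)):
    """ColumnSchema list from generator predictor specs: continuous kinds get
    forests; binary flags are categorical; listed low-missingness variables
    are mode-only."""
    out = []
    for p in predictors:
        if p.name in mode_only:
            out.append(ColumnSchema(p.name, "mode_only"))
        elif p.kind in ("gaussian", "positive-skewed"):
            out.append(ColumnSchema(p.name, "continuous"))
        else:
            out.append(ColumnSchema(p.name, "categorical"))
    return out
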