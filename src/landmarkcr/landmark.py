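"""Landmark dataset construction for dynamic risk prediction.

At each landmark day s the episodes still at risk (T > s, strict) form a
dataset with their covariate values at s and follow-up administratively
censored at s + w, where w is the prediction window.  The per-landmark
datasets can be stacked into one super dataset (with s and s^2 columns) on
which a single "supermodel" is fitted, or transformed into counting-process
records with inverse-probability-of-censoring weights for the subdistribution
hazard (Fine-Gray) supermodel.

All model time scales are days since catheter onset; the landmark day enters
models only through the s, s^2 columns and their interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATUS_CATEGORY = {0: "none", 1: "clabsi", 2: "death", 3: "discharge"}

#: columns of a landmark record table that are not covariates
ID_COLS = ["episode_id", "admission_id", "s", "T_lm", "status", "y7", "category"]


@dataclass
class PredictionConfig:
    """Prediction window and landmark grid."""

    w: int = 7
    landmark_grid: tuple = tuple(range(31))

    def __post_init__(self):
        self.landmark_grid = tuple(int(s) for s in self.landmark_grid)
        if self.w <= 0:
            raise ValueError("w must be positive")
        g = np.asarray(self.landmark_grid)
        if len(g) == 0 or np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("landmark_grid must be strictly increasing and >= 0")


def at_risk(episodes: pd.DataFrame, s: float) -> pd.DataFrame:
    """Episodes still event-free at landmark s (T > s, strict boundary: an
    event on day s belongs to the window of landmark s-1)."""
    if s < 0:
        raise ValueError("landmark must be >= 0")
    return episodes[episodes["T"] > s]


def _lookback_values(trajectories, covariates, lookback, s):
    """Covariate vector Z(s) per episode: current-day value, except flags
    with a 7-day charting window which are a rolling OR over days s-6..s."""
    window = trajectories[(trajectories["day"] >= s - 6) & (trajectories["day"] <= s)]
    today = window[window["day"] == s].set_index("episode_id")
    out = today[covariates].copy()
    for name in covariates:
        if lookback.get(name) == "7day-any":
            rolled = window.groupby("episode_id")[name].max()
            out[name] = rolled.reindex(out.index)
    return out


def build_landmark_dataset(episodes, trajectories, s, config: PredictionConfig,
                           covariates=None, lookback=None) -> pd.DataFrame:
    """One row per episode at risk at s, with administrative censoring at
    s + w.

    Columns: episode_id, admission_id, s, covariates Z(s), T_lm = min(T, s+w),
    status in {0 censored, 1 clabsi, 2 death, 3 discharge}, y7 = 1 iff the
    infection occurs within the window, category label.
    """
    risk = at_risk(episodes, s)
    if covariates is None:
        covariates = [c for c in trajectories.columns
                      if c not in ("episode_id", "day")]
    lookback = lookback or {}
    if risk.empty:
        warnings.warn(f"empty risk set at landmark {s}")
        cols = ID_COLS + list(covariates)
        return pd.DataFrame(columns=cols)
    Z = _lookback_values(trajectories, list(covariates), lookback, s)
    out = risk[["episode_id", "admission_id"]].copy()
    out["s"] = s
    out = out.join(Z, on="episode_id")
    T = risk["T"].to_numpy()
    D = risk["D"].to_numpy()
    within = T <= s + config.w
    out["T_lm"] = np.minimum(T, s + config.w)
    out["status"] = np.where(within, D, 0)
    out["y7"] = (within & (D == 1)).astype(int)
    out["category"] = out["status"].map(STATUS_CATEGORY)
    return out.reset_index(drop=True)


def stack_landmarks(tables, config: PredictionConfig) -> pd.DataFrame:
    """Concatenate per-landmark tables and add s, s_sq columns."""
    tables = [t for t in tables if len(t)]
    if not tables:
        raise ValueError("no non-empty landmark tables to stack")
    cols = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != cols:
            raise ValueError("landmark tables have mismatching schemas")
    stacked = pd.concat(tables, ignore_index=True)
    stacked["s_sq"] = stacked["s"].astype(float) ** 2
    return stacked


def build_stacked_dataset(episodes, trajectories, config: PredictionConfig,
                          covariates=None, lookback=None) -> pd.DataFrame:
    """Landmark datasets over the whole grid, stacked."""
    tables = [
        build_landmark_dataset(episodes, trajectories, s, config,
                               covariates=covariates, lookback=lookback)
        for s in config.landmark_grid
    ]
    return stack_landmarks(tables, config)


def finegray_transform(landmark_table: pd.DataFrame, config: PredictionConfig,
                       covariates=None) -> pd.DataFrame:
    """Counting-process records for the subdistribution (Fine-Gray) hazard of
    the infection cause at one landmark.

    - cause-1 events: one record (s, T, event=1, weight 1)
    - administratively censored: one record (s, s+w, 0, 1)
    - competing events at T_c: the episode stays in the subdistribution risk
      set after T_c; its follow-up (T_c, s+w] is split at the censoring
      distribution's jump times with weights G(t-)/G(T_c-).  Under purely
      administrative censoring G never drops before s+w, so each competing
      episode contributes the single record (s, s+w, 0, 1).
    """
    if landmark_table.empty:
        return landmark_table.copy()
    if covariates is None:
        covariates = [c for c in landmark_table.columns if c not in ID_COLS
                      and c != "s_sq"]
    s = float(landmark_table["s"].iloc[0])
    horizon = s + config.w
    T_lm = landmark_table["T_lm"].to_numpy(dtype=float)
    status = landmark_table["status"].to_numpy()
    base_cols = ["episode_id", "admission_id", "s"] + list(covariates)
    base = landmark_table[base_cols].reset_index(drop=True)
    cens_jumps = np.unique(T_lm[(status == 0) & (T_lm < horizon)])
    if len(cens_jumps) == 0:
        # purely administrative censoring: all weights 1, one record per row
        out = base.copy()
        out["start"] = s
        out["stop"] = np.where(status == 1, T_lm, horizon)
        out["event"] = (status == 1).astype(int)
        out["weight"] = 1.0
        return out
    rows = []
    for i in range(len(base)):
        st = status[i]
        t = T_lm[i]
        if st == 1:
            rows.append((i, s, t, 1, 1.0))
        elif st == 0:
            rows.append((i, s, t, 0, 1.0))
        else:
            # competing event: extend in the subdistribution risk set
            jumps = cens_jumps[(cens_jumps > t) & (cens_jumps < horizon)]
            cuts = np.concatenate([[t], jumps, [horizon]])
            G_Tc = _G_before(T_lm, status, t + 1e-9)
            for a, b in zip(cuts[:-1], cuts[1:]):
                wgt = _G_before(T_lm, status, b) / max(G_Tc, 1e-300)
                rows.append((i, a, b, 0, min(wgt, 1.0)))
    rec = pd.DataFrame(rows, columns=["_ix", "start", "stop", "event", "weight"])
    out = base.loc[rec["_ix"]].reset_index(drop=True)
    out[["start", "stop", "event", "weight"]] = \
        rec[["start", "stop", "event", "weight"]].to_numpy()
    out["event"] = out["event"].astype(int)
    return out


def _G_before(T_lm, status, t):
    """Kaplan-Meier survival of the censoring distribution just before t.
    Under purely administrative censoring all censoring mass sits at s+w so
    this is identically 1 for t <= s+w."""
    g = 1.0
    at = len(T_lm)
    for tt in np.unique(T_lm):
        if tt >= t:
            break
        d_cens = np.sum((T_lm == tt) & (status == 0))
        n_here = np.sum(T_lm == tt)
        if at > 0:
            g *= 1.0 - d_cens / at
        at -= n_here
    return g


def stack_finegray(landmark_tables, config: PredictionConfig, covariates=None):
    """Counting-process transform per landmark, then stacked with s, s_sq."""
    parts = [finegray_transform(t, config, covariates=covariates)
             for t in landmark_tables if len(t)]
    if not parts:
        raise ValueError("no non-empty landmark tables")
    stacked = pd.concat(parts, ignore_index=True)
    stacked["s_sq"] = stacked["s"].astype(float) ** 2
    return stacked
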