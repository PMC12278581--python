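"""Regularized multi-task learning: one logistic task per landmark day,
estimated jointly with a temporal-smoothness penalty.

The objective is

    sum_t  L_t(w_t, b_t) / n_t  +  lambda_task * sum_t ||w_t - w_{t+1}||^2
                                +  lambda_ridge * sum_t ||w_t||^2

where L_t is the logistic negative log-likelihood of task (landmark) t.  The
cross-task term is the quadratic form of the path-graph Laplacian over the
ordered landmarks, which shrinks the coefficients of adjacent landmarks
toward each other; intercepts are never penalized.  Each task standardizes
its covariates with its own training mean/sd, and applies those same
statistics to any test records.

Optimizer: Nesterov-accelerated gradient descent with backtracking line
search and function-value restarts, which keeps the objective monotone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._cox import FitError


@dataclass
class RMTLConfig:
    lambda_task: float = 1.0
    lambda_ridge: float = 0.0
    cv_folds: int = 5
    lambda_grid: tuple = tuple(np.logspace(-3, 2, 9))
    tol: float = 1e-6
    max_iter: int = 5000
    seed: int = 0

    def validate(self):
        if self.lambda_task < 0 or self.lambda_ridge < 0:
            raise ValueError("regularization weights must be >= 0")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be non-empty")


@dataclass
class TaskData:
    """One landmark's design/outcome set (pre-standardization)."""

    s: int
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # admission ids, for grouped CV


class RMTLFit:
    def __init__(self, landmarks, W, b, stats, lambda_task, objective_trace,
                 dropped):
        self.landmarks = list(landmarks)   # fitted task order
        self.W = W                         # (T, p) coefficients
        self.b = b                         # (T,) intercepts
        self.stats = stats                 # s -> (mean vector, sd vector)
        self.lambda_task = lambda_task
        self.objective_trace = objective_trace
        self.dropped = dropped             # landmarks dropped (one class)

    def predict(self, s, X):
        """Logistic probabilities for records at landmark s (raw covariate
        scale; task-s training statistics are applied here)."""
        if s not in self.landmarks:
            warnings.warn(f"landmark {s} has no fitted task; returning NaN")
            return np.full(len(X), np.nan)
        t = self.landmarks.index(s)
        m, sd = self.stats[s]
        Z = (np.asarray(X, dtype=float) - m) / sd
        return expit(np.clip(Z @ self.W[t] + self.b[t], -500, 500))

    def to_json(self):
        import json
        return json.dumps({
            "landmarks": self.landmarks,
            "W": self.W.tolist(),
            "intercepts": self.b.tolist(),
            "stats": {str(s): [m.tolist(), sd.tolist()]
                      for s, (m, sd) in self.stats.items()},
            "lambda_task": self.lambda_task,
            "dropped": self.dropped,
        }, indent=2)

    def summary(self):
        import pandas as pd
        df = pd.DataFrame(self.W, index=self.landmarks)
        df["intercept"] = self.b
        return (f"RMTL fit | tasks={len(self.landmarks)} "
                f"lambda_task={self.lambda_task:g} "
                f"final objective={self.objective_trace[-1]:.6f}\n"
                + df.to_string(float_format=lambda v: f"{v: .4f}"))


def _standardize_tasks(tasks):
    stats, Z = {}, []
    for t in tasks:
        m = t.X.mean(axis=0)
        sd = t.X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        stats[t.s] = (m, sd)
        Z.append((t.X - m) / sd)
    return stats, Z


def _objective(W, b, Z, y, lam_task, lam_ridge):
    val = 0.0
    for t in range(len(Z)):
        eta = Z[t] @ W[t] + b[t]
        val += float(np.mean(np.logaddexp(0.0, eta) - y[t] * eta))
    if len(Z) > 1:
        diffs = W[1:] - W[:-1]
        val += lam_task * float(np.sum(diffs**2))
    val += lam_ridge * float(np.sum(W**2))
    return val


def _gradient(W, b, Z, y, lam_task, lam_ridge):
    T, p = W.shape
    gW = np.zeros_like(W)
    gb = np.zeros_like(b)
    for t in range(T):
        r = expit(np.clip(Z[t] @ W[t] + b[t], -500, 500)) - y[t]
        n = len(y[t])
        gW[t] = Z[t].T @ r / n
        gb[t] = float(r.sum() / n)
    if T > 1:
        lap = np.zeros_like(W)
        lap[:-1] += W[:-1] - W[1:]
        lap[1:] += W[1:] - W[:-1]
        gW += 2.0 * lam_task * lap
    gW += 2.0 * lam_ridge * W
    return gW, gb


def fit_rmtl(task_datasets, config: RMTLConfig) -> RMTLFit:
    """Joint fit over per-landmark tasks.

    task_datasets: list of TaskData ordered by landmark.  Tasks with a single
    outcome class are dropped with a warning (their landmark yields missing
    predictions).  Deterministic given the config.
    """
    config.validate()
    tasks = []
    dropped = []
    for t in task_datasets:
        if len(np.unique(t.y)) < 2:
            warnings.warn(f"task at landmark {t.s} has one outcome class; dropped")
            dropped.append(t.s)
        else:
            tasks.append(t)
    if not tasks:
        raise FitError("no task has both outcome classes")
    stats, Z = _standardize_tasks(tasks)
    y = [np.asarray(t.y, dtype=float) for t in tasks]
    T, p = len(tasks), tasks[0].X.shape[1]
    W = np.zeros((T, p))
    b = np.zeros(T)
    lam, ridge = config.lambda_task, config.lambda_ridge

    obj = _objective(W, b, Z, y, lam, ridge)
    trace = [obj]
    step = 1.0
    # Nesterov acceleration with backtracking and monotone restarts
    Wm, bm = W.copy(), b.copy()  # momentum carriers
    tk = 1.0
    for it in range(config.max_iter):
        gW, gb = _gradient(Wm, bm, Z, y, lam, ridge)
        obj_ref = _objective(Wm, bm, Z, y, lam, ridge)
        gnorm2 = float(np.sum(gW**2) + np.sum(gb**2))
        # backtracking from the extrapolated point (sufficient decrease)
        while True:
            W_new = Wm - step * gW
            b_new = bm - step * gb
            obj_new = _objective(W_new, b_new, Z, y, lam, ridge)
            if obj_new <= obj_ref - 0.5 * step * gnorm2 + 1e-15:
                break
            step *= 0.5
            if step < 1e-14:
                raise FitError("backtracking line search collapsed")
        if obj_new > obj:  # restart momentum, enforce monotonicity
            Wm, bm, tk = W.copy(), b.copy(), 1.0
            continue
        tk_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk**2))
        Wm = W_new + ((tk - 1.0) / tk_new) * (W_new - W)
        bm = b_new + ((tk - 1.0) / tk_new) * (b_new - b)
        tk = tk_new
        W, b, obj = W_new, b_new, obj_new
        trace.append(obj)
        step *= 1.5  # allow the step to grow back
        # gradient tolerance, scaled by the penalty strength so that very
        # strong coupling (whose gradient components are O(lambda * diff))
        # converges once the coefficient differences are numerically fused
        gtol = config.tol * max(1.0, lam, ridge)
        gW_cur, gb_cur = _gradient(W, b, Z, y, lam, ridge)
        if max(np.max(np.abs(gW_cur)), np.max(np.abs(gb_cur))) < gtol:
            break
    else:
        raise FitError(
            f"RMTL did not converge in {config.max_iter} iterations"
        )
    return RMTLFit([t.s for t in tasks], W, b, stats, lam, trace, dropped)


def tune_lambda(task_datasets, config: RMTLConfig):
    """Grouped 5-fold cross-validation over the lambda grid.

    Folds are formed over admissions pooled across tasks, so all landmarks of
    one admission share a fold.  Selects the grid value minimizing the mean
    held-out deviance (ties broken toward the larger, smoother value).
    """
    config.validate()
    grid = list(config.lambda_grid)
    if len(grid) == 1:
        return grid[0]
    rng = np.random.default_rng(config.seed)
    all_groups = np.unique(np.concatenate([t.groups for t in task_datasets]))
    perm = rng.permutation(all_groups)
    fold_of = {g: i % config.cv_folds for i, g in enumerate(perm)}
    scores = []
    for lam in grid:
        devs = []
        for fold in range(config.cv_folds):
            train_tasks, heldout = [], []
            for t in task_datasets:
                te = np.array([fold_of[g] == fold for g in t.groups])
                tr = ~te
                if len(np.unique(t.y[tr])) < 2 or te.sum() == 0:
                    continue
                train_tasks.append(
                    TaskData(t.s, t.X[tr], t.y[tr], t.groups[tr]))
                heldout.append((t.s, t.X[te], t.y[te]))
            if not train_tasks:
                continue
            cfg = RMTLConfig(lambda_task=lam, lambda_ridge=config.lambda_ridge,
                             tol=config.tol, max_iter=config.max_iter,
                             seed=config.seed)
            try:
                fit = fit_rmtl(train_tasks, cfg)
            except FitError:
                continue
            dev = 0.0
            n_tot = 0
            for s, Xte, yte in heldout:
                if s not in fit.landmarks:
                    continue
                p = np.clip(fit.predict(s, Xte), 1e-12, 1 - 1e-12)
                dev += -2.0 * float(np.sum(yte * np.log(p)
                                           + (1 - yte) * np.log(1 - p)))
                n_tot += len(yte)
            if n_tot:
                devs.append(dev / n_tot)
        if not devs:
            raise FitError("all cross-validation folds degenerate")
        scores.append(float(np.mean(devs)))
    scores = np.asarray(scores)
    best = np.flatnonzero(scores <= scores.min() + 1e-12)[-1]
    return grid[best]
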