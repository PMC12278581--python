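"""Shared simulation-study helpers used by unit and acceptance tests."""

import numpy as np
import pandas as pd

import landmarkcr as L
from landmarkcr.simulate import PredictorSpec, SimulationConfig, generate_cohort


def recovery_config(seed):
    """Cohort for the coefficient-recovery study: moderate, balanced
    cause-specific rates so each cause accrues a few thousand events at
    ~10,000 episodes."""
    preds = [
        PredictorSpec("flag_a", "binary-timevarying", p_init=0.5,
                      p_on=0.03, p_off=0.03),
        PredictorSpec("flag_b", "binary-static", p_init=0.5),
        PredictorSpec("vital", "gaussian", mean=0.0, sd=1.0, ar1=0.8),
        PredictorSpec("lab", "positive-skewed", mean=1.5, sd=0.7, ar1=0.85),
    ]
    betas = np.array([
        [0.5, -0.4, 0.3, 0.35],
        [-0.3, 0.5, -0.25, 0.2],
        [0.25, -0.3, 0.2, -0.4],
    ])
    return SimulationConfig(
        n_admissions=9100, p_multi_episode=0.1, max_follow_up=60,
        predictors=preds, true_betas=betas,
        baseline_hazards=(0.03, 0.03, 0.05), seed=seed,
    )


def fit_cause_specific_daily(cfg, episodes, traj):
    """Cause-specific Cox fits on per-day counting-process records (the
    hazard of day d+1 acts on Z(d)); returns a 3 x p estimate matrix."""
    rec = traj.merge(episodes[["episode_id", "T", "D"]], on="episode_id")
    rec = rec[rec["day"] < rec["T"]].reset_index(drop=True)
    X = np.column_stack([
        np.log1p(rec[p.name]) if p.kind == "positive-skewed" else rec[p.name]
        for p in cfg.predictors
    ])
    start = rec["day"].to_numpy(dtype=float)
    stop = start + 1.0
    est = np.empty_like(cfg.true_betas)
    for k in (1, 2, 3):
        event = (rec["T"] == rec["day"] + 1) & (rec["D"] == k)
        est[k - 1] = L.survival.CoxModel(X, start, stop, event).fit() \
            .params.to_numpy()
    return est


def run_cause_specific_recovery(n_reps=5, seed0=1000):
    """Monte-Carlo bias (mean estimate minus truth) of the cause-specific
    coefficients over replicate cohorts."""
    reps = []
    for r in range(n_reps):
        cfg = recovery_config(seed=seed0 + r)
        episodes, traj, _ = generate_cohort(cfg)
        reps.append(fit_cause_specific_daily(cfg, episodes, traj))
    return np.mean(reps, axis=0) - recovery_config(0).true_betas


def run_fg_recovery(n=4000, beta=0.5, pmix=0.66, seed=9):
    """Fine-Gray recovery under a proportional subdistribution hazards
    mechanism (mixture construction): F1(t|Z) = 1-(1-pmix(1-e^{-t}))^e^{bZ}.
    Returns (estimate, model SE)."""
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, 1))
    e = np.exp(beta * Z[:, 0])
    p1 = 1.0 - (1.0 - pmix) ** e
    is1 = rng.random(n) < p1
    T = np.empty(n)
    u_scaled = rng.random(is1.sum()) * p1[is1]
    inner = 1.0 - (1.0 - u_scaled) ** (1.0 / e[is1])
    T[is1] = -np.log(1.0 - inner / pmix)
    T[~is1] = rng.exponential(1.0, (~is1).sum())
    D = np.where(is1, 1, 2)
    lm0 = pd.DataFrame({
        "episode_id": np.arange(n), "admission_id": np.arange(n), "s": 0.0,
        "T_lm": T, "status": D, "y7": 0, "category": "none", "z": Z[:, 0],
    })
    cfg = L.landmark.PredictionConfig(w=int(np.ceil(T.max())) + 1,
                                      landmark_grid=(0,))
    cp = L.landmark.finegray_transform(lm0, cfg, covariates=["z"])
    fit = L.survival.fit_finegray(cp, cp[["z"]].to_numpy(), names=["z"])
    return float(fit.params.iloc[0]), float(fit.bse.iloc[0])
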