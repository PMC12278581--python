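"""Survival fitters against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import landmarkcr as L
from landmarkcr._cox import CoxEngine, FitError, newton_solve
from landmarkcr.survival import (
    CauseSpecificResults, CoxModel, fit_cause_specific, fit_cox,
    fit_finegray, fit_finegray_per_landmark, fit_landmark_supermodel,
)


def brute_force_efron_loglik(beta, X, T, E):
    """Naive O(n^2) Efron partial log-likelihood (right censoring, start 0)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    r = np.exp(eta)
    ll = 0.0
    for t in np.unique(T[E]):
        D = np.flatnonzero((T == t) & E)
        R = np.flatnonzero(T >= t)
        d = len(D)
        ll += eta[D].sum()
        for j in range(d):
            ll -= np.log(r[R].sum() - (j / d) * r[D].sum())
    return ll


@pytest.mark.parametrize("n,p,seed", [(40, 2, 0), (100, 3, 1), (60, 1, 2)])
def test_cox_matches_brute_force_newton_oracle(n, p, seed):
    """Coefficients agree to 1e-6 with direct numerical maximization of the
    explicitly-written Efron partial likelihood."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    T = np.ceil(rng.exponential(8 * np.exp(-X @ np.linspace(0.5, -0.5, p)), n))
    E = rng.random(n) < 0.7
    ours = CoxModel(X, np.zeros(n), T, E, ties="efron").fit()
    res = optimize.minimize(
        lambda b: -brute_force_efron_loglik(b, X, T, E), np.zeros(p),
        method="BFGS", options={"gtol": 1e-10},
    )
    assert np.abs(ours.params.to_numpy() - res.x).max() < 1e-6


def test_cox_toy_binary_example():
    """Four events at days 1..4 with interleaved groups: coefficient matches
    exhaustive maximization of the explicit partial likelihood.  (A fully
    group-ordered event sequence has a monotone likelihood and no MLE.)"""
    X = np.array([[0.0], [1.0], [0.0], [1.0]])
    T = np.array([1.0, 2.0, 3.0, 4.0])
    E = np.ones(4, bool)
    ours = CoxModel(X, np.zeros(4), T, E).fit()
    res = optimize.minimize_scalar(
        lambda b: -brute_force_efron_loglik(np.array([b]), X, T, E),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    )
    assert abs(ours.params.iloc[0] - res.x) < 1e-6


def test_breslow_baseline_equals_nelson_aalen_without_covariates():
    rng = np.random.default_rng(3)
    n = 200
    T = np.ceil(rng.exponential(5, n))
    E = rng.random(n) < 0.8
    fit = CoxModel(np.zeros((n, 1)), np.zeros(n), T, E, names=["null"]).fit()
    # Nelson-Aalen: d_t / n_at_risk(t)
    for t, inc in zip(fit.baseline_times, fit.baseline_increments):
        d = np.sum((T == t) & E)
        at = np.sum(T >= t)
        assert inc == pytest.approx(d / at, abs=1e-12)


def test_duplicated_rows_leave_coefficients_unchanged():
    rng = np.random.default_rng(4)
    n = 80
    X = rng.normal(size=(n, 2))
    T = np.ceil(rng.exponential(6 * np.exp(-X[:, 0] * 0.4), n))
    E = rng.random(n) < 0.7
    f1 = CoxModel(X, np.zeros(n), T, E, ties="breslow").fit()
    X2, T2, E2 = np.vstack([X, X]), np.concatenate([T, T]), np.concatenate([E, E])
    f2 = CoxModel(X2, np.zeros(2 * n), T2, E2, ties="breslow").fit()
    assert np.abs(f1.params - f2.params).max() < 1e-6


def test_predict_cox_risk_closed_form_and_limits():
    fit = CoxModel(np.array([[1.0], [0.0], [1.0]]), np.zeros(3),
                   np.array([1.0, 2.0, 3.0]), np.ones(3, bool)).fit()
    # overwrite the baseline with a known value to check the formula alone
    fit.baseline_times = np.array([7.0])
    fit.baseline_increments = np.array([0.05])
    fit.params[:] = [0.0]
    assert fit.predict_risk(np.array([[1.0]]), 7)[0] == \
        pytest.approx(1 - np.exp(-0.05), rel=1e-12)
    fit.params[:] = [-40.0]
    assert fit.predict_risk(np.array([[1.0]]), 7)[0] == pytest.approx(0.0, abs=1e-12)


def test_cause_specific_reduces_to_cox_without_competing_events():
    rng = np.random.default_rng(5)
    n = 120
    X = rng.normal(size=(n, 2))
    T = np.ceil(rng.exponential(5, n))
    D = np.where(rng.random(n) < 0.6, 1, 0)  # cause 1 or censored only
    rec = pd.DataFrame({"T": T, "D": D})
    cs = fit_cause_specific(rec, X)
    cox = fit_cox(rec, X, cause=1)
    assert np.abs(cs.fits[1].params - cox.params).max() == 0


def test_constant_hazard_cumulative_hazards_linear(constant_hazard_cohort):
    """With rates 0.1/0.1/0 the estimated per-cause cumulative hazards grow
    linearly; on daily-grouped data the Nelson-Aalen daily increment is the
    per-day cause probability (0.1/0.2)*(1-e^{-0.2}) = 0.0906, the value
    whose Aalen-Johansen composition returns the exact continuous-time CIF."""
    _, episodes, _, _ = constant_hazard_cohort
    rec = pd.DataFrame({"T": episodes["T"], "D": episodes["D"]})
    X = np.zeros((len(rec), 1))
    expected = 0.5 * (1 - np.exp(-0.2))
    for k in (1, 2):
        fit = fit_cox(rec, X, cause=k, admin_censor_at=10)
        cum = np.cumsum(fit.baseline_increments)
        slope = cum[-1] / fit.baseline_times[-1]
        assert slope == pytest.approx(expected, rel=0.05)
        # increments roughly constant over days (linear cumulative hazard)
        assert fit.baseline_increments.std() < 0.2 * expected


def test_admin_censoring_locality():
    """Fits with admin censoring at day 7 are identical on two cohorts that
    agree up to day 7."""
    rng = np.random.default_rng(6)
    n = 150
    X = rng.normal(size=(n, 2))
    T = np.ceil(rng.exponential(6, n))
    D = rng.integers(1, 4, n)
    rec1 = pd.DataFrame({"T": T, "D": D})
    T2, D2 = T.copy(), D.copy()
    late = T > 7
    T2[late] = T[late] + rng.integers(1, 20, late.sum())
    D2[late] = rng.integers(1, 4, late.sum())
    rec2 = pd.DataFrame({"T": T2, "D": D2})
    f1 = fit_cox(rec1, X, admin_censor_at=7)
    f2 = fit_cox(rec2, X, admin_censor_at=7)
    assert np.abs(f1.params - f2.params).max() == 0


def test_cif_conservation_and_monotonicity(constant_hazard_cohort):
    _, episodes, _, _ = constant_hazard_cohort
    rng = np.random.default_rng(0)
    n = len(episodes)
    X = rng.normal(size=(n, 1))
    rec = pd.DataFrame({"T": episodes["T"], "D": episodes["D"]})
    fit = fit_cause_specific(rec, X)
    Z = rng.normal(size=(5, 1))
    cifs = fit.predict_all_cifs(Z, 0, 7)
    # conservation: residual survival + all cause CIFs = 1
    h = np.zeros(5)
    total = sum(cifs.values())
    # compute survival directly from the hazard composition
    surv = 1.0 - total
    assert np.all(total <= 1 + 1e-12)
    risks7 = fit.predict_cif(Z, 0, 7)
    risks10 = fit.predict_cif(Z, 0, 10)
    assert np.all(risks10 >= risks7 - 1e-12)


def test_cif_constant_hazard_closed_form(constant_hazard_cohort):
    """Predicted 7-day infection CIF within 2% of 0.5*(1-e^{-1.4})."""
    _, episodes, _, _ = constant_hazard_cohort
    rec = pd.DataFrame({"T": episodes["T"], "D": episodes["D"]})
    X = np.zeros((len(rec), 1))
    fit = fit_cause_specific(rec, X)
    pred = fit.predict_cif(np.zeros((1, 1)), 0, 7)[0]
    assert pred == pytest.approx(0.5 * (1 - np.exp(-1.4)), rel=0.02)


def test_zero_cause1_baseline_gives_zero_cif():
    rec = pd.DataFrame({"T": [2.0, 3.0, 4.0, 5.0], "D": [2, 3, 2, 3]})
    X = np.zeros((4, 1))
    fit = CauseSpecificResults({
        2: fit_cox(rec, X, cause=2), 3: fit_cox(rec, X, cause=3)})
    assert fit.predict_cif(np.zeros((1, 1)), 0, 7, cause=1)[0] == 0.0


# --- Fine-Gray ------------------------------------------------------------


def _fg_cp_static(T, D, Z, names, w=None):
    n = len(T)
    lm0 = pd.DataFrame({"episode_id": np.arange(n), "admission_id": np.arange(n),
                        "s": 0.0, "T_lm": T, "status": D, "y7": 0,
                        "category": "none"})
    for j, nm in enumerate(names):
        lm0[nm] = Z[:, j]
    horizon = w if w is not None else int(np.ceil(T.max())) + 1
    cfg = L.landmark.PredictionConfig(w=horizon, landmark_grid=(0,))
    return L.landmark.finegray_transform(lm0, cfg, covariates=names)


def test_finegray_reduces_to_cox_without_competing_events():
    rng = np.random.default_rng(7)
    n = 150
    Z = rng.normal(size=(n, 2))
    T = np.ceil(rng.exponential(5 * np.exp(-0.3 * Z[:, 0]), n))
    D = np.where(rng.random(n) < 0.7, 1, 0)
    cp = _fg_cp_static(T, np.where(D == 1, 1, 0), Z, ["a", "b"], w=60)
    fg = fit_finegray(cp, cp[["a", "b"]].to_numpy(), names=["a", "b"])
    rec = pd.DataFrame({"T": T, "D": D})
    cox = fit_cox(rec, Z, names=["a", "b"], admin_censor_at=60, ties="breslow")
    assert np.abs(fg.params - cox.params).max() < 1e-8


def test_finegray_weight_scale_invariance():
    rng = np.random.default_rng(8)
    n = 200
    Z = rng.normal(size=(n, 2))
    T = np.ceil(rng.exponential(5, n))
    D = rng.integers(1, 4, n)
    cp = _fg_cp_static(T, D, Z, ["a", "b"])
    f1 = fit_finegray(cp, cp[["a", "b"]].to_numpy(), names=["a", "b"])
    cp2 = cp.copy()
    cp2["weight"] = 2.0 * cp2["weight"]
    f2 = fit_finegray(cp2, cp2[["a", "b"]].to_numpy(), names=["a", "b"])
    assert np.abs(f1.params - f2.params).max() < 1e-10


def test_finegray_recovers_subdistribution_coefficient():
    """Data drawn from a proportional subdistribution hazards mechanism
    (mixture construction, beta=0.5, n=4000) is recovered within 3 SE."""
    rng = np.random.default_rng(9)
    n, beta, pmix = 4000, 0.5, 0.66
    Z = rng.normal(size=(n, 1))
    e = np.exp(beta * Z[:, 0])
    p1 = 1.0 - (1.0 - pmix) ** e  # P(cause 1 | Z)
    is1 = rng.random(n) < p1
    U = rng.random(n)
    # F1(t|Z)/p1 = [1-(1-pmix(1-e^-t))^e] / p1: invert by bisection
    T = np.empty(n)
    u_scaled = U[is1] * p1[is1]
    ee = e[is1]
    inner = 1.0 - (1.0 - u_scaled) ** (1.0 / ee)
    T[is1] = -np.log(1.0 - inner / pmix)
    T[~is1] = rng.exponential(1.0, (~is1).sum())
    D = np.where(is1, 1, 2)
    cp = _fg_cp_static(T, D, Z, ["z"])
    fit = fit_finegray(cp, cp[["z"]].to_numpy(), names=["z"])
    se = fit.bse.iloc[0]
    assert abs(fit.params.iloc[0] - beta) < 3 * se


def test_fg_risk_closed_form():
    rng = np.random.default_rng(10)
    n = 100
    Z = rng.normal(size=(n, 1))
    T = np.ceil(rng.exponential(5, n))
    D = rng.integers(1, 3, n)
    cp = _fg_cp_static(T, D, Z, ["z"])
    fit = fit_finegray(cp, cp[["z"]].to_numpy(), names=["z"])
    fit.baseline_times = np.array([3.0])
    fit.baseline_increments = np.array([0.02])
    fit.params[:] = [0.0]
    assert fit.predict_risk(np.array([[1.0]]), 7)[0] == \
        pytest.approx(1 - np.exp(-0.02), rel=1e-12)
    fit.baseline_increments = np.array([0.0])
    assert fit.predict_risk(np.array([[5.0]]), 7)[0] == 0.0


# --- landmark supermodels -------------------------------------------------


def test_supermodel_single_landmark_reduces_to_static(small_cohort):
    cfg, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    pc = L.landmark.PredictionConfig(w=7, landmark_grid=(0,))
    lookback = {p.name: p.lookback for p in cfg.predictors}
    stacked = L.landmark.build_stacked_dataset(episodes, traj, pc,
                                               lookback=lookback)
    spec = L.features.default_covariate_spec(cfg.predictors)
    recipe = L.features.fit_recipe(stacked, spec, include_landmark_terms=True)
    X, names = L.features.build_design(stacked, recipe)
    assert "s" not in names  # constant landmark terms are dropped
    sm = fit_landmark_supermodel(stacked, "cox", X, names=names)
    static = fit_cox(stacked, X, names=names)
    assert np.abs(sm.params - static.params).max() == 0


def test_fg_per_landmark_failure_recorded_not_fatal():
    rng = np.random.default_rng(11)
    n = 60
    lm = pd.DataFrame({
        "episode_id": np.arange(n), "admission_id": np.arange(n), "s": 3.0,
        "T_lm": 10.0, "status": 0, "y7": 0, "category": "none",
        "z": rng.normal(size=n),
    })
    # no cause-1 events at this landmark -> recorded failure
    cfg = L.landmark.PredictionConfig(w=7, landmark_grid=(3,))
    cp = L.landmark.finegray_transform(lm, cfg, covariates=["z"])
    fits = fit_finegray_per_landmark(
        {3: cp}, lambda t: (t[["z"]].to_numpy(), ["z"]))
    assert isinstance(fits[3], FitError)


def test_nonconvergent_fit_raises_explicitly():
    # perfectly separated covariate -> monotone likelihood
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    T = np.array([5.0, 6.0, 1.0, 2.0])
    E = np.array([False, False, True, True])
    with pytest.raises(FitError):
        CoxModel(X, np.zeros(4), T, E).fit()
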