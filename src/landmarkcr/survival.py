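"""Time-to-event risk models: Cox, cause-specific, Fine-Gray, and their
landmark supermodel variants.

All models share one numerical core (weighted partial likelihood over
counting-process risk sets, Newton-Raphson with step-halving, Breslow
baseline) and one prediction contract: a 7-day risk of the infection cause
for a covariate vector, either from catheter onset (static) or conditional
on being event-free at a landmark day s (dynamic).

Model/Results organisation: construct a model object from data, call
``.fit()``, get a results object carrying coefficients, baseline
cumulative-hazard increments and prediction methods.  The module-level
``fit_*`` functions are thin wrappers over these classes.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from ._cox import CoxEngine, FitError, newton_solve

__all__ = [
    "CoxModel", "CoxResults", "CauseSpecificResults", "FineGrayResults",
    "fit_cox", "fit_cause_specific", "fit_finegray",
    "fit_landmark_supermodel", "fit_finegray_per_landmark",
    "predict_cox_risk", "predict_cif", "predict_fg_risk", "FitError",
]


def _clip_prob(p, context=""):
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        warnings.warn(f"predicted probabilities clipped to [0,1] {context}")
    return np.clip(p, 0.0, 1.0)


class CoxModel:
    """Proportional-hazards partial likelihood over (start, stop] records.

    Parameters
    ----------
    design : (n, p) array
    start, stop : entry and exit times (time since catheter onset)
    event : boolean event indicator for the modeled cause
    weights : optional case weights (IPCW for subdistribution fits)
    ties : "efron" (default for unweighted fits) or "breslow"
    names : column names for reporting
    """

    def __init__(self, design, start, stop, event, weights=None,
                 ties="efron", names=None):
        self.design = np.asarray(design, dtype=float)
        self.start = np.asarray(start, dtype=float)
        self.stop = np.asarray(stop, dtype=float)
        self.event = np.asarray(event).astype(bool)
        self.weights = weights
        self.ties = ties
        self.names = list(names) if names is not None else \
            [f"x{j}" for j in range(self.design.shape[1])]

    def fit(self, tol=1e-8, max_iter=100) -> "CoxResults":
        eng = CoxEngine(self.design, self.start, self.stop, self.event,
                        weights=self.weights, ties=self.ties)
        beta, ll, g, H, n_iter = newton_solve(
            eng.loglik_grad_hess, np.zeros(self.design.shape[1]),
            tol=tol, max_iter=max_iter,
        )
        times, incr = eng.breslow_baseline(beta)
        return CoxResults(
            params=pd.Series(beta, index=self.names),
            baseline_times=times, baseline_increments=incr,
            loglik=ll, n_iter=n_iter, ties=self.ties,
            hessian=H, n_obs=len(self.stop), n_events=int(self.event.sum()),
        )


class CoxResults:
    """Fitted proportional-hazards model (one cause)."""

    def __init__(self, params, baseline_times, baseline_increments, loglik,
                 n_iter, ties, hessian, n_obs, n_events):
        self.params = params
        self.baseline_times = np.asarray(baseline_times, dtype=float)
        self.baseline_increments = np.asarray(baseline_increments, dtype=float)
        self.loglik = loglik
        self.n_iter = n_iter
        self.ties = ties
        self.hessian = hessian
        self.n_obs = n_obs
        self.n_events = n_events

    @property
    def bse(self):
        """Model-based standard errors (inverse observed information).  For
        stacked landmark supermodels these ignore the within-episode
        correlation across landmarks; used for screening only."""
        cov = np.linalg.inv(-self.hessian)
        return pd.Series(np.sqrt(np.diag(cov)), index=self.params.index)

    def linear_predictor(self, Z):
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != len(self.params):
            raise ValueError(
                f"covariate vector has {Z.shape[1]} entries, model has "
                f"{len(self.params)} ({list(self.params.index)})"
            )
        return Z @ self.params.to_numpy()

    def cumhaz_between(self, a, b):
        """Baseline cumulative hazard over (a, b]."""
        mask = (self.baseline_times > a) & (self.baseline_times <= b)
        return float(self.baseline_increments[mask].sum())

    def predict_risk(self, Z, horizon, from_day=0.0):
        """1 - exp(-[Lambda0(s+w) - Lambda0(s)] * exp(beta'Z)), clipped."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        lp = self.linear_predictor(Z)
        dL = self.cumhaz_between(from_day, from_day + horizon)
        return _clip_prob(-np.expm1(-dL * np.exp(lp)), "(cox risk)")

    def summary(self):
        df = pd.DataFrame({
            "coef": self.params,
            "exp(coef)": np.exp(self.params),
            "se(coef)": self.bse,
        })
        head = (f"Proportional-hazards fit | n={self.n_obs} "
                f"events={self.n_events} ties={self.ties} "
                f"loglik={self.loglik:.3f} iter={self.n_iter}\n")
        return head + df.to_string(float_format=lambda v: f"{v: .4f}")

    def to_json(self):
        return json.dumps({
            "params": self.params.to_dict(),
            "baseline_times": self.baseline_times.tolist(),
            "baseline_increments": self.baseline_increments.tolist(),
            "ties": self.ties,
            "loglik": self.loglik,
        }, indent=2)


class CauseSpecificResults:
    """One CoxResults per cause (1 infection, 2 death, 3 discharge)."""

    def __init__(self, fits: dict):
        self.fits = fits  # cause -> CoxResults or FitError

    def ok(self, cause):
        return isinstance(self.fits.get(cause), CoxResults)

    def predict_cif(self, Z, from_day=0.0, horizon=7.0, cause=1):
        """Discrete Aalen-Johansen composition of the cause-specific hazards:
        F_k(s+w | s) = sum over event times t in (s, s+w] of
        h_k(t|Z) * prod over earlier times of (1 - sum_j h_j(t'|Z))."""
        times = np.unique(np.concatenate([
            f.baseline_times for f in self.fits.values()
            if isinstance(f, CoxResults)
        ]))
        times = times[(times > from_day) & (times <= from_day + horizon)]
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        n = Z.shape[0]
        if len(times) == 0:
            return np.zeros(n)
        # per-cause hazard contributions at each time
        h = np.zeros((3, n, len(times)))
        for k, fit in self.fits.items():
            if not isinstance(fit, CoxResults):
                continue
            lp = fit.linear_predictor(Z)
            incr = np.zeros(len(times))
            mask = (fit.baseline_times > from_day) & \
                   (fit.baseline_times <= from_day + horizon)
            incr_map = dict(zip(fit.baseline_times[mask],
                                fit.baseline_increments[mask]))
            for j, t in enumerate(times):
                incr[j] = incr_map.get(t, 0.0)
            h[k - 1] = np.exp(lp)[:, None] * incr[None, :]
        h_tot = h.sum(axis=0)
        if np.any(h_tot > 1 + 1e-12):
            warnings.warn("hazard increments exceed 1; survival floor at 0")
        surv_before = np.cumprod(np.clip(1.0 - h_tot, 0.0, 1.0), axis=1)
        surv_before = np.column_stack([np.ones(n), surv_before[:, :-1]])
        F = (h[cause - 1] * surv_before).sum(axis=1)
        return _clip_prob(F, "(cause-specific CIF)")

    def predict_all_cifs(self, Z, from_day=0.0, horizon=7.0):
        return {k: self.predict_cif(Z, from_day, horizon, cause=k)
                for k in (1, 2, 3)}

    def summary(self):
        parts = []
        for k in sorted(self.fits):
            f = self.fits[k]
            parts.append(f"--- cause {k} ---")
            parts.append(f.summary() if isinstance(f, CoxResults) else
                         f"fit failed: {f}")
        return "\n".join(parts)


class FineGrayResults(CoxResults):
    """Subdistribution-hazard fit; risk prediction uses the subdistribution
    cumulative hazard directly: 1 - exp(-dLambda_sub * exp(beta'Z))."""


# ---------------------------------------------------------------------------
# functional fitting surface


def _admin_censor(stop, event_cause, at):
    """Truncate follow-up at `at`: times capped, causes beyond zeroed."""
    stop = np.asarray(stop, dtype=float)
    cause = np.asarray(event_cause).copy()
    beyond = stop > at
    cause[beyond] = 0
    return np.minimum(stop, at), cause


def fit_cox(records: pd.DataFrame, design, names=None, admin_censor_at=None,
            cause=1, ties="efron") -> CoxResults:
    """Cox model for one cause on episode records with columns T (or T_lm)
    and D (or status); other causes' events are treated as censoring times
    (this is exactly the cause-`cause` component of a cause-specific fit).

    admin_censor_at truncates follow-up (times capped, statuses zeroed) at
    the given day before fitting.
    """
    tcol = "T" if "T" in records else "T_lm"
    dcol = "D" if "D" in records else "status"
    stop = records[tcol].to_numpy(dtype=float)
    D = records[dcol].to_numpy()
    if admin_censor_at is not None:
        stop, D = _admin_censor(stop, D, admin_censor_at)
    start = records["s"].to_numpy(dtype=float) if "s" in records \
        else np.zeros(len(records))
    model = CoxModel(design, start, stop, D == cause, ties=ties, names=names)
    return model.fit()


def fit_cause_specific(records, design, names=None,
                       admin_censor_at=None) -> CauseSpecificResults:
    """One Cox fit per cause; a failed per-cause fit is stored as the
    FitError (never silent, never fatal for the other causes)."""
    fits = {}
    for k in (1, 2, 3):
        try:
            fits[k] = fit_cox(records, design, names=names,
                              admin_censor_at=admin_censor_at, cause=k)
        except FitError as e:
            warnings.warn(f"cause {k} fit failed: {e}")
            fits[k] = e
    if not isinstance(fits[1], CoxResults):
        raise FitError(f"infection-cause fit failed: {fits[1]}")
    return CauseSpecificResults(fits)


def fit_finegray(cp_records: pd.DataFrame, design, names=None,
                 ties="breslow") -> FineGrayResults:
    """Weighted Cox partial likelihood on counting-process records from
    ``landmark.finegray_transform`` (columns start, stop, event, weight).
    Breslow ties by default, matching the IPCW-weighted likelihood."""
    model = CoxModel(
        design,
        cp_records["start"].to_numpy(dtype=float),
        cp_records["stop"].to_numpy(dtype=float),
        cp_records["event"].to_numpy().astype(bool),
        weights=cp_records["weight"].to_numpy(dtype=float),
        ties=ties, names=names,
    )
    r = model.fit()
    return FineGrayResults(
        params=r.params, baseline_times=r.baseline_times,
        baseline_increments=r.baseline_increments, loglik=r.loglik,
        n_iter=r.n_iter, ties=r.ties, hessian=r.hessian, n_obs=r.n_obs,
        n_events=r.n_events,
    )


def fit_landmark_supermodel(stacked: pd.DataFrame, family, design, names=None):
    """Landmark supermodel over a stacked dataset.

    family "cox": one Cox fit for the infection cause; "cause_specific":
    three; "finegray": expects counting-process stacked records (from
    ``landmark.stack_finegray``).  Each landmark record contributes risk only
    within its own window (start=s, stop=T_lm], which the counting-process
    representation enforces.
    """
    if family == "cox":
        return fit_cox(stacked, design, names=names)
    if family == "cause_specific":
        return fit_cause_specific(stacked, design, names=names)
    if family == "finegray":
        return fit_finegray(stacked, design, names=names)
    raise ValueError(f"unknown supermodel family {family!r}")


def fit_finegray_per_landmark(per_landmark_cp: dict, design_fn):
    """Independent Fine-Gray fit per landmark; failures are recorded per
    landmark (value is the FitError), not fatal.

    per_landmark_cp maps s -> counting-process table; design_fn maps a table
    to (design matrix, names).
    """
    fits = {}
    for s, cp in per_landmark_cp.items():
        try:
            if len(cp) == 0 or cp["event"].sum() == 0:
                raise FitError(f"no infection events at landmark {s}")
            X, names = design_fn(cp)
            fits[s] = fit_finegray(cp, X, names=names)
        except (FitError, np.linalg.LinAlgError) as e:
            warnings.warn(f"Fine-Gray fit failed at landmark {s}: {e}")
            fits[s] = e if isinstance(e, FitError) else FitError(str(e))
    return fits


# prediction wrappers mirroring the functional op surface

def predict_cox_risk(fit: CoxResults, Z, horizon, from_day=0.0):
    return fit.predict_risk(Z, horizon, from_day=from_day)


def predict_cif(fit: CauseSpecificResults, Z, from_day=0.0, horizon=7.0):
    return fit.predict_cif(Z, from_day=from_day, horizon=horizon)


def predict_fg_risk(fit: FineGrayResults, Z, from_day=0.0, horizon=7.0):
    return fit.predict_risk(Z, horizon, from_day=from_day)
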