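"""Weighted Cox partial-likelihood engine over counting-process risk sets.

This is the numerical core shared by the plain Cox model, the cause-specific
hazard model, the Fine-Gray subdistribution model (via IPCW-weighted records)
and all landmark supermodel variants.  Records are (start, stop] intervals;
an episode is at risk for an event at time t iff start < t <= stop.  Daily
(integer) event times produce heavy ties, handled by Efron's correction for
unweighted fits and Breslow's for weighted ones.
"""

from __future__ import annotations

import numpy as np


class FitError(RuntimeError):
    """Raised when a likelihood fit fails (non-convergence, separation,
    monotone likelihood, singular information).  Never silent."""


def _check_inputs(X, start, stop, event, weights):
    X = np.asarray(X, dtype=float)
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(bool)
    n = X.shape[0]
    if weights is None:
        weights = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
    if not (len(start) == len(stop) == len(event) == len(weights) == n):
        raise ValueError("input length mismatch")
    if np.any(stop <= start):
        raise ValueError("stop must exceed start for every record")
    if np.any(weights < 0):
        raise ValueError("negative weights")
    return X, start, stop, event, weights


class CoxEngine:
    """Precomputes risk-set bookkeeping; evaluates loglik/gradient/Hessian.

    Risk sets are maintained incrementally while sweeping the distinct event
    times in decreasing order: a record enters at the largest event time not
    exceeding its stop and leaves once the sweep passes its start.
    """

    def __init__(self, X, start, stop, event, weights=None, ties="efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        X, start, stop, event, weights = _check_inputs(X, start, stop, event, weights)
        self.X, self.start, self.stop = X, start, stop
        self.event, self.weights, self.ties = event, weights, ties
        self.n, self.p = X.shape
        self.times = np.unique(stop[event])  # ascending distinct event times
        L = len(self.times)
        if L == 0:
            raise FitError("no events of the modeled type in the data")
        # index of the largest event time <= stop (entry point in the sweep)
        self._enter = np.searchsorted(self.times, stop, side="right") - 1
        # a record is OUT of the risk set at time index k iff times[k] <= start
        self._leave = np.searchsorted(self.times, start, side="right") - 1
        # event membership per time index
        ev_idx = np.searchsorted(self.times, stop[event])
        self._events_at = [[] for _ in range(L)]
        for row, k in zip(np.flatnonzero(event), ev_idx):
            self._events_at[k].append(row)
        self._enter_at = [[] for _ in range(L)]
        self._leave_at = [[] for _ in range(L)]
        for i in range(self.n):
            k_in = self._enter[i]
            if k_in < 0:
                continue
            self._enter_at[k_in].append(i)
            k_out = self._leave[i]
            if k_out >= 0:
                self._leave_at[k_out].append(i)

    def loglik_grad_hess(self, beta):
        X, w, ties = self.X, self.weights, self.ties
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        r = w * np.exp(eta)
        p = self.p
        ll = 0.0
        g = np.zeros(p)
        H = np.zeros((p, p))
        S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
        for k in range(len(self.times) - 1, -1, -1):
            add = self._enter_at[k]
            if add:
                ra, Xa = r[add], X[add]
                S0 += ra.sum()
                S1 += ra @ Xa
                S2 += (Xa * ra[:, None]).T @ Xa
            drop = self._leave_at[k]
            if drop:
                rd, Xd = r[drop], X[drop]
                S0 -= rd.sum()
                S1 -= rd @ Xd
                S2 -= (Xd * rd[:, None]).T @ Xd
            ev = self._events_at[k]
            if not ev:
                continue
            we, Xe, re = w[ev], X[ev], r[ev]
            WD = we.sum()
            ll += float(we @ eta[ev])
            g += we @ Xe
            if ties == "breslow" or len(ev) == 1:
                if S0 <= 0:
                    raise FitError("empty risk set at an event time")
                m1 = S1 / S0
                ll -= WD * np.log(S0)
                g -= WD * m1
                H -= WD * (S2 / S0 - np.outer(m1, m1))
            else:
                d = len(ev)
                S0D = re.sum()
                S1D = re @ Xe
                S2D = (Xe * re[:, None]).T @ Xe
                wbar = WD / d
                for j in range(d):
                    f = j / d
                    phi0 = S0 - f * S0D
                    if phi0 <= 0:
                        raise FitError("empty risk set at an event time")
                    phi1 = S1 - f * S1D
                    m1 = phi1 / phi0
                    ll -= wbar * np.log(phi0)
                    g -= wbar * m1
                    H -= wbar * ((S2 - f * S2D) / phi0 - np.outer(m1, m1))
        return ll, g, H

    def breslow_baseline(self, beta):
        """Baseline cumulative-hazard increments dLambda0(t_k) = sum of event
        weights at t_k over the weighted risk-set total S0(t_k)."""
        r = self.weights * np.exp(np.clip(self.X @ beta, -500, 500))
        L = len(self.times)
        incr = np.zeros(L)
        S0 = 0.0
        for k in range(L - 1, -1, -1):
            add = self._enter_at[k]
            if add:
                S0 += r[add].sum()
            drop = self._leave_at[k]
            if drop:
                S0 -= r[drop].sum()
            ev = self._events_at[k]
            if ev:
                incr[k] = self.weights[ev].sum() / S0
        return self.times.copy(), incr


def newton_solve(fun, beta0, tol=1e-8, max_iter=100, max_abs_beta=15.0):
    """Maximize a concave objective by Newton-Raphson with step-halving.

    `fun(beta)` returns (loglik, gradient, hessian-of-loglik).  Converges when
    the gradient's max absolute entry drops below `tol`.  Divergence of the
    coefficients (monotone likelihood / separation — the likelihood flattens
    while the coefficient walks off, so the magnitude check applies at every
    exit, not only during iteration) and singular information raise FitError.
    """
    beta = np.asarray(beta0, dtype=float).copy()

    def _checked(value):
        if np.max(np.abs(value[0])) > max_abs_beta:
            raise FitError(
                "diverging coefficients: monotone likelihood or separation"
            )
        return value

    ll, g, H = fun(beta)
    for it in range(max_iter):
        if np.max(np.abs(g)) < tol:
            return _checked((beta, ll, g, H, it))
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            raise FitError("singular information matrix (collinear design?)")
        if not np.all(np.isfinite(step)):
            raise FitError("non-finite Newton step")
        # Newton decrement: the expected log-likelihood gain of a full step.
        # Once it falls below the float resolution of the log-likelihood the
        # solution is converged to machine precision even if the raw
        # gradient (a large-cancellation sum) cannot reach the absolute
        # tolerance on big stacked datasets.
        decrement = 0.5 * float(g @ step)
        if decrement < 100 * np.finfo(float).eps * (1.0 + abs(ll)):
            return _checked((beta, ll, g, H, it))
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, H_new = fun(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            # the likelihood can no longer be improved at float resolution;
            # accept if the expected remaining gain is negligible on the
            # scale of the log-likelihood, otherwise report failure
            if decrement < 1e-7 * (1.0 + abs(ll)):
                return _checked((beta, ll, g, H, it))
            raise FitError("step-halving failed to improve the likelihood")
        beta, ll, g, H = cand, ll_new, g_new, H_new
        # loose runaway guard during iteration (transient overshoots of a
        # few units are normal for rare outcomes; the tight separation
        # check applies only at convergence)
        if np.max(np.abs(beta)) > 10 * max_abs_beta:
            raise FitError(
                "diverging coefficients: monotone likelihood or separation"
            )
    raise FitError(f"no convergence in {max_iter} Newton iterations "
                   f"(max |gradient| = {np.max(np.abs(g)):.3g})")
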