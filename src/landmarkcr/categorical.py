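"""Binary logistic and four-category multinomial outcome models.

With no censoring, the 7-day infection outcome is fully observed for every
at-risk episode, so the categorical family needs no competing-risk
correction: a competing event inside the window simply counts as a
non-event (logistic) or as its own outcome class (multinomial).  Reference
category is "none" (still at risk at s+w); the non-reference blocks are
ordered clabsi, death, discharge so coefficient signs are deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from ._cox import FitError, newton_solve

CATEGORIES = ("none", "clabsi", "death", "discharge")


def _add_intercept(X):
    X = np.asarray(X, dtype=float)
    return np.column_stack([np.ones(len(X)), X])


class LogisticModel:
    """Maximum-likelihood logistic regression (IRLS / Newton with
    step-halving; gradient tolerance 1e-8).  Complete separation surfaces as
    a FitError, never as silent shrinkage."""

    def __init__(self, design, y, names=None):
        design = np.asarray(design, dtype=float)
        # centering improves conditioning and keeps the working intercept on
        # the logit-of-prevalence scale; the reported intercept is mapped
        # back to the original covariate scale after the fit
        self._center = design.mean(axis=0) if design.size else \
            np.zeros(design.shape[1])
        self.X = _add_intercept(design - self._center)
        self.y = np.asarray(y, dtype=float)
        if not set(np.unique(self.y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary")
        if self.y.min() == self.y.max():
            raise FitError("only one outcome class present")
        base = list(names) if names is not None else \
            [f"x{j}" for j in range(self.X.shape[1] - 1)]
        self.names = ["intercept"] + base

    def _llgh(self, beta):
        eta = np.clip(self.X @ beta, -500, 500)
        p = expit(eta)
        ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        g = self.X.T @ (self.y - p)
        W = p * (1.0 - p)
        H = -(self.X * W[:, None]).T @ self.X
        return ll, g, H

    def fit(self, tol=1e-8, max_iter=100) -> "LogisticResults":
        beta, ll, g, H, it = newton_solve(self._llgh, np.zeros(self.X.shape[1]),
                                          tol=tol, max_iter=max_iter)
        beta = beta.copy()
        beta[0] -= beta[1:] @ self._center
        return LogisticResults(pd.Series(beta, index=self.names), ll, it, H)


class LogisticResults:
    def __init__(self, params, loglik, n_iter, hessian):
        self.params = params
        self.loglik = loglik
        self.n_iter = n_iter
        self.hessian = hessian

    def predict_proba(self, design):
        X = _add_intercept(design)
        if X.shape[1] != len(self.params):
            raise ValueError("design width does not match fitted model")
        return expit(np.clip(X @ self.params.to_numpy(), -500, 500))

    def summary(self):
        df = pd.DataFrame({"coef": self.params,
                           "odds ratio": np.exp(self.params)})
        return (f"Logistic fit | loglik={self.loglik:.3f} iter={self.n_iter}\n"
                + df.to_string(float_format=lambda v: f"{v: .4f}"))

    def to_json(self):
        import json
        return json.dumps({"params": self.params.to_dict(),
                           "loglik": self.loglik}, indent=2)


class MultinomialModel:
    """Multinomial logit with reference category "none"; joint Newton MLE.

    Categories absent from the training data get no coefficient block; their
    predicted probability is 0 (with a warning at fit time).
    """

    def __init__(self, design, category, names=None):
        design = np.asarray(design, dtype=float)
        self._center = design.mean(axis=0) if design.size else \
            np.zeros(design.shape[1])
        self.X = _add_intercept(design - self._center)
        cats = pd.Categorical(category, categories=CATEGORIES)
        if cats.isna().any():
            raise ValueError(f"unknown outcome categories; allowed {CATEGORIES}")
        self.codes = cats.codes.astype(int)
        present = set(np.unique(self.codes))
        if len(present) < 2:
            raise FitError("fewer than two outcome categories present")
        self.blocks = [k for k in (1, 2, 3) if k in present]
        missing = [CATEGORIES[k] for k in (1, 2, 3) if k not in present]
        if missing:
            warnings.warn(f"categories absent from training: {missing}; "
                          "their predicted probability is 0")
        base = list(names) if names is not None else \
            [f"x{j}" for j in range(self.X.shape[1] - 1)]
        self.names = ["intercept"] + base

    def _llgh(self, theta):
        n, d = self.X.shape
        K = len(self.blocks)
        B = theta.reshape(K, d)
        eta = self.X @ B.T  # (n, K)
        eta = np.clip(eta, -500, 500)
        denom = np.logaddexp.reduce(np.column_stack([np.zeros(n), eta]), axis=1)
        P = np.exp(eta - denom[:, None])  # (n, K)
        Y = np.zeros((n, K))
        for j, k in enumerate(self.blocks):
            Y[:, j] = self.codes == k
        ll = float(np.sum(Y * eta) - np.sum(denom))
        G = self.X.T @ (Y - P)  # (d, K)
        H = np.empty((K * d, K * d))
        for a in range(K):
            for b in range(K):
                w = P[:, a] * ((a == b) - P[:, b])
                H[a * d:(a + 1) * d, b * d:(b + 1) * d] = \
                    -(self.X * w[:, None]).T @ self.X
        return ll, G.T.ravel(), H

    def fit(self, tol=1e-8, max_iter=100) -> "MultinomialResults":
        d = self.X.shape[1]
        theta, ll, g, H, it = newton_solve(
            self._llgh, np.zeros(len(self.blocks) * d), tol=tol,
            max_iter=max_iter,
        )
        B = theta.reshape(len(self.blocks), d).copy()
        B[:, 0] -= B[:, 1:] @ self._center
        coefs = {CATEGORIES[k]: pd.Series(B[j], index=self.names)
                 for j, k in enumerate(self.blocks)}
        return MultinomialResults(coefs, ll, it)


class MultinomialResults:
    def __init__(self, coefs: dict, loglik, n_iter):
        self.coefs = coefs  # category name -> Series (reference "none" at 0)
        self.loglik = loglik
        self.n_iter = n_iter

    def predict_proba(self, design) -> pd.DataFrame:
        X = _add_intercept(design)
        etas = {}
        for cat in CATEGORIES[1:]:
            if cat in self.coefs:
                etas[cat] = np.clip(X @ self.coefs[cat].to_numpy(), -500, 500)
        n = len(X)
        E = np.column_stack([np.zeros(n)] + [etas[c] for c in etas])
        denom = np.logaddexp.reduce(E, axis=1)
        out = pd.DataFrame({"none": np.exp(-denom)})
        for j, c in enumerate(etas):
            out[c] = np.exp(E[:, j + 1] - denom)
        for cat in CATEGORIES[1:]:
            if cat not in out:
                out[cat] = 0.0
        return out[list(CATEGORIES)]

    def summary(self):
        parts = [f"Multinomial fit | loglik={self.loglik:.3f} "
                 f"iter={self.n_iter} (reference: none)"]
        for cat, s in self.coefs.items():
            parts.append(f"--- {cat} vs none ---")
            parts.append(s.to_frame("coef").to_string(
                float_format=lambda v: f"{v: .4f}"))
        return "\n".join(parts)

    def to_json(self):
        import json
        return json.dumps({"coefs": {c: s.to_dict()
                                     for c, s in self.coefs.items()},
                           "loglik": self.loglik}, indent=2)


def fit_logistic(design, y, names=None) -> LogisticResults:
    return LogisticModel(design, y, names=names).fit()


def fit_multinomial(design, category, names=None) -> MultinomialResults:
    return MultinomialModel(design, category, names=names).fit()


def predict_category_risk(fit, design, target="clabsi"):
    """Predicted probability of the target class: the positive class for a
    logistic fit, the named category for a multinomial fit."""
    if isinstance(fit, LogisticResults):
        return fit.predict_proba(design)
    return fit.predict_proba(design)[target].to_numpy()
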