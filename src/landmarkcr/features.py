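"""Design-matrix construction for the risk models.

A FeatureRecipe is learned on training records only (spline knots,
standardization statistics) and then applied unchanged to any table with the
same covariates, so no test-set statistic can leak into a model.  Continuous
predictors may enter untransformed, log1p-transformed (right-skewed labs) or
through a restricted cubic spline with three knots (linear tails; knots at
the 10th/50th/90th training percentiles).  For dynamic (landmark) models the
design additionally carries the landmark day s, its square, and optional
covariate-by-landmark interaction products.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import FitError

TRANSFORMS = ("identity", "log1p", "rcs3")


def rcs_basis(x, knots):
    """Restricted (natural) cubic spline basis columns for the given knots.

    Returns k-1 columns for k knots: the identity column plus k-2 nonlinear
    columns in Harrell's truncated-power parameterization, which is linear
    beyond the outer knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    cols = [x]
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2
    plus = lambda v: np.maximum(v, 0.0) ** 3
    for j in range(k - 2):
        tj = knots[j]
        c = (plus(x - tj)
             - plus(x - tk1) * (tk - tj) / (tk - tk1)
             + plus(x - tk) * (tk1 - tj) / (tk - tk1)) / norm
        cols.append(c)
    return np.column_stack(cols)


@dataclass
class FeatureRecipe:
    """Frozen transformation plan learned from training data."""

    covariates: list
    transforms: dict                      # name -> identity|log1p|rcs3
    knots: dict = field(default_factory=dict)          # name -> [k1,k2,k3]
    dropped: list = field(default_factory=list)        # zero-variance columns
    include_landmark_terms: bool = False
    interactions: list = field(default_factory=list)   # names with x*s, x*s^2
    standardize: bool = False
    stats: dict = field(default_factory=dict)          # column -> (mean, sd)

    def to_json(self):
        return json.dumps(
            {
                "covariates": self.covariates,
                "transforms": self.transforms,
                "knots": {k: list(v) for k, v in self.knots.items()},
                "dropped": self.dropped,
                "include_landmark_terms": self.include_landmark_terms,
                "interactions": self.interactions,
                "standardize": self.standardize,
                "stats": {k: list(v) for k, v in self.stats.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text):
        d = json.loads(text)
        d["knots"] = {k: tuple(v) for k, v in d["knots"].items()}
        d["stats"] = {k: tuple(v) for k, v in d["stats"].items()}
        return cls(**d)


def fit_recipe(train_records: pd.DataFrame, covariate_spec: dict,
               want_standardize: bool = False,
               include_landmark_terms: bool = False,
               interactions=()) -> FeatureRecipe:
    """Learn a FeatureRecipe from training records.

    covariate_spec maps covariate name -> transform.  Spline knots are the
    10/50/90 training percentiles (numpy's default linear interpolation,
    i.e. type-7 quantiles); covariates constant in training are dropped with
    a warning; rcs3 falls back to a linear term when there are fewer than 10
    distinct training values.
    """
    covs, transforms, knots, dropped = [], {}, {}, []
    for name, tf in covariate_spec.items():
        if tf not in TRANSFORMS:
            raise ValueError(f"unknown transform {tf!r} for {name}")
        x = train_records[name].to_numpy(dtype=float)
        x = x[~np.isnan(x)]
        if len(np.unique(x)) <= 1:
            warnings.warn(f"covariate {name} is constant in training; dropped")
            dropped.append(name)
            continue
        covs.append(name)
        if tf == "rcs3":
            vals = x
            if len(np.unique(vals)) < 10:
                warnings.warn(
                    f"covariate {name}: too few distinct values for rcs3; "
                    "falling back to a linear term"
                )
                transforms[name] = "identity"
                continue
            q = np.quantile(vals, [0.10, 0.50, 0.90])
            if len(np.unique(q)) < 3:
                warnings.warn(
                    f"covariate {name}: tied rcs3 knots; falling back to linear"
                )
                transforms[name] = "identity"
                continue
            transforms[name] = "rcs3"
            knots[name] = tuple(q)
        else:
            transforms[name] = tf
    if include_landmark_terms and ("s" not in train_records
                                   or train_records["s"].nunique() < 2):
        warnings.warn("single landmark in training data: s, s^2 terms are "
                      "constant and dropped (static mode)")
        include_landmark_terms = False
    recipe = FeatureRecipe(
        covariates=covs, transforms=transforms, knots=knots, dropped=dropped,
        include_landmark_terms=include_landmark_terms,
        interactions=[i for i in interactions if i in covs],
        standardize=want_standardize,
    )
    if want_standardize:
        M, names = _raw_design(train_records, recipe)
        for j, nm in enumerate(names):
            col = M[:, j]
            sd = float(np.std(col))
            recipe.stats[nm] = (float(np.mean(col)), sd if sd > 0 else 1.0)
    return recipe


def _raw_design(records, recipe: FeatureRecipe):
    cols, names = [], []
    for name in recipe.covariates:
        x = records[name].to_numpy(dtype=float)
        tf = recipe.transforms[name]
        if tf == "identity":
            cols.append(x)
            names.append(name)
        elif tf == "log1p":
            cols.append(np.log1p(x))
            names.append(f"log1p_{name}")
        else:
            B = rcs_basis(x, recipe.knots[name])
            cols.append(B[:, 0])
            names.append(name)
            for j in range(1, B.shape[1]):
                cols.append(B[:, j])
                names.append(f"{name}_rcs{j}")
    if recipe.include_landmark_terms:
        s = records["s"].to_numpy(dtype=float)
        cols += [s, s**2]
        names += ["s", "s_sq"]
        for name in recipe.interactions:
            x = records[name].to_numpy(dtype=float)
            if recipe.transforms[name] == "log1p":
                x = np.log1p(x)
            cols += [x * s, x * s**2]
            names += [f"{name}_x_s", f"{name}_x_s_sq"]
    return np.column_stack(cols), names


def build_design(records: pd.DataFrame, recipe: FeatureRecipe):
    """Apply a fitted recipe; returns (matrix, column names).

    Column order is deterministic: main effects (with spline columns right
    after their base column), then s, s_sq, then interaction products.
    Missing values are an error -- imputation happens upstream.
    """
    bad = [c for c in recipe.covariates
           if records[c].isna().any()]
    if bad:
        raise ValueError(f"missing values in columns {bad}; impute first")
    M, names = _raw_design(records, recipe)
    if recipe.standardize:
        for j, nm in enumerate(names):
            m, sd = recipe.stats.get(nm, (0.0, 1.0))
            M[:, j] = (M[:, j] - m) / sd
    return M, names


def default_covariate_spec(predictors) -> dict:
    """Transform plan per predictor kind: skewed labs are log1p-transformed,
    systolic blood pressure gets a 3-knot restricted cubic spline, everything
    else enters linearly."""
    spec = {}
    for p in predictors:
        if p.kind == "positive-skewed":
            spec[p.name] = "log1p"
        elif p.name == "systolic_bp":
            spec[p.name] = "rcs3"
        else:
            spec[p.name] = "identity"
    return spec


def select_interactions(stacked: pd.DataFrame, candidates, alpha=0.05,
                        covariate_spec=None):
    """Wald screening of covariate-by-landmark interactions.

    For each candidate covariate the cause-specific (infection cause) landmark
    supermodel is refitted with the (x*s, x*s^2) product terms added, and the
    two interaction coefficients are tested jointly with a 2-df Wald test
    using the model-based covariance (inverse observed information).  Returns
    the candidates with p < alpha.
    """
    from scipy import stats as sps

    from ._cox import CoxEngine, newton_solve

    if stacked["s"].nunique() < 2:
        raise ValueError("need at least two landmarks to test interactions")
    if covariate_spec is None:
        from .landmark import ID_COLS
        covariate_spec = {c: "identity" for c in stacked.columns
                          if c not in ID_COLS + ["s_sq"]}
    selected = []
    for cand in candidates:
        recipe = fit_recipe(stacked, covariate_spec,
                            include_landmark_terms=True, interactions=[cand])
        X, names = build_design(stacked, recipe)
        try:
            eng = CoxEngine(
                X,
                stacked["s"].to_numpy(dtype=float),
                stacked["T_lm"].to_numpy(dtype=float),
                (stacked["status"] == 1).to_numpy(),
                ties="efron",
            )
            beta, ll, g, H, _ = newton_solve(eng.loglik_grad_hess,
                                             np.zeros(X.shape[1]))
            cov = np.linalg.inv(-H)
        except (FitError, np.linalg.LinAlgError) as e:
            warnings.warn(f"interaction candidate {cand} skipped: {e}")
            continue
        ix = [names.index(f"{cand}_x_s"), names.index(f"{cand}_x_s_sq")]
        b = beta[ix]
        V = cov[np.ix_(ix, ix)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            warnings.warn(f"interaction candidate {cand}: singular Wald block")
            continue
        pval = float(sps.chi2.sf(stat, df=2))
        if pval < alpha:
            selected.append(cand)
    return selected
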