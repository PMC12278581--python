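"""Performance metrics and the repeated grouped-split validation harness.

Because there is no censoring, the 7-day infection outcome is fully observed
for every at-risk episode, so every metric treats the outcome as binary:
AUROC, calibration slope, observed/expected ratio, estimated calibration
index (ECI) and the scaled Brier score.  Dynamic models are evaluated per
landmark on the test episodes still at risk there.

The harness mirrors bedside validation: admissions (not episodes) are split
2:1 into train and test, the imputer / feature recipe / models are learned
on training admissions only, and the whole procedure is repeated with fresh
splits to get cross-repetition means and percentile intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import rankdata

from ._cox import FitError
from . import categorical, features, impute, landmark, rmtl as rmtl_mod, survival

STATIC_MODELS = ("cox", "cox_ac", "cs", "cs_ac", "fg", "fg_ac", "lr", "mlr")
DYNAMIC_MODELS = ("lm_cox", "lm_cs", "lm_fg", "fg_sep", "lm_lr", "lm_mlr",
                  "rmtl")
ALL_MODELS = STATIC_MODELS + DYNAMIC_MODELS

_CLIP = 1e-8


def _missing(reason):
    warnings.warn(reason)
    return np.nan


def auroc(y, p):
    """Mann-Whitney AUROC with ties counted 1/2; NaN if one class."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return _missing("AUROC undefined: single outcome class")
    r = rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def calibration_slope(y, p):
    """Slope of the logistic recalibration y ~ logit(p)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _CLIP, 1 - _CLIP)
    lp = logit(p)
    if np.std(lp) < 1e-12:
        return _missing("calibration slope undefined: constant predictions")
    try:
        fit = categorical.fit_logistic(lp[:, None], y)
    except FitError as e:
        return _missing(f"calibration slope fit failed: {e}")
    return float(fit.params.iloc[1])


def oe_ratio(y, p):
    """Observed event proportion over mean predicted risk."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.mean() <= 0:
        return _missing("O/E undefined: zero mean prediction")
    return float(y.mean() / p.mean())


def eci(y, p):
    """Estimated calibration index: mean squared distance between the
    predictions and a flexible observed-probability curve (logistic fit on a
    3-knot restricted cubic spline of logit(p))."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _CLIP, 1 - _CLIP)
    if len(y) < 50 or y.min() == y.max():
        return _missing("ECI undefined: too few records or one class")
    lp = logit(p)
    knots = np.quantile(lp, [0.10, 0.50, 0.90])
    if len(np.unique(knots)) < 3 or np.std(lp) < 1e-12:
        basis = lp[:, None] if np.std(lp) > 1e-12 else None
        if basis is None:
            return _missing("ECI undefined: constant predictions")
    else:
        basis = features.rcs_basis(lp, knots)
    try:
        fit = categorical.fit_logistic(basis, y)
    except FitError as e:
        return _missing(f"ECI calibration fit failed: {e}")
    curve = fit.predict_proba(basis)
    return float(np.mean((p - curve) ** 2))


def scaled_brier(y, p):
    """1 - Brier(model)/Brier(event-rate null); 1 is perfect, 0 matches the
    null model, negative is worse than the null."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    ybar = y.mean()
    null = np.mean((y - ybar) ** 2)
    if null <= 0:
        return _missing("scaled Brier undefined: zero-variance outcome")
    return float(1.0 - np.mean((y - p) ** 2) / null)


METRICS = {
    "auroc": auroc,
    "calibration_slope": calibration_slope,
    "oe_ratio": oe_ratio,
    "eci": eci,
    "scaled_brier": scaled_brier,
}


def compute_metrics(y, p) -> dict:
    mask = ~np.isnan(np.asarray(p, dtype=float))
    y = np.asarray(y, dtype=float)[mask]
    p = np.asarray(p, dtype=float)[mask]
    if len(y) == 0:
        return {m: np.nan for m in METRICS}
    return {m: f(y, p) for m, f in METRICS.items()}


def split_by_admission(admission_ids, fraction=2 / 3, seed=0):
    """Sample admissions (never episodes) into train/test.  The training
    count is round(n * fraction) (banker-free: floor(x + 0.5)).  Same seed,
    same split."""
    ids = np.unique(np.asarray(admission_ids))
    if len(ids) < 3:
        raise ValueError("need at least 3 admissions to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n_train = int(np.floor(len(ids) * fraction + 0.5))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class HarnessConfig:
    """Everything the repeated-split harness needs beyond the data."""

    prediction: landmark.PredictionConfig = field(
        default_factory=landmark.PredictionConfig)
    covariate_spec: dict = field(default_factory=dict)
    lookback: dict = field(default_factory=dict)
    imputer_schema: list = field(default_factory=list)
    n_repetitions: int = 100
    train_fraction: float = 2 / 3
    # interaction selection: "per-split" re-runs the Wald screening on each
    # training split; a list hard-codes the interaction set
    interaction_mode: object = "per-split"
    interaction_candidates: tuple = ()
    interaction_alpha: float = 0.05
    rmtl_config: rmtl_mod.RMTLConfig = field(default_factory=rmtl_mod.RMTLConfig)
    tune_rmtl: bool = True
    master_seed: int = 0


class PerformanceReport:
    """Tidy per-(model, landmark, repetition) metric records with
    cross-repetition summaries."""

    def __init__(self, records: pd.DataFrame, failures: list):
        self.records = records
        self.failures = failures

    def summary(self, interval="percentile") -> pd.DataFrame:
        """Mean and 95% interval per (model, landmark, metric).  interval:
        "percentile" (2.5-97.5 percentiles of repetition values) or
        "normal" (mean +- 1.96 sd)."""
        rows = []
        for (model, lm, metric), grp in self.records.groupby(
                ["model", "landmark", "metric"]):
            v = grp["value"].to_numpy(dtype=float)
            v = v[~np.isnan(v)]
            if len(v) == 0:
                rows.append((model, lm, metric, np.nan, np.nan, np.nan, 0))
                continue
            if interval == "percentile":
                lo, hi = np.percentile(v, [2.5, 97.5])
            else:
                lo = v.mean() - 1.96 * v.std()
                hi = v.mean() + 1.96 * v.std()
            rows.append((model, lm, metric, float(v.mean()), float(lo),
                         float(hi), len(v)))
        return pd.DataFrame(
            rows, columns=["model", "landmark", "metric", "mean", "lo",
                           "hi", "n_reps"])

    def to_csv(self, path):
        self.records.to_csv(path, index=False)


def _design_for(records, recipe):
    X, names = features.build_design(records, recipe)
    return X, names


def _fit_static_roster(roster, train0, test0, recipe, w):
    """Fit the requested static models on the landmark-0 table (full
    follow-up retained in T/D columns) and predict 7-day risk on test."""
    X_tr, names = _design_for(train0, recipe)
    X_te, _ = _design_for(test0, recipe)
    y_tr = train0["y7"].to_numpy()
    preds = {}
    fails = []

    def attempt(name, fn):
        try:
            preds[name] = fn()
        except (FitError, np.linalg.LinAlgError) as e:
            fails.append((name, "static", str(e)))
            preds[name] = np.full(len(test0), np.nan)

    full_records = pd.DataFrame({"T": train0["T_full"], "D": train0["D_full"]})

    if "cox" in roster:
        attempt("cox", lambda: survival.fit_cox(
            full_records, X_tr, names=names).predict_risk(X_te, w))
    if "cox_ac" in roster:
        attempt("cox_ac", lambda: survival.fit_cox(
            full_records, X_tr, names=names, admin_censor_at=w
        ).predict_risk(X_te, w))
    if "cs" in roster:
        attempt("cs", lambda: survival.fit_cause_specific(
            full_records, X_tr, names=names).predict_cif(X_te, 0.0, w))
    if "cs_ac" in roster:
        attempt("cs_ac", lambda: survival.fit_cause_specific(
            full_records, X_tr, names=names, admin_censor_at=w
        ).predict_cif(X_te, 0.0, w))
    if "fg" in roster or "fg_ac" in roster:
        cfg_inf = landmark.PredictionConfig(
            w=int(np.ceil(full_records["T"].max())) + 1, landmark_grid=(0,))
        cfg_ac = landmark.PredictionConfig(w=w, landmark_grid=(0,))

        def fg_table(cfg):
            t = train0.copy()
            t["T_lm"] = np.minimum(train0["T_full"], cfg.w)
            t["status"] = np.where(train0["T_full"] <= cfg.w,
                                   train0["D_full"], 0)
            covs = list(recipe.covariates)
            return landmark.finegray_transform(t, cfg, covariates=covs)

        if "fg" in roster:
            def _fg():
                cp = fg_table(cfg_inf)
                Xcp, nm = _design_for(cp, recipe)
                return survival.fit_finegray(cp, Xcp, names=nm).predict_risk(
                    X_te, w)
            attempt("fg", _fg)
        if "fg_ac" in roster:
            def _fgac():
                cp = fg_table(cfg_ac)
                Xcp, nm = _design_for(cp, recipe)
                return survival.fit_finegray(cp, Xcp, names=nm).predict_risk(
                    X_te, w)
            attempt("fg_ac", _fgac)
    if "lr" in roster:
        attempt("lr", lambda: categorical.fit_logistic(
            X_tr, y_tr, names=names).predict_proba(X_te))
    if "mlr" in roster:
        attempt("mlr", lambda: categorical.predict_category_risk(
            categorical.fit_multinomial(X_tr, train0["category"], names=names),
            X_te))
    return preds, fails


def _fit_dynamic_roster(roster, stacked_tr, stacked_te, per_lm_tr_cp, recipe,
                        hcfg: HarnessConfig, rep_seed):
    """Fit dynamic models on the stacked training data; return per-model
    dict s -> (y7 test, predictions) plus failure log."""
    pred_cfg = hcfg.prediction
    w = pred_cfg.w
    grid = [s for s in pred_cfg.landmark_grid
            if (stacked_te["s"] == s).any()]
    X_tr, names = _design_for(stacked_tr, recipe)
    preds = {}
    fails = []

    def test_block(s):
        blk = stacked_te[stacked_te["s"] == s]
        Xb, _ = _design_for(blk, recipe)
        return blk, Xb

    def attempt_supermodel(name, fit_fn, predict_fn):
        try:
            fit = fit_fn()
        except (FitError, np.linalg.LinAlgError) as e:
            fails.append((name, "fit", str(e)))
            preds[name] = {s: (test_block(s)[0]["y7"].to_numpy(),
                               np.full((stacked_te["s"] == s).sum(), np.nan))
                           for s in grid}
            return
        out = {}
        for s in grid:
            blk, Xb = test_block(s)
            try:
                out[s] = (blk["y7"].to_numpy(), predict_fn(fit, s, Xb))
            except (FitError, np.linalg.LinAlgError) as e:
                fails.append((name, f"predict s={s}", str(e)))
                out[s] = (blk["y7"].to_numpy(), np.full(len(blk), np.nan))
        preds[name] = out

    if "lm_cox" in roster:
        attempt_supermodel(
            "lm_cox",
            lambda: survival.fit_cox(stacked_tr, X_tr, names=names),
            lambda fit, s, Xb: fit.predict_risk(Xb, w, from_day=s),
        )
    if "lm_cs" in roster:
        attempt_supermodel(
            "lm_cs",
            lambda: survival.fit_cause_specific(stacked_tr, X_tr, names=names),
            lambda fit, s, Xb: fit.predict_cif(Xb, from_day=s, horizon=w),
        )
    if "lm_fg" in roster:
        def _fit_lmfg():
            cp = pd.concat(list(per_lm_tr_cp.values()), ignore_index=True)
            cp["s_sq"] = cp["s"].astype(float) ** 2
            Xcp, nm = _design_for(cp, recipe)
            return survival.fit_finegray(cp, Xcp, names=nm)
        attempt_supermodel(
            "lm_fg", _fit_lmfg,
            lambda fit, s, Xb: fit.predict_risk(Xb, w, from_day=s),
        )
    if "fg_sep" in roster:
        # per-landmark recipes without the landmark terms
        import dataclasses as _dc
        recipe_static = _dc.replace(recipe, include_landmark_terms=False,
                                    interactions=[])
        fits = survival.fit_finegray_per_landmark(
            per_lm_tr_cp,
            lambda cp: features.build_design(cp, recipe_static),
        )
        out = {}
        for s in grid:
            blk = stacked_te[stacked_te["s"] == s]
            Xb, _ = features.build_design(blk, recipe_static)
            f = fits.get(s)
            if isinstance(f, survival.FineGrayResults):
                out[s] = (blk["y7"].to_numpy(),
                          f.predict_risk(Xb, w, from_day=s))
            else:
                fails.append(("fg_sep", f"s={s}", str(f)))
                out[s] = (blk["y7"].to_numpy(), np.full(len(blk), np.nan))
        preds["fg_sep"] = out
        preds["fg_sep_fits"] = fits
    if "lm_lr" in roster:
        attempt_supermodel(
            "lm_lr",
            lambda: categorical.fit_logistic(
                X_tr, stacked_tr["y7"].to_numpy(), names=names),
            lambda fit, s, Xb: fit.predict_proba(Xb),
        )
    if "lm_mlr" in roster:
        attempt_supermodel(
            "lm_mlr",
            lambda: categorical.fit_multinomial(
                X_tr, stacked_tr["category"], names=names),
            lambda fit, s, Xb: categorical.predict_category_risk(fit, Xb),
        )
    if "rmtl" in roster:
        import dataclasses as _dc
        recipe_task = _dc.replace(recipe, include_landmark_terms=False,
                                  interactions=[])
        tasks = []
        for s in pred_cfg.landmark_grid:
            blk = stacked_tr[stacked_tr["s"] == s]
            if len(blk) == 0:
                continue
            Xb, _ = features.build_design(blk, recipe_task)
            tasks.append(rmtl_mod.TaskData(
                s, Xb, blk["y7"].to_numpy(dtype=float),
                blk["admission_id"].to_numpy()))
        try:
            rcfg = _dc.replace(hcfg.rmtl_config, seed=rep_seed)
            if hcfg.tune_rmtl:
                lam = rmtl_mod.tune_lambda(tasks, rcfg)
                rcfg = _dc.replace(rcfg, lambda_task=lam)
            fit = rmtl_mod.fit_rmtl(tasks, rcfg)
            out = {}
            for s in grid:
                blk = stacked_te[stacked_te["s"] == s]
                Xb, _ = features.build_design(blk, recipe_task)
                out[s] = (blk["y7"].to_numpy(), fit.predict(s, Xb))
            preds["rmtl"] = out
        except (FitError, np.linalg.LinAlgError) as e:
            fails.append(("rmtl", "fit", str(e)))
            preds["rmtl"] = {s: (stacked_te[stacked_te["s"] == s]["y7"].to_numpy(),
                                 np.full((stacked_te["s"] == s).sum(), np.nan))
                             for s in grid}
    return preds, fails


def repeated_split_evaluate(episodes, trajectories, roster, hcfg: HarnessConfig
                            ) -> PerformanceReport:
    """The full repeated-split validation loop.

    Per repetition: grouped 2:1 admission split -> imputer fitted on the
    training rows of the stacked landmark dataset -> both sides imputed ->
    recipe and models fitted on train -> 7-day infection risks predicted on
    test (per landmark for dynamic models) -> metrics.  Fit failures are
    logged, not fatal.
    """
    unknown = [m for m in roster if m not in ALL_MODELS]
    if unknown:
        raise ValueError(f"unknown models {unknown}; allowed {ALL_MODELS}")
    static_roster = [m for m in roster if m in STATIC_MODELS]
    dynamic_roster = [m for m in roster if m in DYNAMIC_MODELS]
    pred_cfg = hcfg.prediction

    # stacked dataset for the whole cohort (built once; splits subset it)
    stacked = landmark.build_stacked_dataset(
        episodes, trajectories, pred_cfg,
        covariates=list(hcfg.covariate_spec), lookback=hcfg.lookback)
    # full follow-up columns for the static (non-administratively-censored)
    # fits at landmark 0
    tmap = episodes.set_index("episode_id")
    stacked["T_full"] = stacked["episode_id"].map(tmap["T"])
    stacked["D_full"] = stacked["episode_id"].map(tmap["D"])

    records = []
    failures = []
    rng = np.random.default_rng(hcfg.master_seed)
    rep_seeds = rng.integers(0, 2**31 - 1, hcfg.n_repetitions)
    for rep in range(hcfg.n_repetitions):
        rep_seed = int(rep_seeds[rep])
        train_ids, test_ids = split_by_admission(
            episodes["admission_id"], fraction=hcfg.train_fraction,
            seed=rep_seed)
        tr = stacked[stacked["admission_id"].isin(train_ids)].reset_index(drop=True)
        te = stacked[stacked["admission_id"].isin(test_ids)].reset_index(drop=True)

        if hcfg.imputer_schema:
            imputer = impute.fit_imputer(tr, hcfg.imputer_schema,
                                         seed=rep_seed)
            tr = imputer.transform(tr)
            te = imputer.transform(te)

        if hcfg.interaction_mode == "per-split" and hcfg.interaction_candidates \
                and dynamic_roster:
            try:
                selected = features.select_interactions(
                    tr, hcfg.interaction_candidates,
                    alpha=hcfg.interaction_alpha,
                    covariate_spec=hcfg.covariate_spec)
            except (FitError, ValueError) as e:
                failures.append((rep, "interaction-selection", str(e)))
                selected = []
        elif isinstance(hcfg.interaction_mode, (list, tuple)):
            selected = list(hcfg.interaction_mode)
        else:
            selected = []

        if static_roster:
            recipe0 = features.fit_recipe(
                tr[tr["s"] == 0], hcfg.covariate_spec,
                include_landmark_terms=False)
            tr0 = tr[tr["s"] == 0].reset_index(drop=True)
            te0 = te[te["s"] == 0].reset_index(drop=True)
            preds, fails = _fit_static_roster(static_roster, tr0, te0,
                                              recipe0, pred_cfg.w)
            failures += [(rep,) + f for f in fails]
            y0 = te0["y7"].to_numpy()
            for m in static_roster:
                for metric, val in compute_metrics(y0, preds[m]).items():
                    records.append((m, "static", rep, metric, val))

        if dynamic_roster:
            recipe = features.fit_recipe(
                tr, hcfg.covariate_spec, include_landmark_terms=True,
                interactions=selected)
            need_cp = {"lm_fg", "fg_sep"} & set(dynamic_roster)
            per_lm_cp = {}
            if need_cp:
                for s in pred_cfg.landmark_grid:
                    blk = tr[tr["s"] == s]
                    if len(blk) == 0:
                        continue
                    per_lm_cp[s] = landmark.finegray_transform(
                        blk, pred_cfg, covariates=recipe.covariates)
            preds, fails = _fit_dynamic_roster(
                dynamic_roster, tr, te, per_lm_cp, recipe, hcfg, rep_seed)
            failures += [(rep,) + f for f in fails]
            for m in dynamic_roster:
                for s, (yb, pb) in preds[m].items():
                    for metric, val in compute_metrics(yb, pb).items():
                        records.append((m, s, rep, metric, val))

    df = pd.DataFrame(records,
                      columns=["model", "landmark", "repetition", "metric",
                               "value"])
    return PerformanceReport(df, failures)
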