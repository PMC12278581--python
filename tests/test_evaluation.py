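"""Performance metrics and the repeated grouped-split harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import landmarkcr as L
from landmarkcr.evaluation import (
    ALL_MODELS, DYNAMIC_MODELS, STATIC_MODELS, HarnessConfig, auroc,
    calibration_slope, eci, oe_ratio, repeated_split_evaluate, scaled_brier,
    split_by_admission,
)


def test_auroc_examples_and_brute_force_oracle():
    assert auroc(np.array([1, 0]), np.array([0.9, 0.1])) == 1.0
    assert auroc(np.array([1, 0, 1, 0]), np.full(4, 0.3)) == 0.5
    rng = np.random.default_rng(0)
    y = (rng.random(200) < 0.3).astype(float)
    p = np.round(rng.random(200), 2)  # coarse grid forces ties
    pairs = 0.0
    n_pairs = 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            n_pairs += 1
            pairs += (p[i] > p[j]) + 0.5 * (p[i] == p[j])
    assert abs(auroc(y, p) - pairs / n_pairs) < 1e-12


def test_auroc_single_class_missing():
    with pytest.warns(UserWarning):
        assert np.isnan(auroc(np.ones(5), np.random.rand(5)))


def test_calibration_slope_overconfident_halves():
    rng = np.random.default_rng(1)
    n = 100_000
    p = expit(rng.normal(-2, 1, n))
    y = (rng.random(n) < p).astype(float)
    assert calibration_slope(y, p) == pytest.approx(1.0, abs=0.05)
    p_over = expit(2 * logit(p))
    assert calibration_slope(y, p_over) == pytest.approx(0.5, abs=0.05)
    with pytest.warns(UserWarning):
        assert np.isnan(calibration_slope(y[:100], np.full(100, 0.3)))


def test_oe_ratio_arithmetic():
    y = np.zeros(100)
    y[:2] = 1  # mean 0.02
    assert oe_ratio(y, np.full(100, 0.04)) == pytest.approx(0.5)
    assert oe_ratio(y, y) == 1.0
    with pytest.warns(UserWarning):
        assert np.isnan(oe_ratio(y, np.zeros(100)))


def test_eci_limits():
    rng = np.random.default_rng(2)
    n = 100_000
    p = expit(rng.normal(-2.5, 1, n))
    y = (rng.random(n) < p).astype(float)
    assert eci(y, p) < 1e-4
    delta = 0.02
    assert eci(y, np.clip(p + delta, 0, 1)) == pytest.approx(delta**2,
                                                             rel=0.35)
    assert eci(y, p) >= 0


def test_scaled_brier_examples():
    y = np.array([1.0, 0, 0, 0])
    assert scaled_brier(y, np.full(4, y.mean())) == pytest.approx(0.0)
    assert scaled_brier(y, y) == 1.0
    # worked example: Brier 0 vs null Brier 0.1875
    assert np.mean((y - y.mean()) ** 2) == pytest.approx(0.1875)
    with pytest.warns(UserWarning):
        assert np.isnan(scaled_brier(np.zeros(4), np.zeros(4)))


def test_split_by_admission_properties():
    ids = np.repeat(np.arange(9), 2)
    train, test = split_by_admission(ids, seed=0)
    assert len(train) == 6 and len(test) == 3
    for seed in range(100):
        tr, te = split_by_admission(ids, seed=seed)
        assert set(tr).isdisjoint(te)
        assert set(tr) | set(te) == set(range(9))
    t1 = split_by_admission(ids, seed=5)
    t2 = split_by_admission(ids, seed=5)
    np.testing.assert_array_equal(t1[0], t2[0])


def test_unknown_model_name_rejected(small_cohort):
    _, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    with pytest.raises(ValueError, match="unknown"):
        repeated_split_evaluate(episodes, traj, ["nonsense"], HarnessConfig())


def _tiny_harness_cfg(cfg, grid, n_reps, with_imputer=False, **kw):
    import landmarkcr.impute as imp
    return HarnessConfig(
        prediction=L.landmark.PredictionConfig(w=7, landmark_grid=grid),
        covariate_spec=L.features.default_covariate_spec(cfg.predictors),
        lookback={p.name: p.lookback for p in cfg.predictors},
        imputer_schema=imp.schema_from_predictors(cfg.predictors)
        if with_imputer else [],
        n_repetitions=n_reps,
        interaction_mode=[],
        rmtl_config=L.rmtl.RMTLConfig(lambda_grid=(0.1,)),
        master_seed=7,
        **kw,
    )


def test_full_roster_report_contains_8_static_and_7_dynamic_keys(small_cohort):
    cfg, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    hcfg = _tiny_harness_cfg(cfg, tuple(range(0, 4)), 1)
    report = repeated_split_evaluate(episodes, traj, list(ALL_MODELS), hcfg)
    models = set(report.records["model"])
    assert models == set(ALL_MODELS)
    assert len(STATIC_MODELS) == 8 and len(DYNAMIC_MODELS) == 7
    static_lms = set(report.records.query("model=='lr'")["landmark"])
    assert static_lms == {"static"}
    dyn_lms = set(report.records.query("model=='lm_lr'")["landmark"])
    assert dyn_lms == {0, 1, 2, 3}


def test_highly_informative_predictor_gives_near_perfect_auroc():
    """A single predictor that carries almost all of the outcome signal
    yields near-perfect discrimination in every repetition.  (A literally
    deterministic predictor would separate the training data completely,
    which the logistic fitter reports as a failure rather than fitting
    silently, so the risk is made steep but stochastic.)"""
    rng = np.random.default_rng(3)
    n = 800
    latent = rng.random(n) < 0.2
    risk = np.where(latent, 0.9, 0.005)
    y_event = rng.random(n) < risk
    episodes = pd.DataFrame({
        "episode_id": np.arange(n), "admission_id": np.arange(n),
        "onset_day": 0,
        "T": np.where(y_event, 3.0, 20.0),
        "D": np.where(y_event, 1, 3),
    })
    days = []
    for e in episodes.itertuples():
        for d in range(int(min(e.T, 20)) + 1):
            days.append((e.episode_id, d,
                         5.0 if latent[e.episode_id] else -5.0, rng.normal()))
    traj = pd.DataFrame(days, columns=["episode_id", "day", "oracle", "noise"])
    hcfg = HarnessConfig(
        prediction=L.landmark.PredictionConfig(w=7, landmark_grid=(0,)),
        covariate_spec={"oracle": "identity", "noise": "identity"},
        n_repetitions=2, interaction_mode=[], master_seed=1,
    )
    report = repeated_split_evaluate(episodes, traj, ["lr"], hcfg)
    vals = report.records.query("metric=='auroc'")["value"]
    assert (vals > 0.9).all()


def test_pure_noise_auroc_near_half(small_cohort):
    cfg, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    rng = np.random.default_rng(4)
    noise_traj = traj[["episode_id", "day"]].copy()
    noise_traj["n1"] = rng.normal(size=len(traj))
    noise_traj["n2"] = rng.normal(size=len(traj))
    hcfg = HarnessConfig(
        prediction=L.landmark.PredictionConfig(w=7, landmark_grid=(0,)),
        covariate_spec={"n1": "identity", "n2": "identity"},
        n_repetitions=20, interaction_mode=[], master_seed=2,
    )
    report = repeated_split_evaluate(episodes, noise_traj, ["lr"], hcfg)
    mean_auc = report.records.query("metric=='auroc'")["value"].mean()
    assert abs(mean_auc - 0.5) < 0.03


def test_summary_invariant_to_repetition_order(small_cohort):
    cfg, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    hcfg = _tiny_harness_cfg(cfg, (0, 1), 3)
    report = repeated_split_evaluate(episodes, traj, ["lr", "lm_lr"], hcfg)
    s1 = report.summary()
    shuffled = report.records.sample(frac=1, random_state=0)
    s2 = type(report)(shuffled, report.failures).summary()
    pd.testing.assert_frame_equal(
        s1.sort_values(["model", "landmark", "metric"]).reset_index(drop=True),
        s2.sort_values(["model", "landmark", "metric"]).reset_index(drop=True))


def test_no_admission_spans_train_and_test(small_cohort):
    """Grouped splitting: across repetitions no admission contributes to
    both sides (checked through the split helper the harness uses)."""
    _, episodes = small_cohort[0], small_cohort[1]
    for seed in range(50):
        tr, te = split_by_admission(episodes["admission_id"], seed=seed)
        assert set(tr).isdisjoint(set(te))


def test_identical_master_seed_identical_report(small_cohort):
    cfg, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[3]
    hcfg = _tiny_harness_cfg(cfg, (0, 1), 2, with_imputer=True)
    r1 = repeated_split_evaluate(episodes, traj, ["lr", "lm_lr"], hcfg)
    r2 = repeated_split_evaluate(episodes, traj, ["lr", "lm_lr"], hcfg)
    pd.testing.assert_frame_equal(r1.records, r2.records)
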