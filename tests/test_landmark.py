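"""Landmark dataset construction, stacking and the counting-process
transform with IPCW weights."""

import numpy as np
import pandas as pd
import pytest

import landmarkcr as L
from landmarkcr.landmark import (
    PredictionConfig, at_risk, build_landmark_dataset, build_stacked_dataset,
    finegray_transform, stack_landmarks,
)


@pytest.fixture()
def pc():
    return PredictionConfig(w=7, landmark_grid=tuple(range(0, 11)))


def test_at_risk_strict_boundary(toy_episodes):
    assert 0 in at_risk(toy_episodes, 9)["episode_id"].values
    assert 0 not in at_risk(toy_episodes, 10)["episode_id"].values
    assert len(at_risk(toy_episodes, 0)) == len(toy_episodes)


def test_episode_appears_in_exactly_T_landmark_sets(toy_episodes):
    counts = sum((at_risk(toy_episodes, s)["episode_id"] == 0).sum()
                 for s in range(31))
    assert counts == 10  # T=10 -> present at s=0..9


@pytest.mark.parametrize("T,D,s,exp_Tlm,exp_status,exp_y7,exp_cat", [
    (10.0, 1, 4, 10.0, 1, 1, "clabsi"),
    (10.0, 1, 2, 9.0, 0, 0, "none"),
    (6.0, 3, 1, 6.0, 3, 0, "discharge"),
])
def test_landmark_record_boundaries(toy_episodes, toy_trajectories,
                                    T, D, s, exp_Tlm, exp_status, exp_y7,
                                    exp_cat, pc):
    eps = toy_episodes.copy()
    eps.loc[0, ["T", "D"]] = [T, D]
    lm = build_landmark_dataset(eps, toy_trajectories, s, pc)
    row = lm[lm["episode_id"] == 0].iloc[0]
    assert row["T_lm"] == exp_Tlm
    assert row["status"] == exp_status
    assert row["y7"] == exp_y7
    assert row["category"] == exp_cat


def test_status_conservation(small_cohort, pc):
    _, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    for s in (0, 3, 8):
        lm = build_landmark_dataset(episodes, traj, s, pc)
        assert len(lm) == (episodes["T"] > s).sum()
        assert lm["status"].isin([0, 1, 2, 3]).all()
        assert ((lm["status"] == 1) == (lm["y7"] == 1)).all()
        assert ((lm["status"] == 0) == (lm["category"] == "none")).all()


def test_y7_prevalence_matches_direct_cohort_computation(small_cohort, pc):
    _, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    for s in (0, 5):
        lm = build_landmark_dataset(episodes, traj, s, pc)
        direct = ((episodes["T"] <= s + pc.w) & (episodes["D"] == 1)
                  & (episodes["T"] > s)).sum() / (episodes["T"] > s).sum()
        assert lm["y7"].mean() == pytest.approx(direct, abs=1e-12)


def test_stacking_counts_and_columns(small_cohort, pc):
    _, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    tables = [build_landmark_dataset(episodes, traj, s, pc)
              for s in pc.landmark_grid]
    stacked = stack_landmarks(tables, pc)
    assert len(stacked) == sum(len(t) for t in tables)
    assert "s_sq" in stacked.columns
    sizes = stacked.groupby("s").size()
    assert (sizes.sort_index().diff().dropna() <= 0).all()  # shrinking risk sets
    # one record per (episode, s)
    assert not stacked.duplicated(["episode_id", "s"]).any()


def test_stack_single_landmark_is_input_plus_s_columns(toy_episodes,
                                                       toy_trajectories):
    cfg = PredictionConfig(w=7, landmark_grid=(0,))
    t0 = build_landmark_dataset(toy_episodes, toy_trajectories, 0, cfg)
    stacked = stack_landmarks([t0], cfg)
    assert len(stacked) == len(t0)
    assert (stacked["s_sq"] == 0).all()


def test_empty_risk_set_warns_not_raises(toy_episodes, toy_trajectories, pc):
    with pytest.warns(UserWarning, match="empty risk set"):
        lm = build_landmark_dataset(toy_episodes, toy_trajectories, 50, pc)
    assert lm.empty


def test_schema_mismatch_raises(toy_episodes, toy_trajectories, pc):
    t0 = build_landmark_dataset(toy_episodes, toy_trajectories, 0, pc)
    t1 = build_landmark_dataset(toy_episodes, toy_trajectories, 1, pc)
    t1 = t1.drop(columns=["x"])
    with pytest.raises(ValueError, match="schema"):
        stack_landmarks([t0, t1], pc)


def test_seven_day_lookback_flag_is_rolling_or(small_cohort, pc):
    cfg, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    lookback = {p.name: p.lookback for p in cfg.predictors}
    s = 8
    lm = build_landmark_dataset(episodes, traj, s, pc, lookback=lookback)
    window = traj[(traj["day"] >= s - 6) & (traj["day"] <= s)]
    expected = window.groupby("episode_id")["tpn"].max()
    got = lm.set_index("episode_id")["tpn"]
    assert (got == expected.reindex(got.index)).all()


# --- counting-process transform ------------------------------------------


def test_finegray_transform_examples(pc):
    lm = pd.DataFrame({
        "episode_id": [0, 1], "admission_id": [0, 1], "s": 0.0,
        "T_lm": [3.0, 2.0], "status": [1, 2], "y7": [1, 0],
        "category": ["clabsi", "death"], "z": [0.5, -0.5],
    })
    cp = finegray_transform(lm, PredictionConfig(w=7, landmark_grid=(0,)),
                            covariates=["z"])
    clabsi = cp[cp["episode_id"] == 0].iloc[0]
    assert (clabsi["start"], clabsi["stop"], clabsi["event"],
            clabsi["weight"]) == (0.0, 3.0, 1, 1.0)
    death = cp[cp["episode_id"] == 1].iloc[0]
    # competing event stays in the subdistribution risk set until s+w
    assert (death["start"], death["stop"], death["event"],
            death["weight"]) == (0.0, 7.0, 0, 1.0)


def test_finegray_admin_censored_record(pc):
    lm = pd.DataFrame({
        "episode_id": [0], "admission_id": [0], "s": 0.0, "T_lm": [7.0],
        "status": [0], "y7": [0], "category": ["none"], "z": [0.0],
    })
    cp = finegray_transform(lm, PredictionConfig(w=7, landmark_grid=(0,)),
                            covariates=["z"])
    assert (cp.iloc[0]["stop"], cp.iloc[0]["event"], cp.iloc[0]["weight"]) \
        == (7.0, 0, 1.0)


def test_finegray_person_time_matches_brute_force(pc):
    """Total subdistribution risk-set person-time equals direct enumeration:
    cause-1 episodes contribute T - s, everyone else w."""
    lm = pd.DataFrame({
        "episode_id": range(5), "admission_id": range(5), "s": 2.0,
        "T_lm": [4.0, 9.0, 6.0, 9.0, 5.0], "status": [1, 0, 2, 0, 3],
        "y7": [1, 0, 0, 0, 0],
        "category": ["clabsi", "none", "death", "none", "discharge"],
        "z": np.linspace(-1, 1, 5),
    })
    cfg = PredictionConfig(w=7, landmark_grid=(2,))
    cp = finegray_transform(lm, cfg, covariates=["z"])
    person_time = (cp["stop"] - cp["start"]).sum()
    brute = sum(
        (row.T_lm - 2.0) if row.status == 1 else 7.0
        for row in lm.itertuples()
    )
    assert person_time == pytest.approx(brute, abs=1e-12)


def test_finegray_all_weights_one_under_admin_censoring(small_cohort, pc):
    _, episodes, traj = small_cohort[0], small_cohort[1], small_cohort[2]
    for s in (0, 4):
        lm = build_landmark_dataset(episodes, traj, s, pc)
        cp = finegray_transform(lm, pc)
        assert (cp["weight"] == 1.0).all()
        # conservation: one record per episode when censoring is admin-only
        assert len(cp) == len(lm)


def test_prediction_config_validation():
    with pytest.raises(ValueError):
        PredictionConfig(w=0)
    with pytest.raises(ValueError):
        PredictionConfig(w=7, landmark_grid=(3, 2))
    assert PredictionConfig().w == 7
    assert PredictionConfig().landmark_grid == tuple(range(31))
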