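import numpy as np
import pandas as pd
import pytest

import landmarkcr as L


@pytest.fixture(scope="session")
def small_cohort():
    """Default 8-predictor cohort, 800 admissions, with missingness."""
    cfg = L.simulate.default_config(800, seed=42)
    episodes, traj, truth = L.simulate.generate_cohort(cfg)
    traj_miss = L.simulate.apply_missingness(traj, cfg)
    return cfg, episodes, traj, traj_miss, truth


@pytest.fixture(scope="session")
def constant_hazard_cohort():
    """No covariate effects, constant rates 0.1/0.1/0 per day, n=5000."""
    cfg = L.simulate.SimulationConfig(
        n_admissions=5000, p_multi_episode=0.0, max_follow_up=60,
        predictors=[L.simulate.PredictorSpec("z", "gaussian", mean=0.0, sd=1.0)],
        true_betas=np.zeros((3, 1)),
        baseline_hazards=(0.1, 0.1, 0.0), seed=3,
    )
    episodes, traj, truth = L.simulate.generate_cohort(cfg)
    return cfg, episodes, traj, truth


@pytest.fixture()
def toy_episodes():
    """Five hand-written episodes covering all causes and the boundaries."""
    return pd.DataFrame({
        "episode_id": [0, 1, 2, 3, 4],
        "admission_id": [0, 1, 2, 3, 3],
        "onset_day": [0, 0, 0, 0, 2],
        "T": [10.0, 6.0, 3.0, 2.0, 15.0],
        "D": [1, 3, 1, 2, 3],
    })


@pytest.fixture()
def toy_trajectories(toy_episodes):
    rows = []
    for _, e in toy_episodes.iterrows():
        for day in range(int(min(e["T"], 60)) + 1):
            rows.append({"episode_id": e["episode_id"], "day": day,
                         "x": 0.1 * day + e["episode_id"],
                         "flag": float(e["episode_id"] % 2)})
    return pd.DataFrame(rows)
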