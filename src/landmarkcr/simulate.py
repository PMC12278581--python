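"""Synthetic EHR cohort generator for catheter-episode risk prediction.

Emulates a hospital cohort of admissions carrying central-venous-catheter
episodes, where each episode-day can end in one of three mutually exclusive
terminal events: (1) a catheter-related bloodstream infection, (2) death or
the start of palliative care, or (3) discharge / prolonged catheter removal.
There is no random censoring: every episode ends in one of the three causes.

Time is discrete at the daily resolution at which wards chart their data.
Cause-specific hazards are continuous-time rates held constant within each
day, h_k(s|Z) = b_k(s) * exp(beta_k' Z(s)); conditional on being at risk at
the start of day s+1 the probability of any event during that day is
1 - exp(-H) with H = h_1 + h_2 + h_3, split among causes proportionally to
h_k.  This embedding keeps every per-day probability valid for any rates and
makes constant-rate cohorts agree exactly with the closed-form competing
risks cumulative incidence (lam_k/H) * (1 - exp(-H t)).

Covariate dynamics: binary time-varying flags follow 2-state Markov chains,
continuous predictors follow stationary AR(1) processes (on the log1p scale
for right-skewed labs), static flags are drawn once per episode.  The hazard
linear predictor uses each predictor on its model scale: raw value for
binaries and gaussian vitals, log1p for skewed labs, centered so that the
baseline rates are interpretable at a typical patient.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CAUSES = {1: "clabsi", 2: "death", 3: "discharge"}

_KINDS = ("binary-static", "binary-timevarying", "positive-skewed", "gaussian")


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class PredictorSpec:
    """One predictor and its dynamics.

    kind:
        binary-static      drawn once per episode, constant over days
        binary-timevarying 2-state Markov chain (p_on: 0->1, p_off: 1->0)
        gaussian           stationary AR(1), mean/sd on the raw scale
        positive-skewed    value = expm1 of a stationary AR(1) gaussian with
                           the given mean/sd (so log1p(value) is gaussian)
    lookback: "last" (current day) or "7day-any" (rolling OR over 7 days),
        mirroring how medication flags are charted.
    missing_rate: marginal daily probability that the value is unrecorded
        (continuous predictors only; flags are always observed).
    miss_on / miss_delta: MAR shift — log-odds of missingness changes by
        miss_delta on days where the named binary predictor equals 1.
    """

    name: str
    kind: str
    p_init: float = 0.3
    p_on: float = 0.05
    p_off: float = 0.05
    mean: float = 0.0
    sd: float = 1.0
    ar1: float = 0.8
    lookback: str = "last"
    missing_rate: float = 0.0
    miss_on: str | None = None
    miss_delta: float = 0.0

    def validate(self):
        if self.kind not in _KINDS:
            raise ConfigError(f"predictor {self.name}: unknown kind {self.kind!r}")
        for f in ("p_init", "p_on", "p_off", "missing_rate"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"predictor {self.name}: {f}={v} not in [0,1]")
        if not -1.0 < self.ar1 < 1.0:
            raise ConfigError(f"predictor {self.name}: ar1 must be in (-1,1)")
        if self.sd < 0:
            raise ConfigError(f"predictor {self.name}: sd must be >= 0")
        if self.lookback not in ("last", "7day-any"):
            raise ConfigError(f"predictor {self.name}: lookback {self.lookback!r}")
        if self.missing_rate > 0 and self.kind.startswith("binary"):
            raise ConfigError(
                f"predictor {self.name}: binary predictors are never missing"
            )


@dataclass
class InteractionSpec:
    """Cause-1 log hazard ratio of `predictor` drifts with landmark day s:
    beta(s) = beta + linear * s + quadratic * s**2."""

    predictor: str
    linear: float = 0.0
    quadratic: float = 0.0


@dataclass
class SimulationConfig:
    n_admissions: int = 1000
    p_multi_episode: float = 0.1
    max_follow_up: int = 60
    horizon: int = 7
    predictors: list[PredictorSpec] = field(default_factory=list)
    # 3 x p matrix of cause-specific log hazard ratios (rows: clabsi, death,
    # discharge; columns follow `predictors` order)
    true_betas: np.ndarray | None = None
    # per-cause baseline rates per day: scalars or arrays of length
    # max_follow_up indexed by day-since-onset
    baseline_hazards: tuple = (0.005, 0.01, 0.08)
    interactions: list[InteractionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.true_betas is not None:
            self.true_betas = np.asarray(self.true_betas, dtype=float)

    @property
    def predictor_names(self):
        return [p.name for p in self.predictors]

    def validate(self):
        if self.n_admissions <= 0:
            raise ConfigError("n_admissions must be positive")
        if not 0.0 <= self.p_multi_episode <= 1.0:
            raise ConfigError("p_multi_episode not in [0,1]")
        if self.max_follow_up <= 0:
            raise ConfigError("max_follow_up must be positive")
        if self.horizon <= 0:
            raise ConfigError("horizon must be positive")
        if not self.predictors:
            raise ConfigError("predictors must be non-empty")
        names = self.predictor_names
        if len(set(names)) != len(names):
            raise ConfigError("predictors: duplicate names")
        for p in self.predictors:
            p.validate()
            if p.miss_on is not None and p.miss_on not in names:
                raise ConfigError(f"predictor {p.name}: miss_on {p.miss_on!r} unknown")
        if self.true_betas is None:
            raise ConfigError("true_betas is required")
        if self.true_betas.shape != (3, len(self.predictors)):
            raise ConfigError(
                f"true_betas shape {self.true_betas.shape} != (3, {len(self.predictors)})"
            )
        for k, b in enumerate(self.baseline_hazards):
            arr = np.asarray(b, dtype=float)
            if np.any(arr < 0):
                raise ConfigError(f"baseline_hazards[{k}] has negative values")
            if arr.ndim not in (0, 1):
                raise ConfigError(f"baseline_hazards[{k}] must be scalar or 1-d")
        for ia in self.interactions:
            if ia.predictor not in names:
                raise ConfigError(f"interactions: unknown predictor {ia.predictor!r}")

    def baseline_at(self, cause_idx, day):
        """Baseline rate of cause `cause_idx` (0-based) on landmark day `day`."""
        b = np.asarray(self.baseline_hazards[cause_idx], dtype=float)
        if b.ndim == 0:
            return np.full(np.shape(day), float(b)) if np.ndim(day) else float(b)
        day = np.minimum(day, len(b) - 1)
        return b[day]

    def to_json(self):
        d = dataclasses.asdict(self)
        d["true_betas"] = self.true_betas.tolist()
        d["baseline_hazards"] = [np.asarray(b).tolist() for b in self.baseline_hazards]
        return json.dumps(d, indent=2)


@dataclass
class GeneratorTruth:
    """Oracle payload: realized config plus latent (uncensored) covariate
    paths and the per-day true cause-specific rates used to draw events."""

    config: SimulationConfig
    model_scale_paths: np.ndarray  # (n_episodes, max_follow_up+1, p)
    hazard_paths: np.ndarray       # (n_episodes, max_follow_up, 3)
    linear_predictors: np.ndarray  # (n_episodes, max_follow_up, 3)


def default_config(n_admissions=1000, seed=0, **overrides) -> SimulationConfig:
    """Desk-scale 8-predictor cohort with the qualitative structure of a
    catheter cohort: low infection incidence (~1-3% within 7 days), a strong
    discharge hazard and a smaller death hazard, ICU stays that raise the
    infection and death hazards but delay discharge.
    """
    preds = [
        PredictorSpec("icu", "binary-timevarying", p_init=0.25, p_on=0.02, p_off=0.05),
        PredictorSpec("cvc", "binary-timevarying", p_init=0.60, p_on=0.03, p_off=0.03),
        PredictorSpec("tpn", "binary-timevarying", p_init=0.15, p_on=0.02, p_off=0.08,
                      lookback="7day-any"),
        PredictorSpec("tumor", "binary-static", p_init=0.30),
        PredictorSpec("admission_from_home", "binary-static", p_init=0.80),
        PredictorSpec("temperature", "gaussian", mean=37.0, sd=0.7, ar1=0.85,
                      missing_rate=0.10, miss_on="icu", miss_delta=-0.5),
        PredictorSpec("crp", "positive-skewed", mean=3.0, sd=0.9, ar1=0.95,
                      missing_rate=0.25, miss_on="icu", miss_delta=-0.5),
        PredictorSpec("wbc", "positive-skewed", mean=2.1, sd=0.5, ar1=0.92,
                      missing_rate=0.20, miss_on="icu", miss_delta=-0.5),
    ]
    # rows: clabsi, death, discharge; columns follow `preds`.  Deliberately,
    # some covariates drive mainly the competing events (tumor and admission
    # source shift death/discharge, hence time on the line, with little or no
    # direct infection-hazard effect): exposure-driven infection risk is what
    # separates models that account for competing events from those that do
    # not.
    betas = np.array(
        [
            # icu   cvc   tpn  tumor home   temp   crp   wbc
            [0.50, 0.50, 0.40, 0.00, 0.00, 0.40, 0.35, 0.20],  # clabsi
            [0.80, 0.10, 0.10, 0.50, -0.30, 0.10, 0.30, 0.10],  # death
            [-1.10, -0.35, -0.35, -0.50, 0.35, -0.15, -0.25, -0.05],  # discharge
        ]
    )
    # the discharge/removal hazard is front-loaded: many catheters come out
    # within the first week, a minority of long-stay patients keep theirs
    days = np.arange(60)
    discharge_base = 0.20 * np.exp(-days / 7.0) + 0.035
    cfg = SimulationConfig(
        n_admissions=n_admissions,
        p_multi_episode=0.10,
        max_follow_up=60,
        predictors=preds,
        true_betas=betas,
        baseline_hazards=(0.003, 0.012, discharge_base),
        seed=seed,
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ConfigError(f"unknown config field {k!r}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def table1_config(n_admissions=1000, seed=0) -> SimulationConfig:
    """21-predictor preset mirroring the full routinely-charted covariate
    set (catheter type/location flags, medication flags with 7-day lookback,
    infection history, comorbidities, ward and care flags, vitals, labs,
    admission source)."""
    B = PredictorSpec
    preds = [
        B("cvc", "binary-timevarying", p_init=0.55, p_on=0.05, p_off=0.05),
        B("port_a_cath", "binary-timevarying", p_init=0.15, p_on=0.01, p_off=0.02),
        B("tunneled_cvc", "binary-timevarying", p_init=0.10, p_on=0.01, p_off=0.02),
        B("picc", "binary-timevarying", p_init=0.12, p_on=0.01, p_off=0.02),
        B("subclavian", "binary-timevarying", p_init=0.25, p_on=0.01, p_off=0.02),
        B("jugular", "binary-timevarying", p_init=0.30, p_on=0.02, p_off=0.03),
        B("tpn", "binary-timevarying", p_init=0.15, p_on=0.03, p_off=0.15,
          lookback="7day-any"),
        B("antibacterials", "binary-timevarying", p_init=0.45, p_on=0.08, p_off=0.10,
          lookback="7day-any"),
        B("antineoplastics", "binary-timevarying", p_init=0.10, p_on=0.02, p_off=0.10,
          lookback="7day-any"),
        B("clabsi_history", "binary-static", p_init=0.02),
        B("tumor", "binary-static", p_init=0.30),
        B("lymphoma", "binary-static", p_init=0.04),
        B("transplant", "binary-static", p_init=0.05),
        B("icu", "binary-timevarying", p_init=0.25, p_on=0.03, p_off=0.10),
        B("mechanical_ventilation", "binary-timevarying", p_init=0.15, p_on=0.02,
          p_off=0.12),
        B("temperature", "gaussian", mean=37.0, sd=0.7, ar1=0.6,
          missing_rate=0.10, miss_on="icu", miss_delta=-0.5),
        B("systolic_bp", "gaussian", mean=125.0, sd=18.0, ar1=0.6,
          missing_rate=0.12, miss_on="icu", miss_delta=-0.5),
        B("wbc", "positive-skewed", mean=2.1, sd=0.5, ar1=0.8,
          missing_rate=0.20, miss_on="icu", miss_delta=-0.5),
        B("crp", "positive-skewed", mean=3.0, sd=0.9, ar1=0.85,
          missing_rate=0.25, miss_on="icu", miss_delta=-0.5),
        B("other_positive_culture", "binary-timevarying", p_init=0.08, p_on=0.02,
          p_off=0.05),
        B("admission_from_home", "binary-static", p_init=0.80),
    ]
    p = len(preds)
    rng = np.random.default_rng(12345)  # fixed: part of the preset definition
    betas = np.zeros((3, p))
    name_ix = {b.name: j for j, b in enumerate(preds)}
    strong = {
        "clabsi": {"icu": 0.6, "cvc": 0.5, "tpn": 0.4, "crp": 0.3, "wbc": 0.2,
                   "temperature": 0.35, "clabsi_history": 0.8, "tumor": 0.2},
        "death": {"icu": 0.8, "tumor": 0.5, "mechanical_ventilation": 0.6,
                  "crp": 0.3, "admission_from_home": -0.3},
        "discharge": {"icu": -0.9, "cvc": -0.3, "tpn": -0.3, "crp": -0.2,
                      "mechanical_ventilation": -0.5, "admission_from_home": 0.2},
    }
    for k, cause in enumerate(("clabsi", "death", "discharge")):
        betas[k] = rng.normal(0.0, 0.05, p)
        for nm, v in strong[cause].items():
            betas[k, name_ix[nm]] = v
    cfg = SimulationConfig(
        n_admissions=n_admissions, p_multi_episode=0.10, predictors=preds,
        true_betas=betas, baseline_hazards=(0.004, 0.012, 0.110), seed=seed,
    )
    cfg.validate()
    return cfg


def _model_scale(values, spec: PredictorSpec):
    """Transform raw covariate values to the scale the hazard betas act on."""
    if spec.kind == "positive-skewed":
        return np.log1p(values) - spec.mean
    if spec.kind == "gaussian":
        return values - spec.mean
    return values


def _simulate_paths(cfg: SimulationConfig, n_ep, rng):
    """Latent daily covariate paths for all episodes, days 0..max_follow_up."""
    days = cfg.max_follow_up + 1
    p = len(cfg.predictors)
    raw = np.empty((n_ep, days, p))
    for j, spec in enumerate(cfg.predictors):
        if spec.kind == "binary-static":
            x0 = (rng.random(n_ep) < spec.p_init).astype(float)
            raw[:, :, j] = x0[:, None]
        elif spec.kind == "binary-timevarying":
            x = (rng.random(n_ep) < spec.p_init).astype(float)
            raw[:, 0, j] = x
            u = rng.random((n_ep, days - 1))
            for t in range(1, days):
                switch_on = (x == 0) & (u[:, t - 1] < spec.p_on)
                switch_off = (x == 1) & (u[:, t - 1] < spec.p_off)
                x = np.where(switch_on, 1.0, np.where(switch_off, 0.0, x))
                raw[:, t, j] = x
        else:  # gaussian / positive-skewed: stationary AR(1)
            z = rng.standard_normal((n_ep, days))
            y = np.empty((n_ep, days))
            y[:, 0] = spec.mean + spec.sd * z[:, 0]
            innov_sd = spec.sd * np.sqrt(1.0 - spec.ar1**2)
            for t in range(1, days):
                y[:, t] = spec.mean + spec.ar1 * (y[:, t - 1] - spec.mean) \
                    + innov_sd * z[:, t]
            if spec.kind == "positive-skewed":
                raw[:, :, j] = np.expm1(np.maximum(y, 0.0))
            else:
                raw[:, :, j] = y
    return raw


def generate_cohort(config: SimulationConfig):
    """Draw a full cohort.

    Returns (episodes, trajectories, truth):
      episodes      DataFrame: episode_id, admission_id, onset_day, T, D
      trajectories  DataFrame: episode_id, day, one column per predictor
                    (days 0..min(floor(T)-? terminal day, max_follow_up);
                    values complete — apply_missingness() blanks them)
      truth         GeneratorTruth with latent paths and true daily rates.

    Episodes still event-free after max_follow_up days are assigned a forced
    discharge at max_follow_up + horizon (documented convention so that every
    episode has a terminal event).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # admissions -> episodes
    n_eps_per_adm = np.ones(config.n_admissions, dtype=int)
    extra = rng.random(config.n_admissions) < config.p_multi_episode
    n_eps_per_adm[extra] += 1
    admission_id = np.repeat(np.arange(config.n_admissions), n_eps_per_adm)
    n_ep = len(admission_id)
    episode_ix = np.arange(n_ep)
    # second episodes start later in the admission; onset_day is metadata
    # (all modeling time scales are days since episode onset)
    is_second = np.concatenate(
        [np.arange(k) for k in n_eps_per_adm]
    )
    onset_day = is_second * (2 + rng.integers(0, 10, n_ep))

    raw = _simulate_paths(config, n_ep, rng)
    p = len(config.predictors)
    model = np.empty_like(raw)
    for j, spec in enumerate(config.predictors):
        model[:, :, j] = _model_scale(raw[:, :, j], spec)

    M = config.max_follow_up
    day_idx = np.arange(M)  # hazard for day s+1 uses covariates at day s
    betas = config.true_betas
    lp = np.einsum("ndp,kp->ndk", model[:, :M, :], betas)
    # landmark-time interactions on the cause-1 linear predictor
    for ia in config.interactions:
        j = config.predictor_names.index(ia.predictor)
        drift = ia.linear * day_idx + ia.quadratic * day_idx**2
        lp[:, :, 0] += model[:, :M, j] * drift[None, :]

    base = np.stack(
        [config.baseline_at(k, day_idx) for k in range(3)], axis=-1
    )  # (M, 3)
    rates = base[None, :, :] * np.exp(lp)  # (n_ep, M, 3)
    H = rates.sum(axis=2)
    p_event = -np.expm1(-H)  # P(any event during the day)

    u_event = rng.random((n_ep, M))
    u_cause = rng.random((n_ep, M))
    hit = u_event < p_event
    any_hit = hit.any(axis=1)
    first = np.where(any_hit, hit.argmax(axis=1), -1)

    T = np.empty(n_ep, dtype=float)
    D = np.empty(n_ep, dtype=int)
    horizon = config.horizon
    T[~any_hit] = M + horizon  # forced discharge convention
    D[~any_hit] = 3
    if any_hit.any():
        rows = np.flatnonzero(any_hit)
        f = first[rows]
        T[rows] = f + 1.0  # event at the end of day f+1 since onset
        rk = rates[rows, f, :]
        csum = np.cumsum(rk, axis=1)
        csum /= csum[:, -1:]
        D[rows] = 1 + (u_cause[rows, f][:, None] > csum).sum(axis=1)

    episodes = pd.DataFrame(
        {
            "episode_id": episode_ix,
            "admission_id": admission_id,
            "onset_day": onset_day,
            "T": T,
            "D": D,
        }
    )

    # trajectory rows: days 0..min(T, max_follow_up); no rows after the
    # terminal day
    last_day = np.minimum(T, M).astype(int)
    n_rows = last_day + 1
    ep_col = np.repeat(episode_ix, n_rows)
    day_col = np.concatenate([np.arange(k) for k in n_rows])
    traj = pd.DataFrame({"episode_id": ep_col, "day": day_col})
    for j, spec in enumerate(config.predictors):
        traj[spec.name] = raw[ep_col, day_col, j]

    truth = GeneratorTruth(
        config=config, model_scale_paths=model, hazard_paths=rates,
        linear_predictors=lp,
    )
    return episodes, traj, truth


def apply_missingness(trajectories: pd.DataFrame, config: SimulationConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Blank continuous values under the configured MAR rule.

    Missingness of a value on a given day depends only on observed binary
    flags of the same day (e.g. ICU stays chart labs more often), never on
    the value itself.  Binary flags are never blanked.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    out = trajectories.copy()
    from scipy.special import expit, logit

    for spec in config.predictors:
        if spec.missing_rate <= 0:
            continue
        pm = np.full(len(out), spec.missing_rate)
        if spec.miss_on is not None and spec.miss_delta != 0.0:
            on = out[spec.miss_on].to_numpy().astype(float)
            pm = expit(logit(np.clip(pm, 1e-12, 1 - 1e-12)) + spec.miss_delta * on)
        blank = rng.random(len(out)) < pm
        col = out[spec.name].to_numpy(dtype=float, copy=True)
        col[blank] = np.nan
        out[spec.name] = col
    return out


def write_cohort(episodes, trajectories, truth, outdir):
    """CSV + JSON persistence (episodes.csv, trajectories.csv, truth.json)."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    episodes.to_csv(outdir / "episodes.csv", index=False)
    trajectories.to_csv(outdir / "trajectories.csv", index=False)
    (outdir / "truth.json").write_text(truth.config.to_json())
    return outdir


def read_cohort(indir):
    import pathlib

    indir = pathlib.Path(indir)
    episodes = pd.read_csv(indir / "episodes.csv")
    trajectories = pd.read_csv(indir / "trajectories.csv")
    return episodes, trajectories
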