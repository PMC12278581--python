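# Methods

This note documents the models, the synthetic cohort that stands in for
real hospital data, the numerical choices, and what the tests do and do not
establish.

## Outcome structure and time scales

The unit of analysis is a *catheter episode*: a continuous period with a
central venous catheter, ending in exactly one of three terminal causes —
(1) a catheter-related bloodstream infection, (2) death or the start of
palliative care, (3) discharge or definitive catheter removal.  In-hospital
EHR data are recorded until the episode ends, so there is **no random
censoring**; the only censoring anywhere in the pipeline is the deliberate
*administrative* truncation at the prediction horizon s + w.

All model time scales are days since catheter onset.  The prediction
target is the probability of cause 1 within a window of w = 7 days, either
from onset (static) or conditional on being event-free at landmark day s
(dynamic).  The landmark day enters dynamic models only through the s and
s² covariate terms (and screened interactions), so one fitted equation
serves every prediction day — the landmark-supermodel device.

## Synthetic cohort generator

Real cohorts of this kind sit in controlled-access hospital storage, so the
package generates its own with known truth.

* **Covariates.**  Binary ward/device/medication flags follow 2-state
  Markov chains; vitals follow stationary AR(1) processes; right-skewed
  labs are `expm1` of an AR(1) gaussian, so their log1p transform is the
  scale on which the true coefficients act.  Admission-level flags are
  drawn once per episode.  Medication-style flags carry a 7-day lookback
  (rolling OR) when assembled into landmark records; everything else uses
  the current-day value.
* **Events.**  Cause-specific hazards h_k(s|Z) = b_k(s)·exp(β_k'Z(s)) are
  continuous-time *rates* held constant within each day.  Conditional on
  being at risk at the start of a day, the probability of any event during
  the day is 1 − e^{−H} with H = Σ_k h_k, split among causes in proportion
  to h_k, and the event is recorded at the end of the day (integer T).
  This embedding keeps every per-day probability valid for arbitrary rates
  and makes constant-rate cohorts match the closed-form competing-risks
  cumulative incidence (λ₁/H)(1 − e^{−Ht}) *exactly* — the alternative
  reading of a "daily hazard" as a raw probability would make the 7-day
  incidence at rates 0.1/0.1 equal 0.395 rather than the continuous-time
  0.377 and would leave nothing for the closed-form checks to verify.
* **Default conditions** (the 8-predictor preset): ~1.1 episodes per
  admission; infection baseline 0.003/day; death baseline 0.012/day;
  discharge baseline **front-loaded**, 0.20·e^{−t/7} + 0.035 — most
  catheters come out within the first week and a minority of long-stay
  patients keep theirs, which is both the realistic shape and the regime in
  which the model families genuinely differ (see below).  Covariate effects
  are chosen so that some predictors (tumor, admission-from-home) drive
  *only* the competing events: they change how long a patient stays on the
  line, hence the infection risk through exposure, without touching the
  infection hazard itself.  The resulting 7-day infection incidence is
  ≈2.5%, within the low-prevalence regime of real catheter cohorts, with
  ≈5–8% of episodes still at risk at day 30.  A 21-predictor preset mirrors
  the full covariate battery (catheter types and sites, medication flags,
  comorbidities, vitals, labs, admission source) for structure-faithful
  runs.
* **Missingness** is MAR: labs/vitals are blanked with a per-predictor
  daily rate whose log-odds shift with the observed ICU flag (ICU stays
  chart more completely).  Flags are never missing.
* **Forced termination.**  An episode still event-free after the 60-day
  follow-up cap is assigned a discharge at day 60 + w, so every episode has
  a terminal cause and the risk sets are exact.

What the generator does **not** emulate: informative measurement times,
between-predictor causal structure beyond the shared ICU/illness axis,
real prevalences or missingness percentages of any particular hospital,
multi-catheter within-admission correlation beyond shared admission
membership.  Tests passing on this cohort therefore establish the
*statistical machinery* (risk sets, weights, likelihoods, calibration
arithmetic), not clinical transportability.

## Model families

All fits share one numerical core: a weighted partial likelihood over
counting-process (start, stop] records, maximized by Newton–Raphson with
step-halving.  Convergence requires max |gradient| < 1e−8 or, on large
stacked datasets where that absolute tolerance is below the float64
resolution of the log-likelihood, a Newton decrement under
100·eps·(1+|ll|).  Ties (daily data) are handled by Efron's correction for
unweighted fits and Breslow's for IPCW-weighted ones; the baseline
cumulative hazard is always the Breslow estimator.  Separation / monotone
likelihood is detected by coefficient magnitude (>15 at convergence) and
raised as an explicit `FitError` — never silently penalized.  Predicted
probabilities are clipped to [0,1] with a warning, since discrete hazard
increments can overshoot.

* **Cox** (cause 1 only, competing events treated as censoring):
  risk = 1 − exp(−ΔΛ₀·e^{β'Z}).  Deliberately wrong here — it assumes the
  infection can still happen after discharge or death — and kept as the
  comparison's negative control.
* **Cause-specific**: three Cox fits; risks composed by the discrete
  Aalen–Johansen formula, which conserves probability (cause CIFs plus
  residual survival sum to 1).
* **Fine–Gray**: fitted on the counting-process transform in which
  competing-event episodes remain in the subdistribution risk set until
  s + w, with Kaplan–Meier-of-censoring IPCW weights G(t)/G(T_c).  Under
  purely administrative censoring all weights equal 1 (a tested property);
  the general weighted path exists and is exercised against `cmprsk::crr`
  agreement in development.  Static variants with and without
  administrative censoring differ in how much late follow-up enters the
  fit.
* **Logistic / multinomial**: IRLS and joint Newton MLE with the "none"
  (still-at-risk) reference category; no regularization.  Covariates are
  centered internally for conditioning (reported coefficients are on the
  original scale).  With no censoring these need no competing-risk
  correction: a competing event inside the window is simply a non-event
  (logistic) or its own class (multinomial).
* **RMTL**: per-landmark logistic tasks, each standardized with its own
  training mean/sd, jointly minimizing Σ_t loss_t/n_t + λ₁·Σ‖w_t−w_{t+1}‖²
  + λ₂‖W‖² by monotone Nesterov-accelerated gradient descent (backtracking
  line search, function-value restarts; gradient tolerance 1e−6 scaled by
  the penalty weight so the fused λ₁→∞ limit terminates).  λ₁ is tuned by
  admission-grouped 5-fold cross-validation over a log-spaced grid
  (default 1e−3…1e2, ties toward the smoother value); λ₂ defaults to 0.
  Intercepts are never penalized.

## Feature handling

Recipes are learned on training data only and replayed frozen: log1p for
right-skewed labs (log1p rather than log because synthetic labs can be 0),
a 3-knot restricted cubic spline (natural/linear-tail parameterization,
knots at the 10/50/90 training percentiles, type-7 quantiles) where
configured, s and s² terms for dynamic designs, and screened
covariate-by-landmark interactions.  The interaction screen adds
(x·s, x·s²) to the cause-1 landmark supermodel and applies a joint 2-df
Wald test (α = 0.05) with the model-based covariance; it can be re-run per
training split (leakage-free default) or hard-coded to a fixed list to
mimic a single whole-data selection.  Constant covariates are dropped with
a warning; rcs3 falls back to a linear term below 10 distinct values.

## Imputation

An iterative random-forest imputer in the prediction-setting style: initial
mean/mode fills, then 5 fixed iterations in which each missing-in-training
variable is re-predicted from all other covariates by a fresh forest (100
trees, seed derived from (variable, iteration)), visiting variables in
order of increasing missingness.  Every per-iteration forest is stored, so
applying the imputer to new data replays the exact training-time sequence —
deterministic, trained on training records only, outcome columns excluded
by construction.  Low-missingness categorical variables can be flagged
mode-only.

## Evaluation

Because nothing is censored, every metric treats the outcome as the binary
"infection within (s, s+w]" among episodes at risk at s: Mann–Whitney
AUROC with half-weight ties, calibration slope (logistic recalibration of
y on logit p), O/E ratio (observed rate over mean prediction), ECI (mean
squared distance between p and a flexible observed-probability curve — a
logistic fit on a 3-knot restricted cubic spline of logit p, reported on
the raw squared-probability scale), and the scaled Brier score
1 − Brier/Brier_null.  Undefined cases (single class, constant predictions,
zero-variance outcome) return missing values with warnings.

The validation harness repeats: a 2:1 admission-grouped split (episodes and
all their landmarks travel together; training count = round(2n/3)), imputer
fit on training rows, both sides imputed, recipe and models fit on
training, 7-day risks predicted on the test side (per landmark for dynamic
models), metrics per (model, landmark, repetition).  Summaries are means
with 95% percentile intervals across repetitions (a normal-approximation
switch exists).  Fit failures are logged per (repetition, model, landmark)
and yield missing metrics, never abort the run.

## Why the model families separate (and when they do not)

Cox's miscalibration under strong competing hazards is structural: its
predicted 1 − exp(−Λ₁) ignores that discharge and death remove risk, so it
overestimates by roughly the factor (1 − e^{−wH})/(wH); with the default
hazards that is an O/E near 0.65–0.78.  Its *discrimination* deficit is
subtler: ranking by the cause-1 linear predictor alone discards the
exposure information carried by competing-event predictors.  A static
Fine–Gray model fitted without administrative censoring ranks by the
all-time subdistribution coefficients, which under a *constant* discharge
hazard approximates ranking by h₁/H — the opposite extreme from Cox's h₁,
with the 7-day truth in between, leaving the two near-tied.  With the
realistic front-loaded discharge hazard the within-week exposure
heterogeneity dominates and the competing-risks and categorical models all
out-rank Cox, which is the regime the default generator freezes.  This
analysis is why the default discharge baseline is time-varying; it is a
design property of the study conditions, not a tuning knob.

## Problem sizes used in the shipped checks

Simulation-based checks run at the smallest sizes at which the quantity
being verified is resolvable: hospital-scale (28,000 admissions ≈ 30,800
episodes, 10 split repetitions) for the static model contrast, whose AUROC
orderings differ by ~0.005–0.01; ~10,000 episodes for supermodel
consistency and coefficient recovery (the latter averaged over replicate
cohorts so the Monte-Carlo error per coefficient sits well below the 0.05
bias bound); 2,500 admissions with a 0–25 landmark grid for the
late-landmark Fine–Gray degradation; 8 tasks × 150 records for the
multi-task comparisons.  All seeds are fixed or derived from a single
command-line seed.

## Known limitations

* No robust (sandwich) variances: supermodel standard errors ignore the
  within-episode correlation across stacked landmarks and are used only for
  the interaction screen; the package reports predictions and their
  performance, not coefficient inference.
* The discrete daily recording of events biases hazard-ratio estimates on
  the order of the within-day event probability; at the default rates this
  is well under the tested 0.05 bound but grows with per-day hazards.
* Per-landmark Fine–Gray fits at late landmarks fail by design when risk
  sets shrink (separation); the harness records rather than rescues them.
* The generator's MAR missingness cannot represent MNAR lab ordering
  (sicker patients measured *because* they are sicker), so imputation
  results speak to mechanics, not clinical bias.
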