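# Methods

## Problem setting

For a glioblastoma patient with baseline covariates x, let T ∈ {GTR=0,
SpTR=1} be the extent of resection and S(t | x, T) the brain-cancer-specific
survival function. Only one arm's outcome is ever observed; the package
estimates both and summarizes their difference per patient. Time is in
months throughout; event = 1 means cancer-specific death.

## Synthetic cohort generator

The generator emulates the structure of a US registry cohort of surgically
treated GBM patients. It is the package's test bed, not a fit to any
microdata.

* **Covariates.** Age ~ Normal(64, 13.3), clipped to [18, 95] (median 64,
  IQR ≈ 55–73); tumor diameter log-normal with median 45 mm and IQR ≈
  33–56 mm; binary sex (58.1% male), race (89.8% white), marriage (63.8%),
  urban residence (87.9%), high income (71.0%), metastasis (1.4%);
  categorical reporting region, tumor location, laterality and extension
  with the published frequencies. The three published extension levels sum
  to 96%; they are renormalized over the listed levels.
* **Treatment.** P(SpTR | x) = expit(γ₀ + γ·x) with γ₀ = 0.30 and small
  coefficients on age, sex, size, income, mid-laterality and midline
  extension, reproducing the ~65% SpTR share among resected patients and
  deliberate confounding (the same covariates also carry prognostic
  weight).
* **Outcome.** Weibull proportional hazards, S(t|x,T) =
  exp(−(t/λ)^k · e^{β·x + T(δ₀ + δ·x)}), k = 1.1, λ = 18 months — chosen
  once so the overall median survival is ≈ 12 months, the scale of the
  published anti-recommended group. β follows the published prognostic
  directions (older age, male sex, larger tumor, metastasis, midline
  crossing harmful; confined, temporal/occipital/parietal location
  protective). The interaction δ plants SpTR benefit for frontal tumors
  and larger tumors and SpTR harm for older and male patients, matching
  the qualitative subgroup findings; magnitudes (0.2–0.35 on the
  log-hazard scale) are the package's own choice, fixed once.
* **Censoring.** Administrative at 60 months plus exponential dropout at
  0.008/month, together yielding ≈ 16.6% censoring at the default
  configuration. The source cohort reports only a median follow-up; the
  dropout rate is the generator's own calibration to the published alive
  fraction.
* **Oracle.** Because the DGP is known, the generator emits each patient's
  true per-arm linear predictors, the true ITEs (RST by 256-point
  Gauss–Legendre quadrature, exact to ≪ 1e-6 months; TaR in closed form)
  and the optimal arm (SpTR iff true ITE_RST > 0).

What the generator does **not** emulate: competing risks, time-varying
covariates or effects, measurement error, informative censoring, and any
nonlinearity in the true log-hazard. Passing tests therefore demonstrate
that the pipeline recovers a *linear, proportional-hazards* ground truth
under confounding — they cannot certify behavior on real registry data.

## Survival core

* Cox partial likelihood and the baseline hazard both use the **Breslow**
  tie convention — the same convention differentiable deep-survival losses
  use, so the deep and linear routes are directly comparable. Newton–
  Raphson with gradient max-norm 1e-7 or 100 iterations; sandwich
  (robust) standard errors whenever case weights are supplied.
* Individual curves are S(t) = exp(−H₀(t)·e^lp) with H₀ the per-arm
  Breslow estimator; the nonparametric-baseline-plus-PH-transform reading
  of "Kaplan–Meier transformation" of risk scores.
* Kaplan–Meier carries Greenwood pointwise variance; dRMST confidence
  intervals integrate the Greenwood variance per arm and assume
  independence across arms.
* Median survival is the first grid time with S ≤ 0.5 ("not reached"
  flagged explicitly). RMST is the exact step-function integral; a τ
  beyond the grid is an error unless the curve has already reached 0.
* Harrell's C credits ties in the score 0.5; the optional CI is a seeded
  nonparametric bootstrap (500 resamples by default).
* The integrated Brier score is Graf's IPCW estimator on the distinct
  event times up to τ (trapezoidal in time), censoring distribution from
  the KM of censoring times, truncated with a warning if that KM hits 0.
* The life table uses 1-month intervals (the registry records months) and
  the half-interval censoring correction; SaT is its cumulative survival
  at 60 months.

## Model components

All neural pieces run on a ~300-line numpy reverse-mode autodiff written
for this package; gradients are exact and verified against central finite
differences at 1e-5 relative tolerance in the test suite.

* **LassoNet shared net.** Output = x·θ + MLP(x); representation = last
  hidden layer ⊕ skip value. After every optimizer step the hierarchical
  proximal operator is applied to (θ, first-layer weights): soft-threshold
  θ by λ_skip and enforce ‖W⁽¹⁾ⱼ‖∞ ≤ M·|θⱼ| exactly, so a feature can act
  nonlinearly only while its linear path is active. Default hidden width
  16, λ_skip = 0.01, M = 10; λ_skip is meant to be tuned by CV rather
  than traced along a full regularization path.
* **NODE heads.** Oblivious trees: one softmax-weighted feature choice and
  one threshold per depth level, sigmoid gates at temperature 1, leaf
  distribution as the product of gates, output the leaf-value expectation;
  a layer averages its trees. Defaults: 1 layer, 8 trees, depth 3 —
  deliberately small ensembles sized for CPU training with the numpy
  autodiff; no reference values exist for these hyperparameters, and they
  are exposed in `TrainConfig`. Feature selection uses temperature-
  controlled softmax rather than a sparse-simplex transform: it is smooth,
  exactly differentiable in the hand-rolled autodiff, and reaches the same
  hard-tree limit (verified against an explicitly enumerated tree).
* **IPM penalty.** Squared MMD, V-statistic, RBF kernel with the median
  pairwise-distance bandwidth heuristic; applied to the shared
  representation with the treatment labels of the batch. An empty group in
  an unlucky mini-batch yields penalty 0 with a warning rather than an
  error. Default weight α = 1 (no reference value exists).

## Training protocol

80/20 train/test split stratified by (treatment, event); 5-fold CV for
hyperparameter tuning with mean full-data validation loss (including the
α-weighted IPM term for the balanced kinds — the early-stopping signal is
the training objective). Early stopping monitors a 20% validation split of
the training data with patience counted in **optimizer steps** (default
1000; "iterations" is ambiguous between steps and epochs, and steps is the
recorded, configurable reading). Adam at learning rate 1e-3, batch size
256, maximum 10,000 steps by default; the Cox loss inside a mini-batch
uses the batch risk set. Tests and the acceptance script scale the
iteration budget down (150–1500 steps) and use cohorts of 2,000–4,000
patients — sizes at which the linear ground truth is comfortably
recoverable on one CPU.

## ITE and recommendation

Curves are evaluated on a monthly 0–60 grid. TaR is the first grid time
with predicted mortality ≥ 50%, capped at τ = 60 with a preserved flag
(keeping the ITE total and bounded; two capped arms give ITE_TaR = 0 by
construction). RST is the step integral over [0, 60]. Recommendation:
SpTR iff ITE > 0; ties go to GTR, the less extensive resection. Both
methods are always computed; the method used for grouping is a run-time
switch.

## Evaluation and causal adjustment

dRMST and the univariate Cox HR between Rec and Anti-rec are the core
metrics; per-group RMST/MST/SaT, the log-rank test, C-index and IBS
complete the report. IPTW uses a logistic propensity of Rec membership on
the baseline covariate set (age, race, marriage, income, region, location,
laterality, extension, tumor size, metastasis — treatment is excluded by
contract because it is post-exposure), stabilized weights truncated at the
1st/99th percentiles, and robust-variance weighted Cox / logistic models
for HRᵃ and ORᵃ. Mediation treats the actual surgery as the mediator
between recommendation and death by 60 months (patients censored earlier
count as alive for this binary endpoint): logistic outcome and mediator
models, NDE with the mediator at its exposure-reference distribution, CDE
with the mediator fixed at GTR, risk-difference scale, percentile
bootstrap CIs (500 resamples). No multiplicity adjustment is applied.

## Explanations

SurvSHAP(t): Shapley attributions of the predicted survival function,
marginal (interventional) value function over a background sample, exact
coalition enumeration up to 10 features and a shared-coalition kernel
least-squares solution beyond. Treatment is never an explained feature —
it selects the risk head and baseline — so explanations are per arm.
Per-observation importance is ∫|φⱼ(t)|dt; rankings are tabulated into
per-rank-position counts across observations.

## Numerical choices and degenerate inputs

Zero events anywhere a partial likelihood is needed is an explicit error,
never a silent zero. Constant design columns are dropped (and remembered)
by the linear fitters. Perfect separation in any logistic model falls back
to an L2-penalized fit with a warning. NaN/inf training loss aborts the
fit with a diagnostic. All randomness flows from explicit integer seeds;
fits, splits, bootstraps and explanations are bit-reproducible given the
same seed and inputs.

## Known limitations

The comparator list stops at the models above (no random survival forest
re-implementation). ITEs carry no uncertainty intervals. The MMD is the
only implemented IPM. Model archives store plain JSON parameter lists —
fine at these model sizes, inefficient for much larger ones. The synthetic
DGP's linearity means the neural models' advantage over linear Cox cannot
manifest here; on these cohorts the Cox T-learner is correctly specified
and slightly ahead, and the tests only require the ensembles to recover
the same signal.
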