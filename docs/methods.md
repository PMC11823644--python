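# Methods

## Scope and model

`tobramipd` benchmarks two ways of estimating tobramycin exposure from
sparse therapeutic drug monitoring (TDM) samples:

* **Two-sample log-linear regression (LLR)** — the bedside standard: a
  one-compartment, steady-state infusion model fit to one peak and one
  trough. It uses no prior information and assumes log-linear decay between
  the two samples.
* **MAP Bayesian estimation** — posterior-mode estimation of individual
  log-scale random effects η under a population PK prior, with optional
  prior flattening and likelihood-based (M3) handling of censored samples.

The PK engine evaluates one- and two-compartment IV-infusion models in
closed form (superposition of exact infusion solutions; bi-exponential
macro-constants λ₁, λ₂ from CL, V1, Q, V2 for two compartments). No ODE
integration is used in the library; a stiff ODE integrator serves only as
an independent oracle in the test suite. The `(1 − e^{−λt})/λ` factors are
evaluated through `expm1` so the Q → 0 and t → 0 limits are stable.

### Individual parameter model

Each structural parameter is `theta × covariate factors × exp(eta)`.
Covariate factors are multiplicative and normalized: power form
`(cov/ref)^coef` or linear form `1 + coef·(cov − ref)/ref`. η is
multivariate normal (0, Ω). Residual error is combined proportional +
additive, with the SD evaluated at the model prediction:
`σ(pred)² = (CV·pred)² + add²`. Evaluating σ at the prediction (not the
observation) is the convention compatible with censored likelihoods —
a censored sample has no observed value to plug in — and contrasts
deliberately with LLR's implicit constant-CV weighting of measured values.

### MAP objective

The −2 log posterior (pharmacometric OFV convention, so w = 1 reproduces
the conventional MAP objective):

    OFV(η) = w·ηᵀΩ⁻¹η
           + Σ_quantified [((obs − pred)/σ(pred))² + ln σ(pred)²]
           − 2·Σ_BLOQ ln Φ((LOQ − pred)/σ(pred))

* **Flattening** multiplies the prior quadratic form by w ∈ (0, 1],
  equivalent to inflating Ω by 1/w. Flattening is applied to all random
  effects uniformly; nothing in the estimation problem singles out a
  subset, and a per-parameter scheme would add free choices without a
  principled default.
* **M3 term** uses a log-CDF routine, never the log of an underflowed
  probability, so predictions 10σ above the LOQ still contribute a finite
  (astronomically negative) value.
* Residual-error parameters are fixed at their model values; they are
  population quantities, not per-patient ones.

A note on the flattening monotonicity property: for fixed data, the
standard two-point convexity argument shows the optimized **data-likelihood
term** (OFV minus the weighted prior form) is non-increasing as w
decreases. The bare standardized-residual sum is *not* guaranteed monotone
here, because with σ evaluated at the prediction the `ln σ²` term can trade
against an already-tiny misfit; the tests therefore check the full data
term, which is the rigorous statement and reduces to the residual sum when
σ is constant.

### Optimization

η̂ minimises the OFV by L-BFGS-B (numerical gradients; the surfaces are
smooth and at most 4-dimensional) from η = 0 plus deterministic perturbed
restarts (default 4 in the estimator API; the large simulation grids use
1–2 restarts since the rich multimodality risk is low at 1–2 observations
and 2–3 etas). Convergence tolerance 1e−8 on the OFV. With zero usable
observations the prior mode η = 0 is returned without invoking the
optimizer; if every start fails, the fit falls back to η = 0 with a
warning and a `converged=False` flag.

## LLR details

* **Classification** is by offset from the end of the most recent prior
  infusion: (0, 3] h → peak; ≥ 4 h → trough; the 3–4 h gap → "other"; at or
  before the end of infusion → invalid (such courses are excluded, matching
  clinical practice of discarding on-infusion draws).
* **Grouping** recognises a peak followed by a trough in the same dosing
  interval, or a pre-dose trough followed by exactly one dose and its peak.
  Assignment is greedy, earliest-first, non-overlapping — deterministic and
  the way a clinician reads the chart chronologically.
* **Trough-dose-peak timing.** The printed one-compartment steady-state
  formulas only apply to such a pair under steady-state periodicity: the
  pre-dose trough is carried forward one interval, so the decay time is
  `τ − t_peak − lead`, where `lead` is how far the trough precedes the
  dose. This is a documented convention, not the only conceivable one.
* The elimination-rate numerator/denominator are oriented so that a
  decaying pair gives k > 0 (`ln(C₁/C₂)/(t₂ − t₁)` with t₂ > t₁); a
  non-decaying pair returns `not-evaluable(nonpositive-k)` rather than a
  negative rate. t₁ in the Vd expression is measured from the dose start,
  which makes the `e^{−k(t₁ − t_inf)}` factor dimensionally coherent.
* Every course ends either evaluable or with a machine-readable reason
  (`bloq-sample`, `mistimed`, `insufficient-samples`, `nonpositive-k`), so
  dropout accounting mirrors clinical-data reporting.

## Exposure

"True" and estimated AUC default to **AUC over 0–24 h from the dose start**
of the single simulated dose; the 0–∞ identity `total dose / CL` is also
exposed. For tobramycin's 2–3 h half-life the two differ by only a few
percent, and a fixed finite window keeps the truth and every estimator on
exactly the same footing. Finite-window integrals use a trapezoid on a
0.01 h grid (well below 0.1% error against closed forms); the 0–∞ case is
analytic. LLR's AUC₂₄ is `daily dose / CL`, its steady-state meaning.

## Synthetic cohort

The generator emulates an adult-CF study population:

| quantity | default | rationale |
|---|---|---|
| age (y) | log-normal, median 32.7, p5–p95 22.2–58.8 | study-population summary |
| weight (kg) | 58.2 (39–90.9), bounds 30–150 | " |
| height (cm) | 165.1 (149.9–182.9) | " |
| serum creatinine (mg/dL) | 0.73 (0.38–1.31) | " |
| creatinine clearance (mL/min) | 113.1 (25.4–251.3), bounds 10–400 | consumed directly as a covariate |
| male fraction | 0.56 | 28/50 in the study population |
| dose | 10 mg/kg over 0.5 h, single dose, τ = 24 h | study regimen; not rounded to vial sizes |
| IIV draws per patient | 5 | study design |
| LOQ | 0.4 mg/L | assay limit |
| residual noise | the simulation model's own σ block | the source models' error magnitudes are configuration |

Log-normal marginals are fitted to (median, p5, p95) by matching the median
and the **wider** of the two percentile gaps — the simplest positive,
right-skewed choice; the narrower gap is then only approximated, which for
creatinine clearance leaves the upper tail heavy. Draws are **winsorised**
at the plausibility bounds rather than redrawn: clipping leaves every
quantile inside the bounds untouched, whereas rejection-resampling of the
heavy CRCL tail was observed to drag the median ~10% off target.
Covariates are drawn independently (no correlation structure is published
for this population) and a creatinine-clearance value is drawn directly
rather than derived from a formula (which equation the source models used
is unknown; a Cockcroft–Gault helper exists for users who prefer deriving
it). Observation noise is `pred·(1 + CV·ε₁) + add·ε₂`; draws below the LOQ
(including negative ones) are censored with the value withheld.

What the generator does **not** emulate: covariate correlations,
within-course creatinine drift, multi-dose courses per simulated patient,
sample-time recording errors, or model misspecification beyond swapping
between the two configured priors. Passing tests therefore demonstrate
estimator properties under a correctly specified (or deliberately swapped)
data-generating model, not performance on real hospital data.

The packaged `hennig_like` and `alghanem_like` parameter sets are
**plausible placeholders** (two-compartment adult-CF tobramycin values:
CL ≈ 4.6–5.5 L/h, V1 ≈ 15.5–19 L at reference covariates) meant to be
replaced by transcribed published models; they deliberately differ in
covariate structure, number of IIV terms and residual magnitude so that the
matched-vs-mis-specified comparison is meaningful.

## Metrics

RMSE, nRMSE (= RMSE / mean(obs), in %), MPE (mean percent error, in %).
Clinical accuracy: peak and AUC within 20% of the reference (boundary
inclusive, ≤ 0.20); troughs accurate when predicted and reference agree on
which side of 1 mg/L they fall, with exactly 1 counting as "above" for both
(a consistent tie-break; the rule's direction is unstated and consistency
matters more than direction). Accuracy is computed per concentration pair,
not per course. Censored observed troughs are excluded from nRMSE/MPE
(undefined denominator) but count as "below 1 mg/L" in trough accuracy.

Uncertainty: patient-level bootstrap — patients resampled with replacement
carrying all their pairs, B = 1,000 by default — with 2.5th/97.5th
empirical percentiles (linear "type 7" interpolation, documented for
reproducibility). Two methods are "statistically distinguishable" on a
metric only when their percentile intervals do not overlap. In the
simulation comparison the LLR report can cover fewer patients than the
Bayesian ones (censoring removes pairs); the orchestrator compares them
anyway, flagged through the API's `require_same_patients=False` escape
hatch, since that asymmetric dropout is itself part of the clinical story.

## Determinism and problem sizes

All randomness flows from a single seed through spawned `SeedSequence`
streams (patients / η draws / observation noise / bootstrap), so a full
experiment is byte-reproducible from (config, seed). The shipped test and
acceptance workloads use 50 patients × 5 draws, two estimation models, two
designs (1 & 10 h; single 4 h) and weights {1.0, 0.5} — sizes chosen so a
full desk-scale replication completes in minutes while keeping Monte-Carlo
noise well inside the properties being asserted; larger grids (the full
weight ladder 1.0…0.1, single-sample sweeps over 1–10 h) are one config
edit away.

## Known limitations

* The shipped priors are constructed configuration, so absolute metric
  values are illustrative; only the qualitative contrasts (matched vs
  mis-specified, flattened vs regular, one vs two samples) carry meaning.
* LLR's infusion-phase assumptions are taken at face value; no correction
  for distribution-phase sampling of "peaks" drawn within minutes of the
  infusion end.
* No conditional-residual (CWRES) outlier screening and no population
  re-estimation: the prior is fixed, per the MIPD use case.
* The M3 term assumes the residual model is correctly specified near the
  LOQ, where assay CV in reality rises.
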