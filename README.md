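# tobramipd

Tobramycin exposure estimation in adults with cystic fibrosis: the clinical
standard **two-sample log-linear regression (LLR)** head-to-head against
**MAP Bayesian estimation** from a population pharmacokinetic (popPK)
prior, including flattened priors, censored (below-LOQ) samples via the M3
likelihood, and limited sampling designs — with a synthetic-patient
simulator for benchmarking both estimators against a known true AUC.

Intended for pharmacometricians and clinical-pharmacy researchers who want
a reproducible, tested pipeline for comparing simple exposure calculators
against model-informed precision dosing (MIPD).

## The two estimators

**LLR.** Two concentrations C₁ (peak, at t₁) and C₂ (trough, at t₂) around
a dose D infused over t_inf with interval τ give a one-compartment fit:

    k   = ln(C₁/C₂) / (t₂ − t₁)
    Vd  = D (1 − e^{−k·t_inf}) e^{−k(t₁ − t_inf)} / [t_inf · k · C₁ · (1 − e^{−kτ})]
    CL  = k · Vd,   AUC₂₄ = daily dose / CL

Peaks are samples drawn within 3 h of the end of the infusion, troughs 4+ h
after it; below-LOQ samples (LOQ 0.4 mg/L) make a pair unusable.

**MAP Bayesian.** A popPK model (two-compartment IV infusion with covariate
effects, log-normal inter-individual variability Ω, combined residual error
σ) defines a prior; the individual random effects η minimise

    OFV(η) = w·ηᵀΩ⁻¹η + Σ_quantified [ ((obs − pred)/σ(pred))² + ln σ(pred)² ]
             − 2 Σ_BLOQ ln Φ((LOQ − pred)/σ(pred))

The prior weight w ∈ (0, 1] *flattens* the prior (w = 1 is standard MAP;
smaller w is equivalent to inflating Ω by 1/w), and censored samples
contribute the probability of falling below the LOQ (M3). Exposure comes
from the fitted individual parameters by closed-form simulation.

Performance is compared with nRMSE, mean percent error, and clinical
accuracy (peak/AUC within 20%; troughs agreeing on which side of 1 mg/L),
with patient-level bootstrap percentile intervals.

## Worked example

```python
from tobramipd import Regimen, Observation, TwoSampleLLR, MAPBayesEstimator
from tobramipd.io import Course

regimen = Regimen.single(600.0, tinf=0.5, tinterval=24.0)
course = Course(
    course_id="example", patient_id="pt-1",
    covariates={"WT": 60.0, "CRCL": 110.0},
    regimen=regimen,
    observations=[Observation(1.5, 8.0, loq=0.4), Observation(9.5, 2.0, loq=0.4)],
)

llr = TwoSampleLLR().fit(course)
print(f"LLR: k = {llr.k_:.4f} 1/h, Vd = {llr.vd_:.1f} L, CL = {llr.cl_:.2f} L/h")
print(f"LLR AUC24 = {llr.predict_auc24():.1f} mg*h/L")

bayes = MAPBayesEstimator(model="hennig_like", prior_weight=0.5).fit(course)
print(f"MAP: eta_hat = {bayes.eta_.round(3)}, CL = {bayes.params_.CL:.2f} L/h")
print(f"MAP AUC24 = {bayes.predict_auc():.1f} mg*h/L")
```

prints

```
LLR: k = 0.1733 1/h, Vd = 61.4 L, CL = 10.63 L/h
LLR AUC24 = 56.4 mg*h/L
MAP: eta_hat = [0.525 0.862 0.018], CL = 8.62 L/h
MAP AUC24 = 68.2 mg*h/L
```

LLR reads the decay between the 8 and 2 mg/L samples directly (k ≈ 0.17/h,
CL ≈ 10.6 L/h, so a 600 mg daily dose gives AUC₂₄ ≈ 56 mg·h/L — below the
usual 80–110 mg·h/L target). The Bayesian fit balances the same two samples
against the population prior for this 60 kg patient with creatinine
clearance 110 mL/min: it attributes part of the low concentrations to a
larger-than-typical volume rather than all to clearance, and lands at a
higher AUC₂₄. With a flattened prior (w = 0.5) the data pull further from
the population typical values than standard MAP would allow.

Both estimators follow the scikit-learn conventions (`fit`, `predict`,
`get_params`, fitted attributes with trailing underscores). The same
machinery is scriptable from the shell: `tobramipd simulate | fit-llr |
fit-map | replay | experiment | report` (see `tobramipd --help`).

The packaged popPK parameter sets (`hennig_like`, `alghanem_like`) are
**editable configuration** with plausible adult-CF tobramycin values — swap
in a site-validated model via YAML before drawing any clinical conclusion.

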