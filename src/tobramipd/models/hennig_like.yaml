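# Two-compartment adult-CF tobramycin population PK model ("hennig_like").
# Editable configuration: typical values, IIV and residual error are
# plausible defaults for IV tobramycin in adults with CF and are meant to be
# replaced with a site-validated parameter set before clinical use.
model:
  label: hennig_like
  compartments: 2
  theta:          # at 70 kg, creatinine clearance 100 mL/min
    CL: 5.5       # L/h
    V1: 19.0      # L
    Q: 1.5        # L/h
    V2: 8.0       # L
  iiv: [CL, V1, V2]
  omega:          # lower triangle, log-scale variances
    - [0.09]
    - [0.0, 0.0625]
    - [0.0, 0.0, 0.16]
  sigma:
    prop: 0.15    # proportional CV, fraction
    add: 0.2      # additive SD, mg/L
  covariates:
    - {parameter: CL, covariate: WT,   form: power-normalized,  coefficient: 0.75, reference: 70.0}
    - {parameter: CL, covariate: CRCL, form: linear-normalized, coefficient: 0.4,  reference: 100.0}
    - {parameter: V1, covariate: WT,   form: power-normalized,  coefficient: 1.0,  reference: 70.0}
    - {parameter: Q,  covariate: WT,   form: power-normalized,  coefficient: 0.75, reference: 70.0}
    - {parameter: V2, covariate: WT,   form: power-normalized,  coefficient: 1.0,  reference: 70.0}
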