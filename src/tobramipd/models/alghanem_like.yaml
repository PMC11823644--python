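# Two-compartment adult-CF tobramycin population PK model ("alghanem_like").
# Editable configuration with plausible defaults; deliberately leaner than
# hennig_like (fewer IIV terms, lower residual error) so the matched vs
# mis-specified simulation comparison exercises genuinely different priors.
model:
  label: alghanem_like
  compartments: 2
  theta:          # at 70 kg, creatinine clearance 100 mL/min
    CL: 4.6       # L/h
    V1: 15.5      # L
    Q: 2.2        # L/h
    V2: 11.0      # L
  iiv: [CL, V1]
  omega:
    - [0.06]
    - [0.0, 0.04]
  sigma:
    prop: 0.10
    add: 0.1
  covariates:
    - {parameter: CL, covariate: CRCL, form: linear-normalized, coefficient: 0.7, reference: 100.0}
    - {parameter: V1, covariate: WT,   form: linear-normalized, coefficient: 1.0, reference: 70.0}
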