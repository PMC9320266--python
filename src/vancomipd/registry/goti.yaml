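# Goti vancomycin model for hospitalized adults with and without dialysis.
# Two-compartment, zero-order infusion input. Typical values and variability
# transcribed from the original model publication; treated as configuration.
# omega entries are squared CVs (0.398, 0.816, 0.571 on CL, V1, V2).
model_id: goti
compartments: 2
parameters:
  CL: 4.5    # L/h
  V1: 58.4   # L
  Q: 6.5     # L/h
  V2: 38.4   # L
covariate_relations:
  - {parameter: CL, covariate: crcl_cg, form: power, value: 0.8, reference: 120.0}
  - {parameter: CL, covariate: dialysis, form: factor_if_flag, value: 0.7}
  - {parameter: V1, covariate: total_body_weight, form: power, value: 1.0, reference: 70.0}
  - {parameter: V1, covariate: dialysis, form: factor_if_flag, value: 0.5}
omega:
  names: [CL, V1, V2]
  matrix:
    - [0.158404, 0.0, 0.0]
    - [0.0, 0.665856, 0.0]
    - [0.0, 0.0, 0.326041]
residual_error:
  additive: 0.0
  proportional: 0.227
crcl_variant: cockcroft_gault_total_body_weight
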