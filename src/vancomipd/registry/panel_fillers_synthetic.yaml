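# SYNTHETIC panel fillers.
#
# The multi-model machinery (model selection / model averaging) needs a panel
# of more than one model to be non-trivial. The published panel members other
# than the reference model are not shipped; these two documents are synthetic
# stand-ins (a one-compartment simplification and a perturbed two-compartment
# variant) constructed for this package. Replace with registry files of the
# published models for real use.
model_id: synthetic_1cmt
compartments: 1
parameters:
  CL: 3.8    # L/h
  V1: 52.0   # L
covariate_relations:
  - {parameter: CL, covariate: crcl_cg, form: proportional, value: 1.0, reference: 100.0}
  - {parameter: CL, covariate: dialysis, form: factor_if_flag, value: 0.6}
  - {parameter: V1, covariate: total_body_weight, form: power, value: 1.0, reference: 70.0}
omega:
  names: [CL, V1]
  matrix:
    - [0.09, 0.0]
    - [0.0, 0.25]
residual_error:
  additive: 1.5
  proportional: 0.15
crcl_variant: cockcroft_gault_total_body_weight
notes: synthetic filler model (not a published vancomycin model)
---
model_id: synthetic_2cmt
compartments: 2
parameters:
  CL: 5.2    # L/h
  V1: 44.0   # L
  Q: 4.0     # L/h
  V2: 55.0   # L
covariate_relations:
  - {parameter: CL, covariate: crcl_cg, form: power, value: 0.65, reference: 100.0}
  - {parameter: V1, covariate: total_body_weight, form: power, value: 1.0, reference: 75.0}
omega:
  names: [CL, V1]
  matrix:
    - [0.12, 0.02]
    - [0.02, 0.30]
residual_error:
  additive: 0.8
  proportional: 0.20
crcl_variant: cockcroft_gault_total_body_weight
notes: synthetic filler model (not a published vancomycin model)
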