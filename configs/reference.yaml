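# Reference run configuration: the final vancomycin model at its published
# estimates, dosing simulations only (no fitting).  Use with
#   vancopk run --config configs/reference.yaml --out runs/reference
seed: 1
fit_enabled: false
model:
  structural: one_compartment
  error_kind: additive
  relations:
    - {parameter: CL, covariate: CRCL, form: linear_centered, center: 101.15}
    - {parameter: CL, covariate: WT, form: linear_centered, center: 75.0}
  fixed_values:
    tvcl: 2.45
    tvv: 22.6
    beta_CL_CRCL: 0.0046
    beta_CL_WT: -0.011
    omega2_cl: 0.012769   # (11.3% CV)^2
    omega2_v: 0.051984    # (22.8% CV)^2
    sigma_add: 3.07
scm:
  enabled: false
evaluation:
  bootstrap_enabled: false
  vpc_enabled: false
dosing:
  enabled: true
  crcl_levels: [20.0, 60.0, 100.0, 140.0]
  ttcr: [10.0, 20.0]
  tau: 12.0
  t_inf: 0.5
  n: 1000
  common_dose: 1000.0
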