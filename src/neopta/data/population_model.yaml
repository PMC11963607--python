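# Neonatal amikacin population PK model configuration (schema v1).
#
# Two-compartment disposition with covariate-driven clearance:
#   CL  = theta.CL * (bw_birth_g/1750)^1.34 * (1 + 0.07*(pna_days - 2))
#              * (1 - 0.16*ibuprofen) * exp(eta_CL)
#   V1  = theta.V1 * (bw_current_g/1760)^0.919 * exp(eta_V1)
# Q and V2 are size-scaled with the V1 covariate factor (scaling block).
# Reference neonate: birth weight 1750 g, current weight 1760 g, PNA 2 days.
# Constants calibrated to published neonatal amikacin kinetics; see
# docs/methods.md for the calibration rationale.
schema_version: 1
model:
  theta:
    CL: 0.084     # L/h at reference covariates
    V1: 0.833     # L at reference covariates (~0.47 L/kg)
    Q: 0.05       # L/h, inter-compartmental clearance at reference size
    V2: 0.15      # L, peripheral volume at reference size
  covariates:
    - target: CL
      kind: power
      covariate: bw_birth_g
      reference: 1750
      coefficient: 1.34
    - target: CL
      kind: linear_slope
      covariate: pna_days
      reference: 2
      coefficient: 0.07
    - target: CL
      kind: fractional_change
      covariate: ibuprofen
      coefficient: -0.16
    - target: V1
      kind: power
      covariate: bw_current_g
      reference: 1760
      coefficient: 0.919
  iiv:
    omega_CL: {value: 0.25, fixed: false}
    omega_V1: {value: 0.30, fixed: true}   # not estimable from sparse TDM; fixed
  residual:
    sigma_prop: 0.10   # proportional residual SD (fraction)
    sigma_add: 0.40    # additive residual SD (mg/L)
  scaling:
    q_with_v1: true
    v2_with_v1: true
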