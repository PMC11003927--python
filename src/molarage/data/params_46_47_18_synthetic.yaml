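# SYNTHETIC parameter set for the molar combination 46-47-18.
#
# This file is a synthetic stand-in, not estimates from any real cohort:
# the per-tooth coefficients and residual scales were fixed once to
# magnitudes realistic for the log tissue ratio of sub-adult molars
# (responses near -2 to -3.6 over ages 14-24, negative age slopes, third
# molar most informative).  It parameterises worked examples, simulations
# and tests; do not interpret it as a fitted reference model.
combination: {first: 46, second: 47, third: 18}
tooth_46:
  sex_structure: FULL_INTERACTION
  variance_weight: INV_AGE
  beta0: -1.35
  beta1: -0.072
  beta2: 0.30
  beta3: -0.022
  sigma: 0.050
tooth_47:
  sex_structure: SLOPES_ONLY
  variance_weight: INV_AGE
  beta0: -1.55
  beta1: -0.055
  beta2: 0.0
  beta3: -0.010
  sigma: 0.045
tooth_18:
  sex_structure: FULL_INTERACTION
  variance_weight: CONSTANT
  beta0: -1.20
  beta1: -0.055
  beta2: 0.28
  beta3: -0.018
  sigma: 0.16
correlations: {rho_12: 0.620, rho_13: 0.430, rho_23: 0.598}
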