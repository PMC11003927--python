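# Packaged per-tooth model configurations (AIC-selected defaults):
# sex structure of the mean and variance weighting for each of the
# twelve molars.  Weights follow the WLS convention: variance = sigma^2/w.
tooth_16: {sex_structure: ADDITIVE, variance_weight: INV_AGE}
tooth_17: {sex_structure: ADDITIVE, variance_weight: CONSTANT}
tooth_18: {sex_structure: FULL_INTERACTION, variance_weight: CONSTANT}
tooth_26: {sex_structure: ADDITIVE, variance_weight: INV_AGE}
tooth_27: {sex_structure: ADDITIVE, variance_weight: CONSTANT}
tooth_28: {sex_structure: ADDITIVE, variance_weight: CONSTANT}
tooth_36: {sex_structure: ADDITIVE, variance_weight: INV_AGE}
tooth_37: {sex_structure: SLOPES_ONLY, variance_weight: INV_AGE}
tooth_38: {sex_structure: COMMON, variance_weight: AGE}
tooth_46: {sex_structure: FULL_INTERACTION, variance_weight: INV_AGE}
tooth_47: {sex_structure: SLOPES_ONLY, variance_weight: INV_AGE}
tooth_48: {sex_structure: COMMON, variance_weight: AGE}
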