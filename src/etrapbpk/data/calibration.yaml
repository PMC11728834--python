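# Calibrated model constants (see scripts/calibrate.py for their derivation).
# cellular permeability law: P = a * 10^logP * MW_eff^(-b)  [cm/min]
# 'a' is anchored so that the law reproduces the reported intestinal
# permeability of etrasimod (0.02 cm/min) at logP 5.73, MW_eff 406.5.
# hepatic uptake: PS = P_cell * liver_specific_surface * V_liver
# liver_specific_surface is the effective hepatocyte permeation area per litre
# of liver tissue; with it the healthy hepatic uptake PS sits several-fold
# above the total metabolic intrinsic clearance (passive-uptake dominated but
# finite). version: 1
permeability_a: 1016.89
permeability_b: 4.0
liver_specific_surface_cm2_per_l: 135000.0
gut_effective_surface_cm2: 2000.0
gut_lumen_volume_l: 1.0
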