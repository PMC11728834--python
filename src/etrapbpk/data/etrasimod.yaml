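# Etrasimod drug parameters (model input values).
# Units are explicit in key names. version: 1
name: etrasimod
molecular_weight_g_per_mol: 457.493
effective_molecular_weight_g_per_mol: 406.5
log_lipophilicity: 5.73
pka: 4.26
acid_base_type: acid
solubility_mg_per_ml: 0.000477
fraction_unbound: 0.021          # plasma protein binding 97.9%
blood_to_plasma_ratio: 0.66
intestinal_permeability_cm_per_min: 0.02
dissolution_t50_min: 120.0       # Weibull time to 50% dissolved
# shape is not reported for the tablet; 2.0 places the predicted single-dose
# time-to-peak at the reported median (4 h, observed range 2-8 h), whereas a
# first-order profile (shape 1) leaves a dissolution tail that pushes the
# predicted peak past 8 h
dissolution_shape: 2.0
# specific intrinsic clearance in presence of recombinant enzymes, uL/min/pmol
enzyme_clint_ul_per_min_per_pmol:
  CYP2C8: 0.01157
  CYP2C9: 0.08525
  CYP3A4: 0.01640
  CYP2J2: 0.01872
  CYP2C19: 0.01331
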