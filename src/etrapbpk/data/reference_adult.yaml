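# Reference healthy adult (73 kg, 30 y) scalar physiology.
# Enzyme abundances are whole-liver amounts (umol). Their ratios are fixed by
# the reported fraction-metabolized vector for etrasimod (CYP2C8 0.38,
# CYP2C9 0.37, CYP3A4 0.22, CYP2C19 0.01, CYP2J2 0.01) combined with the
# recombinant-enzyme specific intrinsic clearances; the overall scale was
# solved once with scripts/calibrate.py against the healthy 2 mg single-dose
# exposure anchor. Magnitudes are physiological (whole-liver CYP3A4 of order
# 10 umol). version: 1
weight_kg: 73.0
age_years: 30.0
hematocrit: 0.45
albumin_ratio: 1.0
agp_ratio: 1.0
gfr_ratio: 1.0
# whole-liver enzyme amounts, umol (calibrated; see scripts/calibrate.py)
enzyme_abundance_umol:
  CYP2C8: 36.99
  CYP2C9: 4.889
  CYP3A4: 15.11
  CYP2C19: 0.8463
  CYP2J2: 0.6017
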