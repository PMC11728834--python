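# Pathophysiological alterations in chronic liver disease by Child-Pugh grade.
# All rows are fractions of healthy-control values except hematocrit, which is
# the absolute hematocrit (healthy reference 0.45). CYP activity rows are
# whole-liver activity as a fraction of control. version: 1
parameter,cp_a,cp_b,cp_c
portal_vein_flow,0.40,0.36,0.04
hepatic_artery_flow,1.3,2.3,3.4
renal_flow,0.88,0.65,0.48
cardiac_index,1.11,1.27,1.36
other_organ_flow,1.75,2.25,2.75
albumin,0.81,0.68,0.50
agp,0.60,0.56,0.30
hematocrit,0.39,0.37,0.35
functional_liver_mass,0.69,0.55,0.28
gfr,1.0,0.70,0.36
cyp3a4_activity,1.0,0.40,0.40
cyp2j2_activity,1.0,1.0,1.0
cyp2c8_activity,0.69,0.52,0.33
cyp2c9_activity,0.69,0.52,0.33
cyp2c19_activity,0.32,0.26,0.12
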