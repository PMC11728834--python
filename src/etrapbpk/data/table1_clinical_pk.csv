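# Observed clinical PK of etrasimod (phase-1 trials; mean (SD)).
# weight_kind: weight = body weight in kg; bmi = body-mass index in kg/m^2
# (for BMI-only studies a derived weight of BMI x 1.7^2 m^2 is a stated
# convention of this package, flag derived_weight). version: 1
study,regimen,dose_mg,n,male_pct,age_mean,age_sd,weight_kind,weight_mean,weight_sd,auc_inf_mean,auc_inf_sd,cmax_mean,cmax_sd
single_dose_build_1,single,1,18,68.4,32,8.1,weight,75.7,11.4,763,207,18.8,3.3
ddi_control_cohort_a,single,1,19,73.7,35.3,10.4,weight,73.5,14.2,759,196,19.0,4.4
ddi_control_cohort_b,single,1,19,36.8,36.4,10.6,weight,77.1,16.5,802,232,19.5,5.0
ddi_control_cohort_c,single,2,18,83.3,39.4,9.1,weight,80.6,9.5,1510,488,34.2,11.1
single_dose_build_2,single,2,8,100,31,6.6,weight,77.3,11.48,1900,596,42.5,10.2
sad_0p1,single,0.1,6,66.7,27.3,5.8,bmi,27.8,4.6,79.8,21.3,1.7,0.6
sad_0p35,single,0.35,6,33.3,25.8,4.4,bmi,30.0,4.9,268,31.0,6.3,0.4
sad_1,single,1,6,50.0,31.5,6.4,bmi,29.3,3.8,793,168,17.2,5.5
sad_3,single,3,6,66.7,31.0,7.1,bmi,27.2,4.7,2600,840,60.5,11.7
sad_5,single,5,6,33.3,33.0,9.4,bmi,27.2,6.4,4390,610,102,19.1
mad_0p7,qd21,0.7,10,50.0,34.2,8.8,bmi,28.9,4.5,596,121,30.8,6.6
mad_1p35,qd21,1.35,10,30.0,31.4,9.0,bmi,26.9,3.1,1197,226,63.5,11.8
mad_2,qd21,2,10,40.0,30.1,7.0,bmi,27.0,5.8,2163,489,113,27.5
mad_esc_0p35_2,esc_0p35_2,2,10,50.0,32.8,6.0,bmi,27.2,2.1,1513,359,80.5,17.4
mad_esc_0p5_3,esc_0p5_3,3,10,40.0,29.0,7.2,bmi,27.7,2.2,2867,376,151,19.0
mad_esc_2_3_4,esc_2_3_4,4,30,,,,weight,,,2885,793,163,46.7
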