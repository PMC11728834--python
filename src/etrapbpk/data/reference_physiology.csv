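# Reference adult physiology (73 kg, 30 y) for the whole-body PBPK model.
# Volumes/flows: ICRP-89 / Davies & Morris style reference-man values as used
# across the open PBPK literature; cardiac output 360 L/h (6 L/min).
# Tissue composition fractions (extracellular water f_ew, intracellular water
# f_iw, neutral lipid f_nl, neutral phospholipid f_np), acidic phospholipid
# concentration (ap, mg/g), and tissue:plasma albumin (albumin_ratio) and
# lipoprotein (lipoprotein_ratio) ratios follow the tissue-composition tables
# of the Rodgers-Rowland partitioning literature.
# blood_flow is the arterial-side regional flow (L/h); lung carries the full
# cardiac output in series; blood pools have zero regional flow.
# version: 1
organ,volume_l,blood_flow_l_per_h,f_ew,f_iw,f_nl,f_np,ap_mg_per_g,albumin_ratio,lipoprotein_ratio
lung,0.5,360.0,0.336,0.446,0.022,0.013,3.91,0.212,0.168
heart,0.33,14.4,0.320,0.456,0.014,0.011,2.25,0.157,0.160
brain,1.45,43.2,0.162,0.620,0.039,0.0015,0.40,0.048,0.041
muscle,29.0,45.0,0.118,0.630,0.010,0.0072,1.53,0.064,0.059
adipose,12.0,15.6,0.135,0.017,0.790,0.0016,0.40,0.049,0.068
skin,3.3,18.0,0.382,0.291,0.060,0.0044,1.32,0.277,0.096
bone,10.0,15.0,0.100,0.346,0.017,0.0017,0.67,0.100,0.050
kidney,0.31,66.0,0.273,0.483,0.012,0.024,5.03,0.130,0.137
gut,1.2,54.0,0.282,0.475,0.038,0.0125,2.41,0.158,0.141
spleen,0.18,11.5,0.207,0.579,0.0077,0.0113,3.18,0.097,0.207
liver,1.8,18.0,0.161,0.573,0.014,0.024,4.56,0.086,0.161
rest-of-body,7.0,59.3,0.118,0.630,0.010,0.0072,1.53,0.064,0.059
arterial blood,1.7,0.0,0,0,0,0,0,0,0
venous blood,3.9,0.0,0,0,0,0,0,0,0
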