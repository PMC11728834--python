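# Observed (label) vs predicted etrasimod AUC_inf (ng*h/mL) in healthy adults
# and Child-Pugh A/B/C hepatic impairment, with printed fold errors and the
# printed percent increases over healthy. version: 1
population,observed,observed_pct_increase,predicted,predicted_pct_increase,fold_error
healthy,1510,,1750,,1.16
cp_a,1706,13,1894,12.50,1.11
cp_b,1948,29,2208,28.40,1.13
cp_c,2371,57,2526,52.4,1.07
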