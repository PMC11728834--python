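# Rifampicin as a CYP inducer (perpetrator).
# EC50 (umol/L): inducer concentration at half-maximal induction; Emax:
# maximal fold-increase above baseline activity. The default exposure is a
# constant unbound steady-state concentration: 600 mg QD gives average total
# plasma ~4-5 ug/mL; with fu ~0.17 and MW 822.94 g/mol the unbound molar
# concentration is ~1 umol/L. Assumption of this package. version: 1
name: rifampicin
mode: induction
induction:
  CYP3A4: {ec50_umol_per_l: 0.34, emax: 9.0}
  CYP2C8: {ec50_umol_per_l: 0.34, emax: 3.2}
default_unbound_concentration_umol_per_l: 1.0
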