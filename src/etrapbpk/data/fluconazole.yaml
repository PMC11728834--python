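# Fluconazole as a competitive CYP inhibitor (perpetrator).
# Ki: dissociation constant of the inhibitor-enzyme complex, umol/L.
# The default exposure is a constant unbound steady-state concentration:
# 400 mg QD gives total plasma ~20 ug/mL; with fu 0.89 and MW 306.27 g/mol
# the unbound molar concentration is ~58 umol/L. This regimen-level default is
# an assumption of this package, not a fitted quantity. version: 1
name: fluconazole
mode: inhibition
ki_umol_per_l:
  CYP3A4: 10.7
  CYP2C9: 19.60
  CYP2C19: 1.74
default_unbound_concentration_umol_per_l: 58.0
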