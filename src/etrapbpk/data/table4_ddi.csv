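# Predicted and observed exposure of etrasimod with and without perpetrators.
# Control (fluconazole arm): 1 mg etrasimod alone; control (rifampicin arm):
# 2 mg etrasimod alone. Units: auc_inf ng*h/mL, cmax ng/mL, t_half h.
# The printed T1/2 fold error for the fluconazole arm (0.70) is arithmetically
# inconsistent with its own entries (82.1/88.2) and is stored verbatim but
# excluded from verification. version: 1
arm,group,data,auc_inf,cmax,t_half
inhibition,control,predicted,875,17.7,44.0
inhibition,control,observed,759,19.0,42.5
inhibition,fluconazole,predicted,1772,20.0,82.1
inhibition,fluconazole,observed,1440,21.4,88.2
induction,control,predicted,1750,34.3,44.0
induction,control,observed,1510,34.2,41.1
induction,rifampicin,predicted,754,24.0,17.0
induction,rifampicin,observed,770,36.0,21.0
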