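metric,lower,upper
EDV_mL,102,202
ESV_mL,24,92
SV_mL,57,150
LVEF_pct,50,65
CO_Lmin,4,8
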