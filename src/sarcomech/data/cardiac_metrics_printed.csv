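id,series,EDV_mL,ESV_mL,SV_mL,LVEF_pct,CO_Lmin,EDV_pct,ESV_pct,SV_pct,LVEF_pct_chg,CO_pct
S00,S0,142.789,65.248,77.541,54.305,4.652,,,,,
S01,S0,147.147,79.149,67.998,46.211,4.080,3.05,21.30,-12.31,-14.90,-12.30
S02,S0,145.086,71.815,73.271,50.502,4.396,1.61,10.06,-5.51,-7.00,-5.50
S03,S0,139.946,59.589,80.357,57.420,4.821,-1.99,-8.67,3.63,5.74,3.63
S04,S0,136.392,54.962,81.430,59.703,4.886,-4.48,-15.76,5.02,9.94,5.03
S11,S1,85.827,50.745,35.082,40.875,2.105,-39.89,-22.23,-54.76,-24.73,-54.75
S12,S1,117.718,54.500,63.218,53.703,3.793,-17.56,-16.47,-18.47,-1.11,-18.47
S13,S1,143.697,71.574,72.123,50.191,4.327,0.64,9.70,-6.99,-7.58,-6.99
S14,S1,144.654,78.371,66.283,45.822,3.977,1.31,20.11,-14.52,-15.62,-14.51
S21,S2,91.362,62.443,28.919,31.653,1.735,-36.02,-4.30,-62.70,-41.71,-62.70
S22,S2,112.003,60.796,51.207,45.719,3.072,-21.56,-6.82,-33.96,-15.81,-33.96
S23,S2,140.746,65.127,75.619,53.727,4.537,-1.43,-0.19,-2.48,-1.06,-2.47
S24,S2,137.821,65.020,72.801,52.823,4.368,-3.48,-0.35,-6.11,-2.73,-6.10
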