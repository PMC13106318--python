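# Default constitutive parameter sets.
# Flat key-value document; one section per parameter block.
# Units: stresses/moduli MPa, times s, sarcomere lengths um,
# B per mm, m s per mm.

[passive]
a = 0.004
b = 8.0
a_f = 0.005
b_f = 5.0
a_s = 0.002
b_s = 2.0
a_fs = 0.0
b_fs = 1.0
D = 0.001

[active]
T_max = 0.1
Ca0 = 4.35
Ca0_max = 4.35
B = 4750.0
t0 = 0.1
m = 1048.9
b_relax = -1.429
L_r = 1.85
L_0 = 1.58

[surrogate]
# frozen calibration of the 0D closed loop (volumes mL, pressures mmHg,
# resistances mmHg.s/mL, compliances mL/mmHg, elastance mmHg/mL)
V_wall = 90.0
V_ref = 100.0
E_la = 1.0
V_la_ref = 0.0
C_art = 1.5
C_ven = 8.0
R_mv = 0.12
R_av = 0.08
R_p = 1.1
R_vr = 0.05
V_total = 830.0
cycle_length = 1.0
beat_duration = 0.5
V_lv_init = 120.0
envelope_at_reference = true
wall_recoil = false
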