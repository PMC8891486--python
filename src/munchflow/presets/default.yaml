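# Baseline constants (tobacco loading kinetics, wet soil).
af: 0.3
ags: 2.0
g_max: 400.0
gs_psi50: -1.5
K_max_m: 20.0
K_max_x: 20.0
alpha: 2.0
psi50_m: -2.0
pi_o: -1.2
epsilon: 12.0
LA: 4.74e-3
R_p: 2.4e+20
W_p: 3.57e-11
r: 5.5e-6
M_S: 3.3
V_maxL: 1.58e-7
beta: 0.0
mm: 342.3
Rc: 8.3
T: 293.0
S_l: 7.3e-16
leak_on: false
R_L: 0.25
psi_s: -0.001
VPD: 9.9e-3
c_a: 400.0
A_max: 20.0
p_cap: 50.0
psi_sink: 0.0
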