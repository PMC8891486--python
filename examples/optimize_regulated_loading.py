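"""Constrained optimization of transporter kinetics.

Grid-search the maximum loading rate V_maxL (Arabidopsis..wheat span) and
the pressure-downregulation strength beta, keeping only combinations whose
12-h tail loading pressure stays in the empirically viable 0.6-2.4 MPa
window, and report the export-maximizing pair. A 13x13 grid keeps this
example quick; the headline analyses use 25x25.
"""

from munchflow import optimize_loading

for preset, psi_s in [("R2", -0.001), ("R4", -1.0)]:
    opt = optimize_loading(preset, psi_s, n_vmaxl=13, n_beta=13)
    print(f"{preset} at psi_s = {psi_s} MPa:")
    print(f"  best export  : {opt.S_tot_mg:.2f} mg "
          f"({opt.n_feasible} feasible cells)")
    print(f"  at V_maxL    : {opt.V_maxL:.3g} mol m-2 s-1")
    print(f"  with beta    : {opt.beta:.3g} MPa-1")

# Drier soil and higher structural resistance both demand stronger
# pressure-coupled downregulation (larger beta) at the optimum.
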