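"""The viscosity-limitation failure mode.

A ~25% increase in structural resistance over the R2 class transports fine
in wet soil but fails under drought: sucrose keeps accumulating in the
loading zone, viscosity and resistance climb faster than turgor, and flow
effectively stops.
"""

from munchflow import load_preset, run

for label, psi_s in [("wet (-0.001 MPa)", -0.001), ("dry (-1 MPa)", -1.0)]:
    params = load_preset("R2", psi_s=psi_s).with_overrides(R_p=5.4e20 * 1.25)
    traj, outcome = run(params)
    s = outcome.stats
    print(f"R2 x 1.25, {label}: {outcome.status}")
    print(f"  exported {traj.stot_mg:6.2f} mg; "
          f"tail P_l = {s['P_l_tail']:.2f} MPa; "
          f"tail viscosity = {s['v_tail']*1e9:.3g} mPa s")

# The dry run is classified runaway_viscosity: concentration and pressure
# grow without bound while export stalls after the first hours.
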