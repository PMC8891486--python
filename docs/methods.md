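# Methods

## Model structure and assumptions

The simulated plant is one source leaf, one root-to-leaf xylem path, and
one representative sieve tube running from a loading zone (in the leaf) to
an unloading zone (at the sink). Key simplifications:

1. Loading and unloading are both active (transporter-mediated,
   Michaelis–Menten in the local sucrose concentration); unloading never
   limits export (`V_maxU = 1.2 × V_maxL` by default, and within a step
   the unloading zone may export everything it received).
2. All photosynthate is immediately available to the loading apoplasm; no
   pre-phloem pathway is modelled.
3. Phloem water is not tracked explicitly: the loading zone is in water
   potential equilibrium with the leaf xylem, and each zone's volume
   `W_p` is constant, so zone concentration is pool/volume.
4. The unloading zone equilibrates with a *well-hydrated sink*
   (`psi_sink`, default 0 MPa), not with the drying source soil column.
   With a soil-equilibrated sink, drought would *widen* the source–sink
   turgor difference and make transport easier — the opposite of the
   drought responses this model family exhibits (rising viscosity,
   falling velocity, viscosity-limited failure under drought). The
   parameter is config-exposed; setting `psi_sink = psi_s` recovers the
   soil-equilibrated variant.
5. The xylem water store is steady; only the mesophyll volume integrates.
   Xylem conductance is constant at `K_max,x` (its vulnerability threshold
   lies below the water potentials reached here).
6. Light is saturating and constant; no energy balance or leaf
   temperature; mesophyll sugar does not feed back on mesophyll water
   potential.
7. One viscosity per step, evaluated at the loading-zone concentration,
   scales the whole conduit's resistance (`R_conduit = R_p · v`).
8. Loading-zone turgor in 0.6–2.4 MPa is "viable" (the range of published
   pressure-probe measurements); runs ending outside it are biologically
   unrealistic and are excluded from optimization feasibility.

## Parameters

Defaults (all config-exposed, flat YAML; `load_preset` merges presets over
`presets/default.yaml`):

| symbol | meaning | default | units |
|---|---|---|---|
| `af` | leaf apoplasmic fraction | 0.3 | – |
| `g_max` | max stomatal conductance | 400 | mmol m⁻² s⁻¹ |
| `gs_psi50`, `ags` | stomatal closure midpoint / slope | −1.5, 2.0 | MPa, MPa⁻¹ |
| `K_max_m`, `K_max_x` | max mesophyll / xylem conductance | 20, 20 | mmol m⁻² s⁻¹ MPa⁻¹ |
| `psi50_m`, `alpha` | mesophyll vulnerability midpoint / slope | −2.0, 2.0 | MPa, – |
| `pi_o`, `epsilon` | osmotic potential at full turgor, elastic modulus | −1.2, 12 | MPa |
| `V_sat_m` | saturated mesophyll water volume | `LA × 1.5e-4` | m³ |
| `LA` | leaf area | 4.74e-3 | m² |
| `R_p` | sieve-tube structural resistance | 2.4e20 (R1) … 8.5e21 (R5) | m⁻³ |
| `W_p` | phloem-zone water volume | 3.57e-11 (R1/R2), 1.04e-8 (R3), 1.37e-8 (R4/R5) | m³ |
| `r` | conduit radius | 5.5e-6 | m |
| `M_S` | sucrose affinity of the transporter | 3.3 | mol m⁻³ |
| `V_maxL` | max loading rate | 1.58e-7 (tobacco) | mol m⁻² s⁻¹ |
| `beta` | pressure-downregulation strength | 0 | MPa⁻¹ |
| `R_L` | leaf respiration | 0.25 | µmol C m⁻² s⁻¹ |
| `psi_s`, `VPD` | soil water potential, vapor pressure deficit | −0.001, 9.9e-3 | MPa, mole fraction |
| `T`, `Rc`, `mm` | temperature, gas constant, sucrose molar mass | 293, 8.3, 342.3 | K, m³ Pa K⁻¹ mol⁻¹, g mol⁻¹ |

Four auxiliary inputs are not constrained by the published tables and are
this package's own documented choices:

- **Pressure–volume constants** (`pi_o = −1.2` MPa, `epsilon = 12` MPa,
  `V_sat_m ≈ 150 g m⁻²` leaf water): typical mesophyte values. The
  turgor-loss point follows the identity `π_tlp = π_o ε/(π_o+ε)`
  (−1.33 MPa here). Because export is loading- or transport-limited, the
  downstream results are insensitive to these within realistic ranges;
  they mainly set how `Ψ_m` maps to `g_s` closure.
- **gs → A_net response**: rectangular hyperbola
  `A_net = A_max k g_s/(A_max + k g_s) − R_L` with `A_max = 20`
  µmol m⁻² s⁻¹ and `k = 9·A_max/g_max` (so the gross rate at `g_max` is
  90% of `A_max`). Only smoothness, saturation and monotonicity matter
  downstream: at the default `V_maxL`, carbon supply exceeds loading
  capacity ~9-fold, so export is loading-limited and insensitive to the
  exact photosynthesis constants.
- **Sap viscosity**: the Génotelle sucrose-solution correlation,
  `log10 η[mPa s] = 22.46 N − 0.114 + φ(1.1 + 43.1 N^{1.25})` with
  sucrose mole fraction `N` and `φ = (30−T_C)/(91+T_C)`. The molar
  concentration is converted to a mass fraction through a
  concentration-dependent solution density
  (`ρ[g cm⁻³] = 0.9982 + 0.3875w + 0.1694w²`, fixed-point solve,
  contraction with |g′| < 0.55). Dilute limit ≈ 0.97e-9 MPa s at 293 K
  (pure water ≈ 1.0e-9). Above ~67% mass fraction (saturation at 20 °C)
  the value is flagged `beyond_validity`; the mass fraction is clamped at
  0.95 so deliberately supersaturated runaway regimes keep a finite,
  monotone extrapolation.
- **Leaf volume** for the phloem-volume sweep (0.002–0.8% of leaf
  volume): 1.785e-6 m³, anchored by the smallest R1/R2 zone volume
  (3.57e-11 m³) being 0.002% of it; equivalent to a 377 µm-thick leaf at
  this leaf area.

## Numerics

- Explicit Euler, `dt = 1 s`, 12 h (43 200 steps), single pass per step in
  the order: water balance → assimilation → loading (at the *previous*
  step's `P_l`) → osmotic/turgor/viscosity/resistance/flow → sucrose pool
  updates. All formulas live in one numba-compiled kernel that both the
  public per-operation API and the integrator call, so tests exercise the
  exact compiled code. Deterministic: reruns are bit-identical.
- Stability: the fastest feedback (mesophyll water at wet soil) has gain
  ≈ 0.05 per 1-s step; the sucrose pools’ relaxation rates stay well
  below 1 s⁻¹ except the unloading pool at high `V_maxU`, which is
  flux-limited (a pool can export at most its content per step, so no
  pool ever goes negative and the "export everything that arrives"
  assumption is realized exactly). Timestep-halving changes 12-h export
  by < 1% and final `Ψ_m` by < 0.01 MPa (tested).
- Reverse flow (`P_l < P_u`) advects at the upstream (unloading-zone)
  concentration; the optional membrane leak term
  (`S_l`, lateral area `2πr·W_p/(πr²)`) is off by default.
- A hard cap `P_l > 50 MPa` stops hopeless runaway runs early; such runs
  are reported censored, with export totals from the integrated portion.
- Sucrose amounts are molar internally; milligram values appear only at
  reporting boundaries (`S_tot[mg] = S_tot[mol]·342.3·10³`).

## Run classification

Over the final hour of a run: `steady` needs relative loading-zone
concentration drift < 1e-3 *and* loading/transport/unloading flux
imbalance < 0.1%; `runaway_viscosity` is a pressure-cap hit or positive,
accelerating drift with viscosity more than 10× its value an hour
earlier; a converged run whose tail pressure leaves the 0.6–2.4 MPa
window is `pressure_out_of_bounds`; anything still drifting but
decelerating is `unconverged`. The fifth label exists because the larger
phloem volumes (R3–R5) relax on ~1e4 s timescales, so a legitimate 12-h
run can end mid-approach; experiment feasibility therefore follows the
12-h snapshot protocol (not runaway/failed, tail pressure in the window)
rather than demanding full convergence. All thresholds are
config-exposed (`SteadyCriteria`); none are tuned per scenario.

## Optimization

`optimize_loading` scans an exhaustive grid — `V_maxL` log-spaced over
the measured species span (1.30e-8…2.30e-6 mol m⁻² s⁻¹), β linear over
[0, 3] by default (published optima all fall below 2; [0, 10] available) —
runs each cell's full 12-h simulation, and returns the feasible argmax
with ties broken toward smaller `V_maxL`, then smaller β. The export
surface is nearly flat (< 2.5%) along the contour where tail pressure
rides the 2.4 MPa window edge, so the argmax *coordinates* (unlike the
export maximum) are sensitive to grid discretization; the default is
25×25.

## What the tests do and do not show

The test suite verifies structural invariants (per-step sucrose
conservation to 1e-9, exact β = 0 reduction, PV-curve continuity,
closed-form vulnerability integral vs adaptive quadrature at 1e-8,
determinism), the regime map (which resistance/volume/drought
combinations seize from runaway viscosity, which pressures land in the
viable window), and the quantitative export values and percent changes
under the study conditions. Because the forcing is two constant scalars
(`psi_s`, `VPD`) and light is saturating, passing tests say nothing about
diurnal dynamics, canopy coupling, multi-sink competition, sieve-plate or
callose dynamics, or osmoregulation of the mesophyll — all outside this
model's scope.

## Known limitations

- Single conduit, single source and sink; no discretized pathway, so
  concentration gradients along the tube are not resolved.
- The pressure-coupled downregulation multiplier `e^{−βP_l}` is not
  clamped at 1: sub-atmospheric loading turgor up-regulates loading
  (logged when it happens; it occurs only transiently at startup).
- The unloading-zone turgor rests on the well-hydrated-sink choice
  (assumption 4 above); a sink sharing the source's soil column would
  behave qualitatively differently under drought.
- Problem sizes used throughout (12-h runs at 1-s steps, 25×25 grids,
  20-point volume sweeps) are the package's defaults chosen to resolve
  the regimes cleanly; all are arguments, not constants.
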