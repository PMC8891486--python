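"""Numba-compiled scalar kernels and the explicit-Euler integrator.

Everything numerical lives here; the public modules (`hydraulics`,
`phloem`, `engine`) are thin validated wrappers around these functions so
that the formulas used in tests and the formulas used inside the 43 200-step
integration loop are literally the same compiled code.

Unit system: SI with pressure in MPa (m3, mol, MPa, s, K). Conductances and
gas-exchange fluxes follow the leaf-physiology convention of mmol m-2 s-1
(water) and umol m-2 s-1 (CO2); conversions happen at the marked points.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter-vector layout (see params.ModelParams.to_vector)
# ---------------------------------------------------------------------------
AF, AGS, G_MAX, GS_PSI50, K_MAX_M, K_MAX_X, ALPHA, PSI50_M, PI_O, EPS, \
    V_SAT_M, LA, R_P, W_P, RADIUS, M_S, V_MAXL, V_MAXU, BETA, MM, RC, TEMP, \
    S_L, LEAK_ON, R_L, A_MAX, K_ASSIM, PSI_S, VPD, C_A, P_CAP, \
    PSI_SINK = range(32)
NPAR = 32

# trajectory-record column layout
C_T, C_WM, C_RWC, C_PSI_M, C_PSI_X, C_GS, C_E, C_ANET, C_INFLOW, \
    C_SM, C_CM, C_SPL, C_CPL, C_SU, C_CPU, C_PI_L, C_PI_U, C_PL, C_PU, \
    C_VISC, C_RCOND, C_FP, C_VS, C_LSUCL, C_LSUCU, C_ES, C_STOT, \
    C_VFLAG = range(28)
NCOL = 28

COLUMNS = (
    "t", "W_m", "RWC_m", "psi_m", "psi_x", "g_s", "E", "A_net", "inflow",
    "S_m", "C_m", "S_pL", "C_pL", "S_U", "C_pU", "pi_l", "pi_u", "P_l",
    "P_u", "v", "R_conduit", "F_p", "V_s", "L_sucL", "L_sucU", "E_s",
    "S_tot", "visc_flag",
)

# molar volume of liquid water per mmol (18.02 g/mol at 1 g/cm3)
V_W = 1.802e-8  # m3 mmol-1
MM_WATER = 18.015  # g mol-1
# mass fraction above which the sucrose-viscosity correlation is
# extrapolating past saturation at 20 C (~67 Brix)
W_SATURATION = 0.67
W_CLAMP = 0.95

STATUS_OK = 0
STATUS_NAN = 1
STATUS_PCAP = 2


@njit(cache=True)
def pv_water_potential(rwc, pi_o, af, eps):
    """Leaf water potential (MPa) from relative water content.

    Standard pressure-volume decomposition on symplastic water content
    Rs = (RWC - af)/(1 - af): solute potential pi_o/Rs plus turgor
    -pi_o + eps*(Rs - 1), the latter clamped at zero below the turgor
    loss point Rs_tlp = 1 + pi_o/eps.
    """
    rs = (rwc - af) / (1.0 - af)
    solute = pi_o / rs
    turgor = -pi_o + eps * (rs - 1.0)
    if turgor > 0.0:
        return solute + turgor
    return solute


@njit(cache=True)
def vulnerability_antiderivative(psi, kmax, alpha, psi50):
    """Closed-form antiderivative of the logistic vulnerability curve."""
    # (kmax/alpha) * ln(1 + exp(alpha*(psi - psi50))), written to avoid
    # overflow for large positive arguments
    x = alpha * (psi - psi50)
    if x > 35.0:
        return (kmax / alpha) * x + (kmax / alpha) * np.log1p(np.exp(-x))
    return (kmax / alpha) * np.log1p(np.exp(x))


@njit(cache=True)
def vulnerability_flow(psi_low, psi_high, kmax, alpha, psi50):
    """Integral of K(psi) over [psi_low, psi_high] (mmol m-2 s-1)."""
    return vulnerability_antiderivative(psi_high, kmax, alpha, psi50) - \
        vulnerability_antiderivative(psi_low, kmax, alpha, psi50)


@njit(cache=True)
def stomatal_conductance(psi_m, g_max, ags, gs_psi50):
    return g_max / (1.0 + np.exp(-ags * (psi_m - gs_psi50)))


@njit(cache=True)
def net_assimilation(gs, a_max, k_assim, r_d):
    """Saturating gs -> A_net response, net of dark respiration (umol m-2 s-1)."""
    if gs <= 0.0:
        return -r_d
    gross = a_max * k_assim * gs / (a_max + k_assim * gs)
    return gross - r_d


@njit(cache=True)
def mm_rate(vmax, conc, ms):
    return vmax * conc / (ms + conc)


@njit(cache=True)
def regulated_loading(vmax_l, conc, ms, p_l, beta):
    return vmax_l * np.exp(-beta * p_l) * conc / (ms + conc)


@njit(cache=True)
def solution_density(w):
    """Aqueous-sucrose solution density (g m-3) vs mass fraction at ~20 C."""
    return (0.9982 + 0.3875 * w + 0.1694 * w * w) * 1.0e6


@njit(cache=True)
def sucrose_mass_fraction(conc, mm, w_guess):
    """Mass fraction of sucrose from molar concentration (mol m-3).

    Solves w = conc*mm/rho(w) by fixed point (contraction, |g'| < 0.55);
    w_guess warm-starts the iteration inside the integrator. Clamped at
    W_CLAMP so runaway regimes keep a finite, monotone extrapolation.
    """
    if conc <= 0.0:
        return 0.0
    w = w_guess
    if w <= 0.0 or w >= W_CLAMP:
        w = 0.2
    for _ in range(60):
        w_new = conc * mm / solution_density(w)
        if w_new > W_CLAMP:
            w_new = W_CLAMP
        if abs(w_new - w) < 1.0e-13:
            w = w_new
            break
        w = w_new
    return w


@njit(cache=True)
def sap_viscosity_from_w(w, temp):
    """Genotelle sucrose-solution viscosity (MPa s) from mass fraction."""
    if w <= 0.0:
        n = 0.0
    else:
        n_suc = w / 342.3
        n_wat = (1.0 - w) / MM_WATER
        n = n_suc / (n_suc + n_wat)
    t_c = temp - 273.15
    phi = (30.0 - t_c) / (91.0 + t_c)
    if n > 0.0:
        log10_eta = 22.46 * n - 0.114 + phi * (1.1 + 43.1 * n ** 1.25)
    else:
        log10_eta = -0.114 + phi * 1.1
    return 10.0 ** log10_eta * 1.0e-9  # mPa s -> MPa s


@njit(cache=True)
def sap_viscosity(conc, temp, mm):
    """Phloem-sap viscosity (MPa s) at sucrose concentration conc (mol m-3).

    Returns (viscosity, beyond_validity) where the flag marks
    supersaturated concentrations on which the correlation extrapolates.
    """
    w = sucrose_mass_fraction(conc, mm, 0.2)
    return sap_viscosity_from_w(w, temp), w > W_SATURATION


@njit(cache=True)
def simulate(p, t_end, dt, stride):
    """Integrate the coupled model with the one-pass explicit scheme.

    Per step: (1) psi_m from W_m through the PV curve; (2) mesophyll flow
    from the vulnerability integral bounded by the new psi_m and the
    previous psi_x; (3) g_s from the new psi_m; (4) psi_x update;
    (5) transpiration and W_m update; (6) A_net; (7) phloem loading at the
    previous step's P_l; (8) osmotic/turgor/viscosity/resistance/flow;
    (9) sucrose pool updates with within-step flux limiting.

    Returns (record, n_rows, status, t_stop).
    """
    n_steps = int(round(t_end / dt))
    rec_every = max(int(round(stride / dt)), 1)
    n_rec = n_steps // rec_every + 2
    rec = np.zeros((n_rec, NCOL))

    af = p[AF]
    pi_o = p[PI_O]
    eps = p[EPS]
    v_sat = p[V_SAT_M]
    la = p[LA]
    wp = p[W_P]
    ms = p[M_S]
    mm = p[MM]
    rct = p[RC] * p[TEMP] * 1.0e-6  # MPa per (mol m-3)
    area_r2 = np.pi * p[RADIUS] ** 2
    # lateral membrane area implied by the zone volume and conduit radius
    a_memb = 2.0 * np.pi * p[RADIUS] * (wp / area_r2)
    leak_coeff = p[S_L] * a_memb if p[LEAK_ON] > 0.5 else 0.0
    psi_s = p[PSI_S]

    # quiescent initial state: fully hydrated leaf, empty sucrose pools
    wm = v_sat
    psi_x = psi_s
    sm = 0.0
    spl = 0.0
    su = 0.0
    stot = 0.0
    p_l = psi_s  # zero concentration => P_l = psi_x = psi_s
    w_frac = 0.0  # viscosity mass-fraction warm start

    status = STATUS_OK
    t_stop = t_end
    irow = 0

    for i in range(n_steps):
        # --- water balance -------------------------------------------------
        rwc = wm / v_sat
        if rwc > 1.0:
            rwc = 1.0
        if rwc <= af:
            status = STATUS_NAN
            t_stop = i * dt
            break
        psi_m = pv_water_potential(rwc, pi_o, af, eps)
        inflow = vulnerability_flow(psi_m, psi_x, p[K_MAX_M], p[ALPHA],
                                    p[PSI50_M])
        gs = stomatal_conductance(psi_m, p[G_MAX], p[AGS], p[GS_PSI50])
        psi_x = psi_s - inflow / p[K_MAX_X]
        e_trans = gs * p[VPD]
        wm = wm + dt * la * V_W * (inflow - e_trans)

        # --- gas exchange --------------------------------------------------
        anet = net_assimilation(gs, p[A_MAX], p[K_ASSIM], p[R_L])
        a_suc = anet * 1.0e-6 / 12.0  # umol CO2 -> mol sucrose (12 C each)

        # --- phloem loading at the previous step's loading-zone turgor -----
        cm = sm / wm
        l_sucl = regulated_loading(p[V_MAXL], cm, ms, p_l, p[BETA])

        # --- osmotic / turgor / viscosity / flow ---------------------------
        cpl = spl / wp
        cpu = su / wp
        pi_l = -rct * cpl
        pi_u = -rct * cpu
        p_l = psi_x - pi_l
        p_u = p[PSI_SINK] - pi_u
        w_frac = sucrose_mass_fraction(cpl, mm, w_frac)
        visc = sap_viscosity_from_w(w_frac, p[TEMP])
        vflag = 1.0 if w_frac > W_SATURATION else 0.0
        r_cond = p[R_P] * visc
        f_p = (p_l - p_u) / r_cond
        v_s = f_p / area_r2
        # advect at the upstream concentration (upwinding)
        e_s = f_p * (cpl if f_p >= 0.0 else cpu)
        l_sucu = mm_rate(p[V_MAXU], cpu, ms)

        # --- sucrose pools, flux-limited so nothing goes negative ----------
        production = a_suc * la * dt
        avail_m = sm + (production if production > 0.0 else 0.0)
        load_amt = l_sucl * la * dt
        if load_amt > avail_m:
            load_amt = avail_m
        sm = sm + production - load_amt
        if sm < 0.0:
            sm = 0.0

        leak_amt = leak_coeff * cpl * dt
        exp_amt = e_s * dt
        if exp_amt > 0.0:
            cap = spl + load_amt - leak_amt
            if exp_amt > cap:
                exp_amt = cap if cap > 0.0 else 0.0
        elif exp_amt < -su:
            exp_amt = -su  # reverse flow cannot drain more than the pool
        spl = spl + load_amt - exp_amt - leak_amt
        if spl < 0.0:
            spl = 0.0

        unload_amt = l_sucu * la * dt
        cap_u = su + exp_amt
        if unload_amt > cap_u:
            unload_amt = cap_u if cap_u > 0.0 else 0.0
        su = su + exp_amt - unload_amt
        if su < 0.0:
            su = 0.0
        stot = stot + unload_amt

        bad = not (np.isfinite(wm) and np.isfinite(spl) and
                   np.isfinite(su) and np.isfinite(p_l) and
                   np.isfinite(f_p))
        record_now = ((i + 1) % rec_every == 0) or (i == n_steps - 1) or bad
        if record_now:
            row = rec[irow]
            row[C_T] = (i + 1) * dt
            row[C_WM] = wm
            row[C_RWC] = rwc
            row[C_PSI_M] = psi_m
            row[C_PSI_X] = psi_x
            row[C_GS] = gs
            row[C_E] = e_trans
            row[C_ANET] = anet
            row[C_INFLOW] = inflow
            row[C_SM] = sm
            row[C_CM] = cm
            row[C_SPL] = spl
            row[C_CPL] = cpl
            row[C_SU] = su
            row[C_CPU] = cpu
            row[C_PI_L] = pi_l
            row[C_PI_U] = pi_u
            row[C_PL] = p_l
            row[C_PU] = p_u
            row[C_VISC] = visc
            row[C_RCOND] = r_cond
            row[C_FP] = f_p
            row[C_VS] = v_s
            row[C_LSUCL] = l_sucl
            row[C_LSUCU] = l_sucu
            row[C_ES] = e_s
            row[C_STOT] = stot
            row[C_VFLAG] = vflag
            irow += 1

        if bad:
            status = STATUS_NAN
            t_stop = (i + 1) * dt
            break
        if p_l > p[P_CAP]:
            status = STATUS_PCAP
            t_stop = (i + 1) * dt
            break

    return rec[:irow], irow, status, t_stop
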