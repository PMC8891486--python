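"""Phloem biophysics: Michaelis-Menten loading/unloading, pressure-coupled
loading downregulation, van 't Hoff osmotic potential, sucrose-dependent sap
viscosity, Münch flow through a single sieve tube, and sucrose bookkeeping.

All sucrose amounts are molar internally; gram/milligram quantities appear
only at reporting boundaries (``stot_mg``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .params import ModelParams, ParameterError

__all__ = [
    "SucroseState", "PhloemState", "mm_rate", "regulated_loading",
    "osmotic_potential", "turgor", "sap_viscosity", "conduit_resistance",
    "phloem_flow", "sap_velocity", "sucrose_step", "stot_mg",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SucroseState:
    """Sucrose pools (mol) and the derived concentrations (mol m-3)."""

    S_m: float = 0.0     # mesophyll/apoplasmic sucrose
    S_pL: float = 0.0    # loading-zone sucrose
    S_U: float = 0.0     # unloading-zone sucrose
    S_tot: float = 0.0   # cumulative export to sinks

    def concentrations(self, W_m: float, W_p: float):
        return self.S_m / W_m, self.S_pL / W_p, self.S_U / W_p


@dataclass(frozen=True)
class PhloemState:
    """Derived phloem quantities for one instant."""

    pi_l: float          # loading-zone osmotic potential (MPa)
    pi_u: float          # unloading-zone osmotic potential (MPa)
    P_l: float           # loading-zone turgor (MPa)
    P_u: float           # unloading-zone turgor (MPa)
    v: float             # sap viscosity (MPa s)
    R_conduit: float     # conduit resistance (MPa s m-3)
    F_p: float           # volumetric flow (m3 s-1)
    V_s: float           # sap velocity (m s-1)
    E_s: float           # sucrose mass flow to the unloading zone (mol s-1)
    L_sucL: float        # loading rate (mol m-2 s-1)
    L_sucU: float        # unloading rate (mol m-2 s-1)
    beyond_validity: bool = False


def mm_rate(V_max: float, C: float, M_S: float) -> float:
    """Michaelis-Menten transporter rate V_max*C/(M_S + C)."""
    if C < 0:
        raise ParameterError("negative concentration (state corruption)")
    if V_max < 0 or M_S <= 0:
        raise ParameterError("need V_max >= 0 and M_S > 0")
    return float(K.mm_rate(V_max, C, M_S))


def regulated_loading(V_maxL: float, C: float, M_S: float, P_l: float,
                      beta: float) -> float:
    """Pressure-downregulated loading V_maxL*exp(-beta*P_l)*C/(M_S+C).

    With beta = 0 this is exactly the plain Michaelis-Menten rate. For
    sub-atmospheric turgor (P_l < 0) the multiplier exceeds one
    (up-regulation); this is permitted and logged.
    """
    if C < 0:
        raise ParameterError("negative concentration (state corruption)")
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    if not np.isfinite(P_l):
        raise ParameterError("P_l must be finite")
    if beta > 0 and P_l < 0:
        log.info("loading up-regulated: P_l=%.3f MPa < 0 with beta=%.3g",
                 P_l, beta)
    return float(K.regulated_loading(V_maxL, C, M_S, P_l, beta))


def osmotic_potential(C: float, Rc: float = 8.3, T: float = 293.0) -> float:
    """van 't Hoff osmotic potential pi = -Rc*T*C, returned in MPa."""
    if C < 0:
        raise ParameterError("concentration must be >= 0")
    return -Rc * T * C * 1.0e-6


def turgor(psi_zone: float, pi_zone: float) -> float:
    """Zone turgor P = psi - pi. The loading zone equilibrates with the
    xylem (use psi_x); the unloading zone with the soil (use psi_s)."""
    return psi_zone - pi_zone


def sap_viscosity(C_pL: float, T: float = 293.0,
                  mm: float = 342.3) -> tuple[float, bool]:
    """Sap viscosity (MPa s) at loading-zone concentration C_pL (mol m-3).

    Génotelle sucrose-solution correlation on the sucrose mole fraction,
    with the molar concentration converted to a mass fraction through a
    concentration-dependent solution density. Returns
    ``(viscosity, beyond_validity)``; the flag marks supersaturated
    concentrations where the correlation extrapolates (runaway regimes
    deliberately reach them).
    """
    if C_pL < 0:
        raise ParameterError("concentration must be >= 0")
    v, flag = K.sap_viscosity(C_pL, T, mm)
    return float(v), bool(flag)


def conduit_resistance(R_p: float, v: float) -> float:
    """Total conduit resistance R_conduit = R_p * v (MPa s m-3)."""
    if R_p <= 0 or v <= 0:
        raise ParameterError("R_p and v must be positive")
    return R_p * v


def phloem_flow(P_l: float, P_u: float, R_conduit: float) -> float:
    """Münch volumetric flow F_p = (P_l - P_u)/R_conduit (m3 s-1).

    Negative flow (reverse transport) is legal and advects at the
    unloading-zone concentration.
    """
    if R_conduit <= 0:
        raise ParameterError("R_conduit must be positive")
    return (P_l - P_u) / R_conduit


def sap_velocity(F_p: float, r: float) -> float:
    """Sap velocity V_s = F_p / (pi r^2) (m s-1)."""
    if r <= 0:
        raise ParameterError("conduit radius must be positive")
    return F_p / (np.pi * r * r)


def phloem_state(sucrose: SucroseState, psi_x: float, params: ModelParams,
                 W_m: float, P_l_prev: float | None = None) -> PhloemState:
    """Evaluate all derived phloem quantities at the current pools.

    Loading uses the previous step's loading-zone turgor when supplied
    (matching the integrator's one-pass explicit ordering), otherwise the
    turgor implied by the current concentrations.
    """
    p, env = params.phloem, params.env
    C_m, C_pL, C_pU = sucrose.concentrations(W_m, p.W_p)
    pi_l = osmotic_potential(C_pL, p.Rc, p.T)
    pi_u = osmotic_potential(C_pU, p.Rc, p.T)
    P_l = turgor(psi_x, pi_l)
    P_u = turgor(env.psi_sink, pi_u)
    v, flag = sap_viscosity(C_pL, p.T, p.mm)
    R_cond = conduit_resistance(p.R_p, v)
    F_p = phloem_flow(P_l, P_u, R_cond)
    E_s = F_p * (C_pL if F_p >= 0 else C_pU)
    L_sucL = regulated_loading(
        p.V_maxL, C_m, p.M_S, P_l if P_l_prev is None else P_l_prev, p.beta)
    L_sucU = mm_rate(p.V_maxU, C_pU, p.M_S)
    return PhloemState(pi_l=pi_l, pi_u=pi_u, P_l=P_l, P_u=P_u, v=v,
                       R_conduit=R_cond, F_p=F_p,
                       V_s=sap_velocity(F_p, p.r), E_s=E_s,
                       L_sucL=L_sucL, L_sucU=L_sucU, beyond_validity=flag)


def sucrose_step(sucrose: SucroseState, phloem: PhloemState, A_net: float,
                 params: ModelParams, dt: float) -> SucroseState:
    """Advance the three sucrose pools and the cumulative export by dt.

    dS_m = dt*LA*(A_net,suc - L_sucL);  dS_pL = dt*(L_sucL*LA - E_s);
    dS_U = dt*(E_s - L_sucU*LA);  S_tot += dt*LA*L_sucU, with A_net
    converted from umol CO2 to mol sucrose (12 carbons per sucrose). Each
    pool can export at most its current content within the step, so no
    pool ever goes negative.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    p, h = params.phloem, params.hydraulic
    la = h.LA
    a_suc = A_net * 1.0e-6 / 12.0

    production = a_suc * la * dt
    avail_m = sucrose.S_m + max(production, 0.0)
    load_amt = min(phloem.L_sucL * la * dt, avail_m)
    S_m = max(sucrose.S_m + production - load_amt, 0.0)

    leak_amt = 0.0
    if p.leak_on:
        a_memb = 2.0 * np.pi * p.r * (p.W_p / (np.pi * p.r ** 2))
        leak_amt = p.S_l * a_memb * (sucrose.S_pL / p.W_p) * dt
    exp_amt = phloem.E_s * dt
    if exp_amt > 0:
        exp_amt = min(exp_amt, max(sucrose.S_pL + load_amt - leak_amt, 0.0))
    else:
        exp_amt = max(exp_amt, -sucrose.S_U)
    S_pL = max(sucrose.S_pL + load_amt - exp_amt - leak_amt, 0.0)

    unload_amt = min(phloem.L_sucU * la * dt,
                     max(sucrose.S_U + exp_amt, 0.0))
    S_U = max(sucrose.S_U + exp_amt - unload_amt, 0.0)
    S_tot = sucrose.S_tot + unload_amt

    for name, val in (("S_m", S_m), ("S_pL", S_pL), ("S_U", S_U)):
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite {name} in sucrose step")
    return SucroseState(S_m=S_m, S_pL=S_pL, S_U=S_U, S_tot=S_tot)


def stot_mg(S_tot_mol: float, mm: float = 342.3) -> float:
    """Cumulative export in milligrams from the molar total."""
    return S_tot_mol * mm * 1.0e3
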