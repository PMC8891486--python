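"""Leaf water balance and gas exchange.

The mesophyll is a variable water store connected to a steady-state xylem;
its water potential follows a pressure-volume curve, stomata close
sigmoidally with mesophyll water potential, flow through the mesophyll
integrates a logistic vulnerability curve, and net assimilation is a
saturating function of stomatal conductance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .params import ModelParams, ParameterError

__all__ = [
    "WaterState", "relative_water_content", "pv_water_potential",
    "vulnerability_flow", "stomatal_conductance", "net_assimilation",
    "water_balance_step",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WaterState:
    """Instantaneous leaf water status and gas exchange."""

    W_m: float          # mesophyll water volume (m3)
    RWC_m: float        # relative water content (-)
    psi_m: float        # mesophyll water potential (MPa)
    psi_x: float        # xylem water potential (MPa)
    inflow: float       # mesophyll water inflow (mmol m-2 s-1)
    g_s: float          # stomatal conductance (mmol m-2 s-1)
    E: float            # transpiration (mmol m-2 s-1)
    A_net: float        # net assimilation (umol CO2 m-2 s-1)


def relative_water_content(W_m: float, V_sat_m: float,
                           af: float = 0.3) -> float:
    """RWC_m = W_m / V_sat_m, clamped at 1 with a warning on overshoot.

    Draining the symplasm (RWC_m <= af) makes the pressure-volume relation
    singular and is an error.
    """
    if W_m <= 0 or V_sat_m <= 0:
        raise ParameterError("water volumes must be positive")
    rwc = W_m / V_sat_m
    if rwc > 1.0:
        log.warning("W_m exceeds V_sat_m (RWC=%.6f); clamping to 1", rwc)
        rwc = 1.0
    if rwc <= af:
        raise ParameterError(
            f"RWC_m={rwc:.3f} <= af={af}: symplasm emptied, "
            "water potential undefined")
    return rwc


def pv_water_potential(RWC_m: float, pi_o: float, af: float,
                       epsilon: float) -> float:
    """Mesophyll water potential (MPa) from the pressure-volume curve.

    Solute potential pi_o/Rs plus turgor -pi_o + eps*(Rs-1) on symplastic
    content Rs = (RWC-af)/(1-af); below the turgor-loss point the turgor
    term is zero and the branch is purely osmotic. Continuous, strictly
    increasing, and zero at full hydration.
    """
    if not af < RWC_m <= 1.0 + 1e-12:
        raise ParameterError(f"RWC_m must be in (af, 1], got {RWC_m}")
    if pi_o >= 0 or epsilon <= 0:
        raise ParameterError("need pi_o < 0 and epsilon > 0")
    return float(K.pv_water_potential(min(RWC_m, 1.0), pi_o, af, epsilon))


def vulnerability_flow(psi_low: float, psi_high: float, K_max: float,
                       alpha: float, psi50: float) -> float:
    """Integral of the logistic vulnerability curve over [psi_low, psi_high].

    Evaluated with the closed-form antiderivative
    (K_max/alpha) * ln(1 + exp(alpha*(psi - psi50))); positive when
    psi_high > psi_low (flow down the potential gradient into the
    mesophyll). Units mmol m-2 s-1.
    """
    return float(K.vulnerability_flow(psi_low, psi_high, K_max, alpha, psi50))


def stomatal_conductance(psi_m: float, g_max: float, ags: float,
                         gs_psi50: float) -> float:
    """g_s = g_max / (1 + exp(-ags*(psi_m - gs_psi50))) (mmol m-2 s-1)."""
    return float(K.stomatal_conductance(psi_m, g_max, ags, gs_psi50))


def net_assimilation(g_s: float, params: ModelParams) -> float:
    """Net assimilation (umol CO2 m-2 s-1): a smooth saturating response
    to stomatal conductance, net of dark respiration."""
    if g_s < 0:
        raise ParameterError("g_s must be >= 0")
    return float(K.net_assimilation(g_s, params.A_max, params.k_assim,
                                    params.phloem.R_L))


def water_balance_step(state: WaterState, params: ModelParams,
                       dt: float) -> WaterState:
    """Advance the leaf water balance by one explicit step.

    Order: psi_m from W_m; mesophyll inflow bounded by the new psi_m and
    the previous psi_x; g_s from the new psi_m; xylem potential update
    psi_x = psi_s - inflow/K_max_x; transpiration E = g_s*VPD; then
    W_m += dt*LA*v_w*(inflow - E). The xylem store itself is steady.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    h, env = params.hydraulic, params.env
    rwc = relative_water_content(state.W_m, h.V_sat_m, h.af)
    psi_m = pv_water_potential(rwc, h.pi_o, h.af, h.epsilon)
    inflow = vulnerability_flow(psi_m, state.psi_x, h.K_max_m, h.alpha,
                                h.psi50_m)
    g_s = stomatal_conductance(psi_m, h.g_max, h.ags, h.gs_psi50)
    psi_x = env.psi_s - inflow / h.K_max_x
    E = g_s * env.VPD
    W_m = state.W_m + dt * h.LA * K.V_W * (inflow - E)
    A_net = net_assimilation(g_s, params)
    for name, val in (("W_m", W_m), ("psi_m", psi_m), ("psi_x", psi_x)):
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite {name} in water balance")
    return WaterState(W_m=W_m, RWC_m=rwc, psi_m=psi_m, psi_x=psi_x,
                      inflow=inflow, g_s=g_s, E=E, A_net=A_net)


def initial_water_state(params: ModelParams) -> WaterState:
    """Fully hydrated leaf with the xylem equilibrated to the soil."""
    return WaterState(W_m=params.hydraulic.V_sat_m, RWC_m=1.0, psi_m=0.0,
                      psi_x=params.env.psi_s, inflow=0.0, g_s=0.0, E=0.0,
                      A_net=0.0)
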