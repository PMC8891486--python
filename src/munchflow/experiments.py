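"""Parameter-sweep and optimization drivers.

These reproduce the study designs the model exists for: the phloem
volume x resistance sweep (which phloem volumes avoid runaway viscosity),
the soil dry-down sweep with and without loading regulation, the exhaustive
(V_maxL, beta) grid search for maximum sucrose export subject to viable
loading-zone pressures, and the regulated-vs-unregulated comparison table.

All drivers are pure and deterministic; re-running with the same arguments
reproduces identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import run, PRESSURE_WINDOW, STATUS_RUNAWAY, STATUS_FAILURE
from .params import LEAF_VOLUME, ModelParams, load_preset

__all__ = [
    "SweepResult", "Optimum", "sweep_volume_resistance", "sweep_drought",
    "optimize_loading", "regulation_comparison", "select_volumes",
    "VMAXL_RANGE", "BETA_RANGE",
]

log = logging.getLogger(__name__)

#: published maximum loading rates spanning Arabidopsis -> wheat
VMAXL_RANGE = (1.30e-8, 2.30e-6)
#: downregulation strengths scanned by default (all reported optima < 2)
BETA_RANGE = (0.0, 3.0)


@dataclass
class SweepResult:
    """One row per grid cell; censored/runaway cells flagged, never dropped."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class Optimum:
    """Feasible argmax of a (V_maxL, beta) export grid."""

    V_maxL: float | None
    beta: float | None
    S_tot_mg: float | None
    n_feasible: int
    grid: pd.DataFrame

    @property
    def empty(self) -> bool:
        return self.V_maxL is None


def _cell_record(params: ModelParams, t_end: float, dt: float,
                 stride: float, **coords) -> dict:
    traj, outcome = run(params, t_end=t_end, dt=dt, stride=stride)
    rec = dict(coords)
    rec.update(
        S_tot_mg=traj.stot_mg,
        P_l_tail=outcome.stats.get("P_l_tail", np.nan),
        v_tail=outcome.stats.get("v_tail", np.nan),
        V_s_tail=outcome.stats.get("V_s_tail", np.nan),
        C_pL_tail=outcome.stats.get("C_pL_tail", np.nan),
        status=outcome.status,
        censored=outcome.flags.get("censored", False),
        feasible=outcome.feasible,
    )
    return rec


def sweep_volume_resistance(
        psi_s_list: Sequence[float] = (-0.001, -1.0),
        presets: Sequence[str] = ("R1", "R2", "R3", "R4", "R5"),
        n_wp: int = 20,
        wp_fraction_range: tuple[float, float] = (2.0e-5, 8.0e-3),
        t_end: float = 43200.0, dt: float = 1.0,
        stride: float = 60.0) -> SweepResult:
    """Sweep phloem-zone volume (log-spaced fraction of leaf volume)
    against structural resistance under each soil water potential,
    with unregulated loading at the default V_maxL."""
    wp_grid = np.geomspace(wp_fraction_range[0] * LEAF_VOLUME,
                           wp_fraction_range[1] * LEAF_VOLUME, n_wp)
    rows = []
    for preset in presets:
        base = load_preset(preset)
        for psi_s in psi_s_list:
            for wp in wp_grid:
                p = base.with_overrides(psi_s=psi_s, W_p=float(wp), beta=0.0)
                rows.append(_cell_record(p, t_end, dt, stride,
                                         preset=preset, psi_s=psi_s,
                                         W_p=float(wp)))
    table = pd.DataFrame(rows)
    return SweepResult(table, meta={"kind": "volume_resistance",
                                    "n_wp": n_wp, "dt": dt,
                                    "t_end": t_end})


def select_volumes(sweep: SweepResult,
                   psi_s: float = -1.0) -> pd.DataFrame:
    """Per resistance class, the phloem volume maximizing export while
    avoiding runaway viscosity under the droughted soil condition."""
    t = sweep.table
    sub = t[(t["psi_s"] == psi_s)
            & ~t["status"].isin([STATUS_RUNAWAY, STATUS_FAILURE])]
    picks = []
    for preset, grp in sub.groupby("preset", sort=True):
        if grp.empty:
            log.warning("no non-runaway volume for %s at psi_s=%s",
                        preset, psi_s)
            continue
        best = grp.loc[grp["S_tot_mg"].idxmax()]
        picks.append({"preset": preset, "W_p": best["W_p"],
                      "S_tot_mg": best["S_tot_mg"],
                      "status": best["status"]})
    return pd.DataFrame(picks)


def sweep_drought(presets: Sequence[str] = ("R1", "R2", "R3", "R4", "R5"),
                  psi_s_grid: Iterable[float] | None = None,
                  regulation: str = "none",
                  t_end: float = 43200.0, dt: float = 1.0,
                  stride: float = 60.0) -> SweepResult:
    """Soil dry-down sweep.

    ``regulation``: "none" (default V_maxL, beta=0), "halved"
    (V_maxL halved, beta=0) or "beta" (default V_maxL, beta=0.6).
    """
    if psi_s_grid is None:
        psi_s_grid = np.linspace(-0.001, -1.0, 11)
    if regulation not in ("none", "halved", "beta"):
        raise ValueError(f"unknown regulation mode {regulation!r}")
    rows = []
    for preset in presets:
        base = load_preset(preset)
        if regulation == "halved":
            base = base.with_overrides(V_maxL=base.phloem.V_maxL / 2.0)
        elif regulation == "beta":
            base = base.with_overrides(beta=0.6)
        for psi_s in psi_s_grid:
            p = base.with_overrides(psi_s=float(psi_s))
            rows.append(_cell_record(p, t_end, dt, stride,
                                     preset=preset, psi_s=float(psi_s),
                                     regulation=regulation))
    return SweepResult(pd.DataFrame(rows),
                       meta={"kind": "drought", "regulation": regulation,
                             "dt": dt, "t_end": t_end})


def optimize_loading(preset: str, psi_s: float,
                     vmaxl_range: tuple[float, float] = VMAXL_RANGE,
                     beta_range: tuple[float, float] = BETA_RANGE,
                     n_vmaxl: int = 25, n_beta: int = 25,
                     t_end: float = 43200.0, dt: float = 1.0,
                     stride: float = 60.0) -> Optimum:
    """Exhaustive (V_maxL, beta) grid search for maximum 12-h export.

    V_maxL is log-spaced and beta linear. A cell is feasible when the run
    is neither a failure nor a viscosity runaway and its tail loading-zone
    pressure lies within the empirical 0.6-2.4 MPa window. Ties break
    toward smaller V_maxL, then smaller beta.
    """
    if n_vmaxl < 25 or n_beta < 25:
        log.warning("grid %dx%d is coarser than the 25x25 headline default",
                    n_vmaxl, n_beta)
    vmaxls = np.geomspace(*vmaxl_range, n_vmaxl)
    betas = np.linspace(*beta_range, n_beta)
    base = load_preset(preset, psi_s=psi_s)
    rows = []
    for vmaxl in vmaxls:
        for beta in betas:
            p = base.with_overrides(V_maxL=float(vmaxl), beta=float(beta))
            rows.append(_cell_record(p, t_end, dt, stride,
                                     V_maxL=float(vmaxl), beta=float(beta)))
    grid = pd.DataFrame(rows)
    feas = grid[grid["feasible"]]
    if feas.empty:
        log.warning("no feasible cell for %s at psi_s=%s", preset, psi_s)
        return Optimum(None, None, None, 0, grid)
    best_val = feas["S_tot_mg"].max()
    ties = feas[np.isclose(feas["S_tot_mg"], best_val, rtol=0.0, atol=0.0)]
    ties = ties.sort_values(["V_maxL", "beta"], kind="mergesort")
    top = ties.iloc[0]
    return Optimum(float(top["V_maxL"]), float(top["beta"]),
                   float(top["S_tot_mg"]), int(len(feas)), grid)


def regulation_comparison(
        presets: Sequence[str] = ("R1", "R2", "R3", "R4", "R5"),
        psi_s_list: Sequence[float] = (-0.001, -1.0),
        n_vmaxl: int = 25, n_beta: int = 25,
        t_end: float = 43200.0, dt: float = 1.0,
        stride: float = 60.0) -> pd.DataFrame:
    """Unregulated (default V_maxL, beta=0) vs grid-optimized
    pressure-regulated export, with the percent change, per preset and
    soil water potential."""
    rows = []
    for psi_s in psi_s_list:
        for preset in presets:
            p0 = load_preset(preset, psi_s=psi_s)
            traj0, _ = run(p0, t_end=t_end, dt=dt, stride=stride)
            unreg = traj0.stot_mg
            opt = optimize_loading(preset, psi_s, n_vmaxl=n_vmaxl,
                                   n_beta=n_beta, t_end=t_end, dt=dt,
                                   stride=stride)
            reg = opt.S_tot_mg if not opt.empty else np.nan
            rows.append({
                "preset": preset, "psi_s": psi_s,
                "unregulated_mg": unreg, "regulated_mg": reg,
                "pct_change": 100.0 * (reg - unreg) / unreg
                if np.isfinite(reg) else np.nan,
                "opt_V_maxL": opt.V_maxL, "opt_beta": opt.beta,
            })
    return pd.DataFrame(rows)
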