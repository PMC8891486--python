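"""Time integration, trajectory recording, and run-outcome classification.

The coupled model is advanced with the one-pass explicit (Euler) scheme at
dt = 1 s for 12 h by default. A run ends in one of five states:

``steady``
    tail concentration drift below tolerance and loading/export fluxes
    balanced — a converged Münch equilibrium;
``unconverged``
    still drifting at the end of the run but decelerating and
    non-explosive (large phloem volumes relax over ~1e4 s, so a 12-h run
    can legitimately end mid-approach);
``runaway_viscosity``
    the loading-zone pressure hit the hard cap, or concentration growth is
    accelerating with viscosity exploding — the viscosity-limited failure
    mode;
``pressure_out_of_bounds``
    converged, but the tail loading-zone pressure sits outside the
    empirically viable 0.6-2.4 MPa window;
``numerical_failure``
    non-finite state (aborted with the offending time).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import ModelParams
from .phloem import stot_mg

__all__ = ["Trajectory", "RunOutcome", "run", "classify",
           "PRESSURE_WINDOW", "SteadyCriteria"]

#: empirically viable loading-zone pressure window (MPa)
PRESSURE_WINDOW = (0.6, 2.4)

STATUS_STEADY = "steady"
STATUS_UNCONVERGED = "unconverged"
STATUS_RUNAWAY = "runaway_viscosity"
STATUS_PRESSURE = "pressure_out_of_bounds"
STATUS_FAILURE = "numerical_failure"


@dataclass(frozen=True)
class SteadyCriteria:
    """Numerical thresholds separating steady from runaway regimes."""

    drift_tol: float = 1.0e-3      # relative C_pL drift over the window
    flux_tol: float = 1.0e-3       # relative loading/export imbalance
    window: float = 3600.0         # tail window length (s)
    visc_ratio: float = 10.0       # v growth marking runaway
    accel_ratio: float = 1.05      # drift acceleration marking runaway


@dataclass
class Trajectory:
    """Time-indexed record of a run plus its parameters."""

    data: pd.DataFrame
    params: ModelParams
    dt: float
    stride: float
    t_end: float
    kernel_status: int = K.STATUS_OK
    t_stop: float = 0.0

    @property
    def stot_mg(self) -> float:
        return stot_mg(float(self.data["S_tot"].iloc[-1]),
                       self.params.phloem.mm)

    def tail(self, window: float = 3600.0) -> pd.DataFrame:
        t_last = float(self.data["t"].iloc[-1])
        return self.data[self.data["t"] >= t_last - window]

    def tail_mean(self, column: str, window: float = 3600.0) -> float:
        return float(self.tail(window)[column].mean())

    def summary(self) -> dict[str, Any]:
        tail = self.tail()
        return {
            "S_tot_mg": self.stot_mg,
            "P_l": float(tail["P_l"].mean()),
            "C_pL": float(tail["C_pL"].mean()),
            "v": float(tail["v"].mean()),
            "V_s": float(tail["V_s"].mean()),
            "t_stop": self.t_stop,
        }

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    def save_summary(self, path: str, outcome: "RunOutcome" | None = None) -> None:
        payload = {"preset": self.params.preset, "dt": self.dt,
                   "stride": self.stride, **self.summary()}
        if outcome is not None:
            payload["status"] = outcome.status
            payload.update(outcome.stats)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class RunOutcome:
    """Classification of a finished run with tail statistics."""

    status: str
    stats: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        """Viable per the 12-h protocol: not a failure or runaway, and the
        tail loading-zone pressure inside the empirical window."""
        return (self.status in (STATUS_STEADY, STATUS_UNCONVERGED)
                and self.flags.get("pressure_in_window", False))


def run(params: ModelParams, t_end: float = 43200.0, dt: float = 1.0,
        stride: float = 60.0) -> tuple[Trajectory, RunOutcome]:
    """Integrate the coupled model and classify the outcome.

    Starts from the quiescent state (fully hydrated leaf, empty sucrose
    pools, xylem equilibrated with the soil) and advances ``t_end/dt``
    explicit steps, recording every ``stride`` seconds. Deterministic:
    identical parameters give bit-identical trajectories.
    """
    vec = params.to_vector()
    rec, n, status, t_stop = K.simulate(vec, t_end, dt, stride)
    df = pd.DataFrame(rec[:n], columns=list(K.COLUMNS))
    traj = Trajectory(data=df, params=params, dt=dt, stride=stride,
                      t_end=t_end, kernel_status=status, t_stop=t_stop)
    try:
        outcome = classify(traj)
    except ValueError:
        # runs shorter than the classification window stay unclassified
        outcome = RunOutcome(STATUS_UNCONVERGED, flags={"too_short": True})
    return traj, outcome


def classify(traj: Trajectory,
             criteria: SteadyCriteria | None = None) -> RunOutcome:
    """Classify a trajectory (needs at least 2 h of simulated time)."""
    c = criteria or SteadyCriteria()
    df = traj.data
    if traj.kernel_status == K.STATUS_NAN:
        return RunOutcome(STATUS_FAILURE, stats={"t_stop": traj.t_stop})
    if len(df) < 3 or float(df["t"].iloc[-1]) < 7200.0:
        if traj.kernel_status == K.STATUS_PCAP:
            return RunOutcome(STATUS_RUNAWAY,
                              stats={"t_stop": traj.t_stop},
                              flags={"censored": True})
        raise ValueError("trajectory too short to classify (< 2 h)")

    t = df["t"].to_numpy()
    cpl = df["C_pL"].to_numpy()
    visc = df["v"].to_numpy()
    t_last = t[-1]
    w = c.window
    cpl_end = cpl[-1]
    cpl_1h = _value_at(t, cpl, t_last - w)
    cpl_2h = _value_at(t, cpl, t_last - 2 * w)
    visc_1h = _value_at(t, visc, t_last - w)
    scale = max(abs(cpl_end), 1e-12)
    drift1 = (cpl_1h - cpl_2h) / scale    # previous hour
    drift2 = (cpl_end - cpl_1h) / scale   # final hour
    visc_ratio = visc[-1] / max(visc_1h, 1e-300)

    # instantaneous flux balance at the recorded tail
    la = traj.params.hydraulic.LA
    tail = traj.tail(w)
    es = float(tail["E_s"].mean())
    lsl = float(tail["L_sucL"].mean()) * la
    lsu = float(tail["L_sucU"].mean()) * la
    denom = max(abs(es), 1e-300)
    flux_imbalance = max(abs(lsl - es), abs(es - lsu)) / denom

    p_l_tail = traj.tail_mean("P_l", w)
    in_window = PRESSURE_WINDOW[0] <= p_l_tail <= PRESSURE_WINDOW[1]
    stats = {
        "P_l_tail": p_l_tail, "C_pL_tail": traj.tail_mean("C_pL", w),
        "v_tail": traj.tail_mean("v", w), "V_s_tail": traj.tail_mean("V_s", w),
        "S_tot_mg": traj.stot_mg, "drift": drift2,
        "flux_imbalance": flux_imbalance, "visc_ratio": visc_ratio,
        "t_stop": traj.t_stop,
    }
    flags = {
        "censored": traj.kernel_status == K.STATUS_PCAP,
        "pressure_in_window": bool(in_window),
        "beyond_validity": bool(df["visc_flag"].iloc[-1] > 0),
    }

    if traj.kernel_status == K.STATUS_PCAP:
        return RunOutcome(STATUS_RUNAWAY, stats=stats, flags=flags)
    accelerating = drift2 > 0 and drift2 > c.accel_ratio * max(drift1, 0.0)
    if accelerating and visc_ratio > c.visc_ratio:
        return RunOutcome(STATUS_RUNAWAY, stats=stats, flags=flags)
    if abs(drift2) < c.drift_tol and flux_imbalance < c.flux_tol:
        status = STATUS_STEADY if in_window else STATUS_PRESSURE
        return RunOutcome(status, stats=stats, flags=flags)
    return RunOutcome(STATUS_UNCONVERGED, stats=stats, flags=flags)


def _value_at(t: np.ndarray, y: np.ndarray, t_query: float) -> float:
    """y at the recorded time closest to t_query."""
    idx = int(np.argmin(np.abs(t - t_query)))
    return float(y[idx])
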