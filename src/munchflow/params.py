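"""Model parameters: hydraulic, phloem, gas-exchange and environmental
constants, with validation, YAML config I/O and shipped presets.

Presets live as YAML files under ``munchflow/presets/``: one per structural
resistance class R1..R5 (sieve-element resistances scaled to whole plants
for five active-loading species, in increasing order) and one per species
source of the maximum loading rate V_maxL (arabidopsis, tobacco, wheat).
"""

from __future__ import annotations

import importlib.resources as _resources
import math
from dataclasses import dataclass, field, fields, replace, asdict
from typing import Any, Mapping

import numpy as np
import yaml

from . import _kernel as K

__all__ = [
    "HydraulicParams", "PhloemParams", "Environment", "ModelParams",
    "load_preset", "available_presets", "structural_resistance",
    "load_config", "save_config", "LEAF_VOLUME",
]

#: total leaf volume (m3) anchoring the phloem-volume sweep: the smallest
#: phloem-zone volume used with R1/R2 (3.57e-11 m3) is 0.002% of leaf volume
LEAF_VOLUME = 3.57e-11 / 2.0e-5

_R_PRESETS = ("R1", "R2", "R3", "R4", "R5")
_VMAX_PRESETS = ("arabidopsis", "tobacco", "wheat")


class ParameterError(ValueError):
    """Raised when a parameter bundle violates a physical invariant."""


@dataclass(frozen=True)
class HydraulicParams:
    """Leaf/xylem hydraulics, stomata and pressure-volume constants."""

    af: float = 0.3            # apoplasmic fraction (-)
    ags: float = 2.0           # stomatal closure shape (MPa-1)
    g_max: float = 400.0       # max stomatal conductance (mmol m-2 s-1)
    gs_psi50: float = -1.5     # psi_m at 50% stomatal closure (MPa)
    K_max_m: float = 20.0      # max mesophyll conductance (mmol m-2 s-1 MPa-1)
    K_max_x: float = 20.0      # max xylem conductance (mmol m-2 s-1 MPa-1)
    alpha: float = 2.0         # mesophyll vulnerability shape (-)
    psi50_m: float = -2.0      # psi_m at 50% conductance loss (MPa)
    pi_o: float = -1.2         # osmotic potential at full hydration (MPa)
    epsilon: float = 12.0      # cell-wall modulus of elasticity (MPa)
    LA: float = 4.74e-3        # leaf area (m2)
    V_sat_m: float | None = None  # saturated mesophyll water volume (m3)

    def __post_init__(self) -> None:
        if self.V_sat_m is None:
            # ~150 g m-2 of leaf water at saturation
            object.__setattr__(self, "V_sat_m", self.LA * 1.5e-4)
        if not 0.0 < self.af < 1.0:
            raise ParameterError(f"af must be in (0,1), got {self.af}")
        if self.g_max <= 0:
            raise ParameterError("g_max must be positive")
        if self.pi_o >= 0:
            raise ParameterError("pi_o must be negative")
        if self.epsilon <= 0:
            raise ParameterError("epsilon must be positive")
        if self.V_sat_m <= 0 or self.LA <= 0:
            raise ParameterError("V_sat_m and LA must be positive")
        if self.pi_tlp > self.pi_o:
            raise ParameterError(
                "turgor-loss point must be at least as negative as pi_o")

    @property
    def pi_tlp(self) -> float:
        """Turgor-loss-point osmotic potential, pi_o*eps/(pi_o+eps) (MPa)."""
        return self.pi_o * self.epsilon / (self.pi_o + self.epsilon)


@dataclass(frozen=True)
class PhloemParams:
    """Sieve-tube structure, transporter kinetics and sap constants."""

    R_p: float = 2.4e20        # structural resistance coefficient (m-3)
    W_p: float = 3.57e-11      # phloem-zone water volume (m3)
    r: float = 5.5e-6          # conduit radius (m)
    M_S: float = 3.3           # Michaelis constant for sucrose (mol m-3)
    V_maxL: float = 1.58e-7    # max loading rate (mol m-2 s-1)
    V_maxU: float | None = None  # max unloading rate; default 1.2 x V_maxL
    beta: float = 0.0          # pressure-downregulation shape (MPa-1)
    mm: float = 342.3          # sucrose molar mass (g mol-1)
    Rc: float = 8.3            # gas constant (m3 Pa K-1 mol-1)
    T: float = 293.0           # temperature (K)
    S_l: float = 7.3e-16       # membrane leak permeability (m s-1)
    leak_on: bool = False      # leak term disabled by default
    R_L: float = 0.25          # leaf respiration (umol C m-2 s-1)

    def __post_init__(self) -> None:
        if self.V_maxU is None:
            object.__setattr__(self, "V_maxU", 1.2 * self.V_maxL)
        for name in ("R_p", "W_p", "r", "M_S"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.V_maxL < 0 or self.beta < 0:
            raise ParameterError("V_maxL and beta must be non-negative")
        if self.V_maxU < self.V_maxL:
            raise ParameterError("V_maxU must be >= V_maxL "
                                 "(unloading must not limit export)")


@dataclass(frozen=True)
class Environment:
    """Environmental forcing: two scalars plus constant CO2 and light."""

    psi_s: float = -0.001      # soil water potential (MPa)
    VPD: float = 9.9e-3        # vapor pressure deficit (mole fraction)
    c_a: float = 400.0         # atmospheric CO2 (ppm)
    psi_sink: float = 0.0      # sink-tissue water potential (MPa); the
    # unloading zone equilibrates with a well-hydrated sink rather than
    # with the drying source soil column, so its turgor stays near zero
    # and drought acts on transport through the source side only
    light_saturating: bool = True

    def __post_init__(self) -> None:
        if self.psi_s > 0:
            raise ParameterError("psi_s must be <= 0")
        if self.psi_sink > 0:
            raise ParameterError("psi_sink must be <= 0")
        if self.VPD < 0:
            raise ParameterError("VPD must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Complete, validated parameter bundle for one simulation."""

    hydraulic: HydraulicParams = field(default_factory=HydraulicParams)
    phloem: PhloemParams = field(default_factory=PhloemParams)
    env: Environment = field(default_factory=Environment)
    # gs -> A_net response (rectangular hyperbola, net of respiration)
    A_max: float = 20.0        # light/CO2-saturated gross rate (umol m-2 s-1)
    k_assim: float | None = None  # initial slope; default 9*A_max/g_max
    p_cap: float = 50.0        # hard loading-zone pressure cap (MPa)
    preset: str = "default"

    def __post_init__(self) -> None:
        if self.k_assim is None:
            object.__setattr__(
                self, "k_assim", 9.0 * self.A_max / self.hydraulic.g_max)

    # -- convenience -------------------------------------------------------
    def with_overrides(self, **kv: Any) -> "ModelParams":
        """Return a copy with flat key=value overrides (e.g. beta=0.6)."""
        hnames = {f.name for f in fields(HydraulicParams)}
        pnames = {f.name for f in fields(PhloemParams)}
        enames = {f.name for f in fields(Environment)}
        hkv: dict[str, Any] = {}
        pkv: dict[str, Any] = {}
        ekv: dict[str, Any] = {}
        top: dict[str, Any] = {}
        for key, val in kv.items():
            if key in hnames:
                hkv[key] = val
            elif key in pnames:
                pkv[key] = val
            elif key in enames:
                ekv[key] = val
            elif key in {"A_max", "k_assim", "p_cap", "preset"}:
                top[key] = val
            else:
                raise ParameterError(f"unknown parameter {key!r}")
        if "V_maxL" in pkv and "V_maxU" not in pkv:
            pkv["V_maxU"] = None  # keep the 1.2x unloading coupling
        return replace(
            self,
            hydraulic=replace(self.hydraulic, **hkv) if hkv else self.hydraulic,
            phloem=replace(self.phloem, **pkv) if pkv else self.phloem,
            env=replace(self.env, **ekv) if ekv else self.env,
            **top)

    def to_vector(self) -> np.ndarray:
        """Pack into the float64 layout consumed by the compiled kernel."""
        h, p, e = self.hydraulic, self.phloem, self.env
        v = np.empty(K.NPAR)
        v[K.AF] = h.af
        v[K.AGS] = h.ags
        v[K.G_MAX] = h.g_max
        v[K.GS_PSI50] = h.gs_psi50
        v[K.K_MAX_M] = h.K_max_m
        v[K.K_MAX_X] = h.K_max_x
        v[K.ALPHA] = h.alpha
        v[K.PSI50_M] = h.psi50_m
        v[K.PI_O] = h.pi_o
        v[K.EPS] = h.epsilon
        v[K.V_SAT_M] = h.V_sat_m
        v[K.LA] = h.LA
        v[K.R_P] = p.R_p
        v[K.W_P] = p.W_p
        v[K.RADIUS] = p.r
        v[K.M_S] = p.M_S
        v[K.V_MAXL] = p.V_maxL
        v[K.V_MAXU] = p.V_maxU
        v[K.BETA] = p.beta
        v[K.MM] = p.mm
        v[K.RC] = p.Rc
        v[K.TEMP] = p.T
        v[K.S_L] = p.S_l
        v[K.LEAK_ON] = 1.0 if p.leak_on else 0.0
        v[K.R_L] = p.R_L
        v[K.A_MAX] = self.A_max
        v[K.K_ASSIM] = self.k_assim
        v[K.PSI_S] = e.psi_s
        v[K.VPD] = e.VPD
        v[K.C_A] = e.c_a
        v[K.P_CAP] = self.p_cap
        v[K.PSI_SINK] = e.psi_sink
        return v

    def to_flat_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for section in (self.hydraulic, self.phloem, self.env):
            out.update(asdict(section))
        out.update(A_max=self.A_max, k_assim=self.k_assim,
                   p_cap=self.p_cap, preset=self.preset)
        return out

    @classmethod
    def from_flat_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        hnames = {f.name for f in fields(HydraulicParams)}
        pnames = {f.name for f in fields(PhloemParams)}
        enames = {f.name for f in fields(Environment)}
        tnames = {"A_max", "k_assim", "p_cap", "preset"}
        unknown = set(d) - hnames - pnames - enames - tnames
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(
            hydraulic=HydraulicParams(
                **{k: v for k, v in d.items() if k in hnames}),
            phloem=PhloemParams(
                **{k: v for k, v in d.items() if k in pnames}),
            env=Environment(**{k: v for k, v in d.items() if k in enames}),
            **{k: v for k, v in d.items() if k in tnames},
        )


def structural_resistance(Rse: float, Rsel: float) -> float:
    """Whole-plant structural resistance from a single sieve element.

    R_p = Rse * 2.5e23 / Rsel, with Rse the per-element (lumen + sieve
    plate) resistance and Rsel the element length. The R1..R5 presets carry
    literature R_p values directly; this is the anatomical route to new ones.
    """
    if Rse <= 0 or Rsel <= 0:
        raise ParameterError("Rse and Rsel must be positive")
    return Rse * 2.5e23 / Rsel


def _preset_path(name: str):
    return _resources.files("munchflow.presets").joinpath(f"{name}.yaml")


def available_presets() -> list[str]:
    root = _resources.files("munchflow.presets")
    return sorted(p.name[:-5] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str = "default", *, vmax_source: str | None = None,
                psi_s: float | None = None, **overrides: Any) -> ModelParams:
    """Build a validated parameter bundle from a shipped preset.

    ``name`` is "default", a resistance class R1..R5, or a V_maxL species
    (arabidopsis / tobacco / wheat); a resistance class may additionally be
    combined with ``vmax_source`` and a soil water potential ``psi_s``.
    """
    merged: dict[str, Any] = dict(_read_preset("default"))
    if name != "default":
        if name not in _R_PRESETS + _VMAX_PRESETS:
            raise ParameterError(
                f"unknown preset {name!r}; choose from "
                f"{('default',) + _R_PRESETS + _VMAX_PRESETS}")
        merged.update(_read_preset(name))
    if vmax_source is not None:
        if vmax_source not in _VMAX_PRESETS:
            raise ParameterError(
                f"unknown V_max source {vmax_source!r}; "
                f"choose from {_VMAX_PRESETS}")
        merged.update(_read_preset(vmax_source))
    if psi_s is not None:
        merged["psi_s"] = psi_s
    merged["preset"] = name
    merged.update(overrides)
    return ModelParams.from_flat_dict(merged)


def _read_preset(name: str) -> dict[str, Any]:
    with _preset_path(name).open("r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"preset file {name}.yaml is not a mapping")
    return data


def load_config(path: str) -> ModelParams:
    """Read a flat YAML/JSON key-value config into a parameter bundle."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    base = data.pop("preset", "default")
    return load_preset(base, **data)


def save_config(params: ModelParams, path: str) -> None:
    """Serialize a bundle to flat YAML; round-trips bit-for-bit."""
    d = params.to_flat_dict()
    # floats only, so YAML round-trips exactly via repr
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def water_viscosity(T: float = 293.0) -> float:
    """Dilute-limit sap viscosity (MPa s) from the shipped correlation."""
    return float(K.sap_viscosity(0.0, T, 342.3)[0])


def _check_preset_ordering() -> None:  # exercised by the test suite
    rps = [load_preset(n).phloem.R_p for n in _R_PRESETS]
    assert all(a < b for a, b in zip(rps, rps[1:]))
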