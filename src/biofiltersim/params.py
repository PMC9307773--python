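"""Model parameters, presets, configuration loading and inlet schedules.

All quantities are held internally in an SI-with-hours unit system (m, g,
h); rate constants are per hour and the biofilm diffusivity is stored in
m^2 h^-1.  Configuration files state diffusivity in m^2 s^-1, as it is
conventionally tabulated, and it is converted (x3600) at load time.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import MISSING as _MISSING
from dataclasses import dataclass, field, fields, asdict, replace
from typing import Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KineticParams",
    "TransportParams",
    "NitrogenParams",
    "DiscretizationParams",
    "InletSchedule",
    "ModelParameters",
    "load_parameters",
    "serialize_parameters",
    "preset",
    "PRESET_NAMES",
    "schedule_ramp",
    "ConfigError",
]

HOURS_PER_DAY = 24.0
SECONDS_PER_HOUR = 3600.0


class ConfigError(ValueError):
    """Raised for missing keys, unknown keys or out-of-range values."""


def _require_positive(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not (v > 0):
            raise ConfigError(f"{type(obj).__name__}.{name} must be > 0, got {v!r}")


def _require_nonnegative(obj, names):
    for name in names:
        v = getattr(obj, name)
        if not (v >= 0):
            raise ConfigError(f"{type(obj).__name__}.{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class KineticParams:
    """Haldane degradation kinetics and biomass growth/decay constants.

    v_max   maximum specific degradation rate [g_substrate g_biomass^-1 h^-1]
    k_s     half-saturation (affinity) constant [g m^-3]
    k_i     substrate-inhibition constant [g m^-3]
    mu_max  maximum specific growth rate [h^-1]
    decay_a first-order biomass decay rate [h^-1]
    yield_y biomass yield on substrate [g g^-1]
    rho_bio dry-biomass density of the biofilm [g m^-3]
    """

    v_max: float
    k_s: float
    k_i: float
    mu_max: float
    decay_a: float
    yield_y: float
    rho_bio: float

    def __post_init__(self):
        _require_positive(
            self, ["v_max", "k_s", "k_i", "mu_max", "decay_a", "yield_y", "rho_bio"]
        )
        if not (self.k_i > self.k_s):
            raise ConfigError(
                "Haldane kinetics require k_i > k_s for a non-degenerate rate "
                f"maximum; got k_s={self.k_s}, k_i={self.k_i}"
            )

    @property
    def c_peak(self) -> float:
        """Concentration of the Haldane rate maximum, sqrt(k_s * k_i) [g m^-3]."""
        return math.sqrt(self.k_s * self.k_i)


@dataclass(frozen=True)
class TransportParams:
    """Gas/biofilm partitioning, diffusion and column geometry.

    henry_h              dimensionless gas/biofilm partition constant [-]
    diffusivity_d        substrate diffusivity in the biofilm [m^2 h^-1]
    superficial_velocity gas superficial velocity [m h^-1]
    porosity_eps         bed porosity [-]
    rho_bulk             packing bulk density [kg_compost m^-3]
    area_a               specific biofilm surface area [m^2 kg_compost^-1]
    bed_height           packed-bed height [m]
    bed_diameter         column internal diameter [m]
    """

    henry_h: float
    diffusivity_d: float
    superficial_velocity: float
    porosity_eps: float
    rho_bulk: float
    area_a: float
    bed_height: float = 0.25
    bed_diameter: float = 0.10

    def __post_init__(self):
        _require_positive(
            self,
            [
                "henry_h",
                "diffusivity_d",
                "superficial_velocity",
                "rho_bulk",
                "area_a",
                "bed_height",
                "bed_diameter",
            ],
        )
        if not (0 < self.porosity_eps < 1):
            raise ConfigError(
                f"porosity_eps must lie in (0, 1), got {self.porosity_eps!r}"
            )

    @property
    def cross_section(self) -> float:
        """Empty-column cross-sectional area [m^2]."""
        return math.pi * (self.bed_diameter / 2.0) ** 2

    @property
    def bed_volume(self) -> float:
        """Empty-bed volume [m^3]."""
        return self.cross_section * self.bed_height

    @property
    def flow_q(self) -> float:
        """Volumetric gas flow implied by the superficial velocity [m^3 h^-1]."""
        return self.superficial_velocity * self.cross_section

    @property
    def ebrt_min(self) -> float:
        """Empty-bed residence time from geometry and velocity [min]."""
        return self.bed_height / self.superficial_velocity * 60.0


@dataclass(frozen=True)
class NitrogenParams:
    """Packing nitrogen pool and its coupling to biomass growth.

    n_org     organic nitrogen content of the packing [g_N kg_compost^-1]
    k_min     mineralization rate constant [h^-1]
    k_uptake  background (abiotic) uptake rate constant [h^-1]
    k_n       Michaelis-Menten constant for nitrogen [g_N kg_compost^-1]
    f_n       nitrogen mass fraction of degrading biomass [g_N g_biomass^-1]
    n_inorg_0 initial inorganic nitrogen [g_N kg_compost^-1]
    """

    n_org: float
    k_min: float
    k_uptake: float
    k_n: float
    f_n: float
    n_inorg_0: float = 0.916

    def __post_init__(self):
        _require_nonnegative(
            self, ["n_org", "k_min", "k_uptake", "k_n", "f_n", "n_inorg_0"]
        )
        if self.f_n > 1:
            raise ConfigError(f"f_n is a mass fraction and must be <= 1, got {self.f_n}")

    @property
    def n_equilibrium(self) -> float:
        """Abiotic steady state k_min*n_org/k_uptake [g_N kg^-1] (no biomass)."""
        return self.k_min * self.n_org / self.k_uptake


GROWTH_MODES = ("biofilm_average", "gas_literal")


@dataclass(frozen=True)
class DiscretizationParams:
    """Collocation node counts and integrator settings.

    n_axial / n_biofilm count TOTAL nodes including both boundary points.
    growth_concentration_mode selects which concentration drives the growth
    Haldane factor: the local gas-phase concentration ("gas_literal", the
    growth law as written, default) or the depth-averaged biofilm
    concentration ("biofilm_average").  The literal form produces the sharp
    one-day removal-efficiency collapse; the averaged form softens it.
    advection_scheme: "collocation" (spectral differentiation, default) or
    "upwind" (first-order finite volume; robust at sharp inlet steps).
    """

    n_axial: int = 25
    n_biofilm: int = 10
    solver_rtol: float = 1e-6
    solver_atol: float = 1e-9
    growth_concentration_mode: str = "gas_literal"
    advection_scheme: str = "collocation"

    def __post_init__(self):
        if self.n_axial < 3:
            raise ConfigError(f"n_axial must be >= 3, got {self.n_axial}")
        if self.n_biofilm < 3:
            raise ConfigError(f"n_biofilm must be >= 3, got {self.n_biofilm}")
        _require_positive(self, ["solver_rtol", "solver_atol"])
        if self.growth_concentration_mode not in GROWTH_MODES:
            raise ConfigError(
                f"growth_concentration_mode must be one of {GROWTH_MODES}, "
                f"got {self.growth_concentration_mode!r}"
            )
        if self.advection_scheme not in ("collocation", "upwind"):
            raise ConfigError(
                f"advection_scheme must be 'collocation' or 'upwind', "
                f"got {self.advection_scheme!r}"
            )


@dataclass(frozen=True)
class InletSchedule:
    """Piecewise-constant inlet concentration vs time (hold-previous).

    ``times_h`` are strictly increasing breakpoints [h]; ``values`` [g m^-3]
    apply from each breakpoint until the next.  Before the first breakpoint
    the first value applies.
    """

    times_h: tuple = ()
    values: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size == 0 or t.size != v.size:
            raise ConfigError("schedule needs equal, non-zero numbers of times and values")
        if np.any(np.diff(t) <= 0):
            raise ConfigError("schedule times must be strictly increasing")
        if np.any(v < 0):
            raise ConfigError("schedule concentrations must be >= 0")
        object.__setattr__(self, "times_h", tuple(t))
        object.__setattr__(self, "values", tuple(v))

    def value(self, t: float) -> float:
        """Inlet concentration at time t [h] (hold-previous)."""
        idx = np.searchsorted(self.times_h, t, side="right") - 1
        return self.values[max(idx, 0)]

    def breakpoints_within(self, t0: float, t1: float) -> np.ndarray:
        """Breakpoint times strictly inside (t0, t1), for integrator restarts."""
        t = np.asarray(self.times_h)
        return t[(t > t0) & (t < t1)]

    @classmethod
    def constant(cls, c_in: float) -> "InletSchedule":
        return cls(times_h=(0.0,), values=(float(c_in),))

    @classmethod
    def from_csv(cls, path) -> "InletSchedule":
        """Read a 2-column delimited file with header (time_h, c_in_g_per_m3)."""
        df = pd.read_csv(path)
        cols = [c.strip() for c in df.columns]
        if len(cols) < 2:
            raise ConfigError("schedule file needs two columns: time_h, c_in_g_per_m3")
        return cls(
            times_h=tuple(df.iloc[:, 0].astype(float)),
            values=tuple(df.iloc[:, 1].astype(float)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": list(self.times_h), "c_in_g_per_m3": list(self.values)}
        )


def schedule_ramp(
    increment: float, n_days: int, start_day_value: float | None = None
) -> InletSchedule:
    """Daily staircase: value during day d (1-based) = start + (d-1)*increment.

    ``start_day_value`` defaults to one increment, i.e. the ramp begins at
    ``increment`` on day 1.  Steps change at day boundaries (1 day = 24 h).
    """
    if not increment > 0:
        raise ConfigError(f"increment must be > 0, got {increment}")
    if n_days < 1:
        raise ConfigError(f"n_days must be >= 1, got {n_days}")
    if start_day_value is None:
        start_day_value = increment
    days = np.arange(n_days)
    return InletSchedule(
        times_h=tuple(days * HOURS_PER_DAY),
        values=tuple(start_day_value + days * increment),
    )


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for one biofilter scenario."""

    kinetics: KineticParams
    transport: TransportParams
    nitrogen: NitrogenParams
    discretization: DiscretizationParams = field(default_factory=DiscretizationParams)
    x0: float = 0.003  # initial biomass [g_biomass kg_compost^-1]

    def __post_init__(self):
        if not (self.x0 > 0):
            raise ConfigError(f"x0 must be > 0, got {self.x0}")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with selected (possibly nested) fields replaced."""
        return replace(self, **kwargs)

    @property
    def initial_thickness(self) -> float:
        """Biofilm thickness at the initial biomass loading [m]."""
        return self.x0 / (self.transport.area_a * self.kinetics.rho_bio)


# --- Table-derived presets -------------------------------------------------
#
# Three scenario columns differing only in biofilm surface area A, biofilm
# diffusivity D and packing bulk density rho_bulk.  Diffusivities are stated
# in m^2 s^-1 here (as tabulated) and converted on construction.

_SHARED = dict(
    v_max=0.3,          # g g^-1 h^-1
    k_s=0.05,           # g m^-3
    k_i=2.7,            # g m^-3
    mu_max=0.1,         # h^-1
    decay_a=0.0014,     # h^-1
    yield_y=0.5,        # g g^-1
    rho_bio=1.0e5,      # g m^-3
    henry_h=0.25,       # -
    superficial_velocity=3.63,  # m h^-1
    porosity_eps=0.55,  # -
    n_org=14.98,        # g_N kg^-1
    k_min=0.00007,      # h^-1
    k_uptake=0.0022,    # h^-1
    k_n=0.5,            # g_N kg^-1
    f_n=0.126,          # g_N g^-1
    x0=0.003,           # g kg^-1
)

_PRESET_SPECIFIC = {
    # scenario engineered to show two steady states
    "two_steady_states": dict(area_a=0.95, diffusivity_d_si=1.5e-10, rho_bulk=555.0),
    # steadily increasing inlet concentration (the ramp scenario)
    "steady_increase": dict(area_a=1.1, diffusivity_d_si=1.5e-11, rho_bulk=555.0),
    # second, straw-packed biofilter experiment
    "biofilter_experiment": dict(area_a=0.2375, diffusivity_d_si=1.5e-12, rho_bulk=306.0),
}

PRESET_NAMES = tuple(_PRESET_SPECIFIC)


def preset(name: str) -> ModelParameters:
    """Return one of the three shipped scenario parameter sets."""
    try:
        spec = _PRESET_SPECIFIC[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    s = _SHARED
    return ModelParameters(
        kinetics=KineticParams(
            v_max=s["v_max"],
            k_s=s["k_s"],
            k_i=s["k_i"],
            mu_max=s["mu_max"],
            decay_a=s["decay_a"],
            yield_y=s["yield_y"],
            rho_bio=s["rho_bio"],
        ),
        transport=TransportParams(
            henry_h=s["henry_h"],
            diffusivity_d=spec["diffusivity_d_si"] * SECONDS_PER_HOUR,
            superficial_velocity=s["superficial_velocity"],
            porosity_eps=s["porosity_eps"],
            rho_bulk=spec["rho_bulk"],
            area_a=spec["area_a"],
        ),
        nitrogen=NitrogenParams(
            n_org=s["n_org"],
            k_min=s["k_min"],
            k_uptake=s["k_uptake"],
            k_n=s["k_n"],
            f_n=s["f_n"],
        ),
        discretization=DiscretizationParams(),
        x0=s["x0"],
    )


# --- Config loading --------------------------------------------------------

_SECTION_TYPES = {
    "kinetics": KineticParams,
    "transport": TransportParams,
    "nitrogen": NitrogenParams,
    "discretization": DiscretizationParams,
}

# Config keys that carry units other than the internal m/g/h system.
_CONVERTED_KEYS = {("transport", "diffusivity_d_m2_per_s"): ("diffusivity_d", SECONDS_PER_HOUR)}


def _build_section(section: str, data: dict, cls):
    allowed = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        conv = _CONVERTED_KEYS.get((section, key))
        if conv is not None:
            key, factor = conv
            value = float(value) * factor
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in section {section!r}")
        kwargs[key] = value
    missing = [
        f.name
        for f in fields(cls)
        if f.name not in kwargs
        and f.default is _MISSING
        and f.default_factory is _MISSING  # type: ignore[misc]
    ]
    if missing:
        raise ConfigError(f"section {section!r} is missing required keys: {missing}")
    return cls(**kwargs)


def load_parameters(config_source: Union[str, os.PathLike, dict, io.IOBase]) -> ModelParameters:
    """Build a validated :class:`ModelParameters` from a YAML document or dict.

    The document has nested sections ``kinetics``, ``transport``, ``nitrogen``
    and optionally ``discretization``, plus a top-level ``x0``.  Alternatively
    a top-level ``preset: <name>`` selects a shipped preset, with any sections
    present overriding individual preset values.  A diffusivity may be given
    as ``diffusivity_d_m2_per_s`` (converted x3600) or ``diffusivity_d``
    (already in m^2 h^-1).  Unknown keys are rejected.
    """
    if isinstance(config_source, dict):
        doc = dict(config_source)
    elif hasattr(config_source, "read"):
        doc = yaml.safe_load(config_source.read())
    else:
        text = str(config_source)
        if os.path.exists(text):
            with open(text, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")

    base = None
    if "preset" in doc:
        base = preset(doc.pop("preset"))

    known_top = set(_SECTION_TYPES) | {"x0", "schedule"}
    unknown = set(doc) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            data = doc[name]
            if not isinstance(data, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            if base is not None:
                merged = asdict(getattr(base, name))
                for key, value in data.items():
                    conv = _CONVERTED_KEYS.get((name, key))
                    if conv is not None:
                        key, factor = conv
                        value = float(value) * factor
                    if key not in merged:
                        raise ConfigError(f"unknown key {key!r} in section {name!r}")
                    merged[key] = value
                sections[name] = cls(**merged)
            else:
                sections[name] = _build_section(name, data, cls)
        elif base is not None:
            sections[name] = getattr(base, name)
        elif name == "discretization":
            sections[name] = DiscretizationParams()
        else:
            raise ConfigError(f"missing required section {name!r}")

    x0 = doc.get("x0", base.x0 if base is not None else 0.003)
    return ModelParameters(
        kinetics=sections["kinetics"],
        transport=sections["transport"],
        nitrogen=sections["nitrogen"],
        discretization=sections["discretization"],
        x0=float(x0),
    )


def serialize_parameters(params: ModelParameters) -> str:
    """Render parameters as a YAML document that round-trips through
    :func:`load_parameters` (diffusivity written in m^2 h^-1)."""
    doc = {
        "kinetics": asdict(params.kinetics),
        "transport": asdict(params.transport),
        "nitrogen": asdict(params.nitrogen),
        "discretization": asdict(params.discretization),
        "x0": params.x0,
    }
    return yaml.safe_dump(doc, sort_keys=False)
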