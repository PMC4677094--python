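"""Element laws and parameter presets of the mock-loop lumped-parameter network.

The network models the circuit downstream of the aortic junction: four
branches (innominate, carotid, subclavian, descending aorta), each a
non-linear tap resistance in series with a linear tube resistance and a
Windkessel compliance, draining into a common section (terminal resistance
and compliance) held against a constant atrial head pressure.

Internal units are strictly SI (Pa, m³/s, s, m³/Pa). mmHg and L/min appear
only at I/O boundaries via :func:`convert_pressure` / :func:`convert_flow`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "LMIN_TO_M3S",
    "BRANCH_LABELS",
    "FluidProperties",
    "BranchParams",
    "TerminalParams",
    "LPNConfig",
    "WATER",
    "default_network",
    "nonlinear_drop",
    "series_branch_flow",
    "series_drop",
    "convert_pressure",
    "convert_flow",
    "InvalidParameterError",
]

MMHG_TO_PA = 133.322
LMIN_TO_M3S = 1.0 / 60000.0

#: Canonical branch ordering used everywhere (tables, arrays, CSV columns).
BRANCH_LABELS = ("innominate", "carotid", "subclavian", "descending_aorta")


class InvalidParameterError(ValueError):
    """A network element violates its admissibility constraints."""


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid constants.

    Parameters
    ----------
    density : float
        Mass density ρ (kg/m³).
    viscosity : float
        Dynamic viscosity μ (Pa·s).
    """

    density: float
    viscosity: float

    def __post_init__(self) -> None:
        if not (self.density > 0 and self.viscosity > 0):
            raise InvalidParameterError(
                "fluid density and viscosity must be strictly positive"
            )


#: The loop runs on water (ρ = 1000 kg/m³, μ = 1 cP).
WATER = FluidProperties(density=1000.0, viscosity=1.0e-3)


@dataclass(frozen=True)
class BranchParams:
    """Element constants for one downstream branch.

    The tap is characterised by the quadratic drop law
    ``ΔP₁ = a·Q² + b·Q`` (b may be negative); the tube adds a linear
    resistance ``r2``; ``c`` is the branch Windkessel compliance.
    The series law ΔP = a·Q² + (b + r2)·Q must be strictly increasing for
    Q ≥ 0, which requires ``b + r2 > 0``.
    """

    label: str
    a: float  # Pa·s²/m⁶
    b: float  # Pa·s/m³
    r2: float  # Pa·s/m³
    c: float  # m³/Pa

    def __post_init__(self) -> None:
        if self.label not in BRANCH_LABELS:
            raise InvalidParameterError(
                f"unknown branch label {self.label!r}; expected one of {BRANCH_LABELS}"
            )
        if not (self.a > 0 and self.r2 > 0 and self.c > 0):
            raise InvalidParameterError(
                f"branch {self.label!r}: a, r2 and c must be strictly positive"
            )
        if not self.b + self.r2 > 0:
            raise InvalidParameterError(
                f"branch {self.label!r}: b + r2 must be positive for a monotone "
                "series pressure-flow law"
            )


@dataclass(frozen=True)
class TerminalParams:
    """Common-section constants: resistance of the return line to the atrial
    reservoir and the terminal compliance."""

    r_t: float  # Pa·s/m³
    c_t: float  # m³/Pa

    def __post_init__(self) -> None:
        if not (self.r_t > 0 and self.c_t > 0):
            raise InvalidParameterError("terminal r_t and c_t must be strictly positive")


@dataclass(frozen=True)
class LPNConfig:
    """Full lumped-parameter network configuration.

    ``r_internal`` are the small linear resistances of the 0D junction
    surrogate standing in for the viscous loss of the spatially resolved
    aortic domain, one per branch in :data:`BRANCH_LABELS` order.
    """

    branches: tuple[BranchParams, ...]
    terminal: TerminalParams
    p_atrium: float  # Pa
    fluid: FluidProperties = WATER
    r_internal: tuple[float, ...] = field(default=(1.0e6,) * 4)
    inlet_diameter: float = 0.012  # m

    def __post_init__(self) -> None:
        if len(self.branches) != 4:
            raise InvalidParameterError("exactly four branches are required")
        labels = tuple(br.label for br in self.branches)
        if sorted(labels) != sorted(BRANCH_LABELS):
            raise InvalidParameterError(
                f"branches must carry the four unique labels {BRANCH_LABELS}, got {labels}"
            )
        if labels != BRANCH_LABELS:
            # normalise to canonical order so array extraction is positional
            object.__setattr__(
                self,
                "branches",
                tuple(sorted(self.branches, key=lambda br: BRANCH_LABELS.index(br.label))),
            )
        if len(self.r_internal) != 4 or not all(r > 0 for r in self.r_internal):
            raise InvalidParameterError("r_internal must be four strictly positive values")
        if self.p_atrium < 0:
            raise InvalidParameterError("p_atrium must be non-negative")
        if not self.inlet_diameter > 0:
            raise InvalidParameterError("inlet_diameter must be positive")

    def branch(self, label: str) -> BranchParams:
        """Return the branch with the given label."""
        for br in self.branches:
            if br.label == label:
                return br
        raise KeyError(label)

    # -- array views used by the integrator ---------------------------------

    def branch_arrays(self) -> dict[str, np.ndarray]:
        """Element constants as float arrays in canonical branch order."""
        return {
            "a": np.array([br.a for br in self.branches]),
            "brt": np.array([br.b + br.r2 for br in self.branches]),
            "c": np.array([br.c for br in self.branches]),
            "r_int": np.asarray(self.r_internal, dtype=float),
        }

    # -- JSON round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "branches": [
                {"label": br.label, "a": br.a, "b": br.b, "r2": br.r2, "c": br.c}
                for br in self.branches
            ],
            "terminal": {"r_t": self.terminal.r_t, "c_t": self.terminal.c_t},
            "p_atrium_mmHg": convert_pressure(self.p_atrium, "Pa", "mmHg"),
            "fluid": {"rho": self.fluid.density, "mu": self.fluid.viscosity},
            "r_internal": list(self.r_internal),
            "inlet_diameter_m": self.inlet_diameter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LPNConfig":
        for key in ("branches", "terminal", "p_atrium_mmHg"):
            if key not in d:
                raise KeyError(f"LPN config is missing required key {key!r}")
        branches = tuple(
            BranchParams(label=b["label"], a=b["a"], b=b["b"], r2=b["r2"], c=b["c"])
            for b in d["branches"]
        )
        terminal = TerminalParams(r_t=d["terminal"]["r_t"], c_t=d["terminal"]["c_t"])
        fluid = (
            FluidProperties(density=d["fluid"]["rho"], viscosity=d["fluid"]["mu"])
            if "fluid" in d
            else WATER
        )
        r_int = d.get("r_internal", 1.0e6)
        if isinstance(r_int, (int, float)):
            r_int = (float(r_int),) * 4
        else:
            r_int = tuple(float(r) for r in r_int)
        return cls(
            branches=branches,
            terminal=terminal,
            p_atrium=convert_pressure(d["p_atrium_mmHg"], "mmHg", "Pa"),
            fluid=fluid,
            r_internal=r_int,
            inlet_diameter=d.get("inlet_diameter_m", 0.012),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LPNConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_network() -> LPNConfig:
    """The calibrated preset replicating the experimental circuit.

    Tap coefficients (a, b), tube resistances and compliances were
    characterised against the physical rig; the atrial reservoir holds a
    constant head of 8 mmHg and the working fluid is water.
    """
    return LPNConfig(
        branches=(
            BranchParams("innominate", a=1e13, b=-8e6, r2=5e7, c=1.88e-9),
            BranchParams("carotid", a=2e13, b=-5e6, r2=1e8, c=1.98e-9),
            BranchParams("subclavian", a=1e13, b=-8e6, r2=1e7, c=3.06e-9),
            BranchParams("descending_aorta", a=8e11, b=-1e7, r2=2.5e7, c=1.48e-9),
        ),
        terminal=TerminalParams(r_t=8e7, c_t=0.36e-11),
        p_atrium=8.0 * MMHG_TO_PA,
        fluid=WATER,
        r_internal=(1.0e6,) * 4,
        inlet_diameter=0.012,
    )


def nonlinear_drop(branch: BranchParams, q: float) -> float:
    """Pressure drop across the tap alone, ``ΔP₁ = a·Q² + b·Q``.

    The quadratic fit was calibrated for forward flow; for q < 0 the law is
    extended antisymmetrically (odd function) so the element resists reverse
    flow as well.
    """
    aq = abs(q)
    return math.copysign(branch.a * aq * aq + branch.b * aq, q) if q != 0 else 0.0


def series_drop(branch: BranchParams, q: float) -> float:
    """Drop across tap plus tube in series: ``a·Q² + (b + r2)·Q`` (odd in Q)."""
    aq = abs(q)
    return math.copysign(branch.a * aq * aq + (branch.b + branch.r2) * aq, q) if q else 0.0


def series_branch_flow(branch: BranchParams, dp: float) -> float:
    """Invert the series tap+tube law: the flow producing pressure drop ``dp``.

    For dp ≥ 0 this is the unique non-negative root of
    ``a·Q² + (b + r2)·Q = dp``; for dp < 0 the odd extension applies.
    """
    brt = branch.b + branch.r2
    if brt <= 0:
        raise InvalidParameterError(
            f"branch {branch.label!r}: b + r2 must be positive to invert the series law"
        )
    return _series_flow(branch.a, brt, dp)


def _series_flow(a, brt, dp):
    """Vector-friendly core of :func:`series_branch_flow` (odd in dp)."""
    adp = np.abs(dp)
    q = (np.sqrt(brt * brt + 4.0 * a * adp) - brt) / (2.0 * a)
    out = np.sign(dp) * q
    return float(out) if np.ndim(out) == 0 else out


_PRESSURE_FACTORS = {"Pa": 1.0, "mmHg": MMHG_TO_PA}
_FLOW_FACTORS = {"m3/s": 1.0, "m³/s": 1.0, "L/min": LMIN_TO_M3S}


def _convert(value, from_unit, to_unit, factors, kind):
    try:
        f_from = factors[from_unit]
        f_to = factors[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown {kind} unit {exc.args[0]!r}; expected one of {sorted(factors)}"
        ) from None
    return value * (f_from / f_to)


def convert_pressure(value, from_unit: str, to_unit: str):
    """Convert pressure between 'Pa' and 'mmHg' (1 mmHg = 133.322 Pa)."""
    return _convert(value, from_unit, to_unit, _PRESSURE_FACTORS, "pressure")


def convert_flow(value, from_unit: str, to_unit: str):
    """Convert volumetric flow between 'm3/s' and 'L/min'."""
    return _convert(value, from_unit, to_unit, _FLOW_FACTORS, "flow")
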