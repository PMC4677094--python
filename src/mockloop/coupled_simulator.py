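"""Multi-scale coupling: 0D aortic-junction surrogate driving the LPN.

The spatially resolved aortic domain of the original multi-scale model is
replaced here by an algebraic junction: at every instant the prescribed
inlet flow is distributed over the four branches through small linear
internal resistances, which stand in for the viscous loss of the 3D domain.
The five network pressures (four branch Windkessel nodes and the common
terminal node) evolve by explicit forward-Euler integration with a time
step of 1e-4 s, repeated over cardiac cycles until the pressure state is
periodic.

Stability: the terminal compliance (c_t = 3.6e-12 m³/Pa) makes the common
node marginally stiff. A guard estimates the fastest local time constant at
the operating point and refuses a dt beyond 0.8 of the explicit stability
bound; inside the loop an automatic sub-stepping fallback divides any step
whose instantaneous time constant (evaluated from the current branch flows)
would violate that bound — in the normal operating regime no sub-stepping
occurs and the scheme is plain Euler at the configured dt.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .lpn_model import MMHG_TO_PA, LPNConfig, _series_flow
from .synthetic_waveform import FlowWaveform

__all__ = [
    "NetworkState",
    "SolverSettings",
    "SimulationResult",
    "junction_solve",
    "step_euler",
    "run_to_periodic",
    "steady_state_pressure",
    "stability_dt_bound",
    "wss_poiseuille",
    "power_dissipation",
    "SolverInstabilityError",
    "NotConvergedError",
]

logger = logging.getLogger(__name__)


class SolverInstabilityError(RuntimeError):
    """The integration diverged (a pressure left the physically plausible range)."""


class NotConvergedError(RuntimeError):
    """An operation requiring a periodic solution received a non-converged one."""


@dataclass
class NetworkState:
    """Instantaneous pressures of the five storage nodes."""

    p_branch: np.ndarray  # Pa, four compliance nodes in canonical branch order
    p_common: float  # Pa
    t: float = 0.0  # s

    def __post_init__(self) -> None:
        self.p_branch = np.asarray(self.p_branch, dtype=float)
        if self.p_branch.shape != (4,):
            raise ValueError("p_branch must hold exactly four pressures")
        if not (np.all(np.isfinite(self.p_branch)) and math.isfinite(self.p_common)):
            raise ValueError("pressures must be finite")


@dataclass(frozen=True)
class SolverSettings:
    dt: float = 1e-4  # s
    max_cycles: int = 50
    periodicity_tol: float = 0.1 * MMHG_TO_PA  # Pa
    initial_pressure: float = 80.0 * MMHG_TO_PA  # Pa
    auto_substep: bool = True

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.max_cycles < 2:
            raise ValueError("max_cycles must be at least 2")
        if not self.periodicity_tol > 0:
            raise ValueError("periodicity_tol must be positive")


@dataclass
class SimulationResult:
    """Final-cycle time series and convergence diagnostics.

    ``q_junction`` are the instantaneous flows the junction delivers into
    each branch; ``q_out`` are the flows leaving each branch compliance node
    through its tap+tube toward the common section. All series share the
    ``times`` grid.
    """

    times: np.ndarray
    q_in: np.ndarray
    p_aorta: np.ndarray
    q_junction: np.ndarray  # (4, n)
    q_out: np.ndarray  # (4, n)
    p_branch: np.ndarray  # (4, n)
    p_common: np.ndarray
    cycles_run: int
    final_delta: float  # max node-pressure change between last two cycles (Pa)
    converged: bool
    config: LPNConfig = field(repr=False, default=None)
    period: float = 0.0

    def flow_split_percent(self) -> np.ndarray:
        """Cycle-mean branch flows as % of cycle-mean inlet flow."""
        return 100.0 * self.q_junction.mean(axis=1) / self.q_in.mean()


def junction_solve(config: LPNConfig, state: NetworkState, q_in: float):
    """Distribute the inlet flow over the four branches.

    The junction node is massless: with linear internal resistances the
    junction pressure and branch flows satisfy q_j = (p_a − p_j)/r_j and
    Σ q_j = q_in, giving the closed form
    p_a = (q_in + Σ p_j/r_j) / (Σ 1/r_j).
    """
    r = np.asarray(config.r_internal, dtype=float)
    if np.any(r <= 0):
        raise ValueError("singular junction: all r_internal must be positive")
    g = 1.0 / r
    p_a = (q_in + float(state.p_branch @ g)) / g.sum()
    q = (p_a - state.p_branch) * g
    return p_a, q


def _derivs(arr, p_branch, p_common, p_atrium, r_t, q_in):
    """Flows and pressure derivatives at one instant (vectorised core)."""
    g = 1.0 / arr["r_int"]
    p_a = (q_in + p_branch @ g) / g.sum()
    q_j = (p_a - p_branch) * g
    q_out = _series_flow(arr["a"], arr["brt"], p_branch - p_common)
    dp_branch = (q_j - q_out) / arr["c"]
    q_t = (p_common - p_atrium) / r_t
    dp_common = (q_out.sum() - q_t) / arr["ct"]
    return p_a, q_j, q_out, q_t, dp_branch, dp_common


def _local_tau(arr, r_t, q_out):
    """Fastest local time constant: the terminal node, whose conductance sum
    uses the tangent conductances of the branch laws at the current flows."""
    g_branch = 1.0 / (2.0 * arr["a"] * np.abs(q_out) + arr["brt"])
    return arr["ct"] / (g_branch.sum() + 1.0 / r_t)


def _solver_arrays(config: LPNConfig) -> dict[str, np.ndarray]:
    arr = config.branch_arrays()
    arr["ct"] = config.terminal.c_t
    return arr


def step_euler(config: LPNConfig, state: NetworkState, q_in: float, dt: float) -> NetworkState:
    """One forward-Euler update of the five node ODEs.

    c_j·dp_j/dt = q_j − q_out_j and c_t·dp_c/dt = Σ q_out_j − (p_c − p_atm)/r_t.
    """
    arr = _solver_arrays(config)
    _, _, q_out, _, dpb, dpc = _derivs(
        arr, state.p_branch, state.p_common, config.p_atrium, config.terminal.r_t, q_in
    )
    new = NetworkState(
        p_branch=state.p_branch + dt * dpb,
        p_common=state.p_common + dt * dpc,
        t=state.t + dt,
    )
    if np.any(np.abs(new.p_branch) > 1e6) or abs(new.p_common) > 1e6:
        raise SolverInstabilityError(
            "pressure exceeded 1e6 Pa; reduce dt or enable sub-stepping"
        )
    return new


def stability_dt_bound(config: LPNConfig, q_ref: float) -> float:
    """Explicit-Euler step bound 2·τ with τ evaluated at the steady operating
    point for a reference (cycle-mean) inlet flow ``q_ref``."""
    arr = _solver_arrays(config)
    if q_ref > 0:
        _, q_branch = _steady_split(config, q_ref)
    else:
        q_branch = np.zeros(4)
    return 2.0 * _local_tau(arr, config.terminal.r_t, q_branch)


def run_to_periodic(
    config: LPNConfig, waveform: FlowWaveform, settings: SolverSettings = SolverSettings()
) -> SimulationResult:
    """Integrate over repeated cardiac cycles until the pressure state is periodic.

    Convergence: the maximum change of any node pressure between the ends of
    consecutive cycles falls below ``periodicity_tol``. The final recorded
    cycle is returned together with diagnostics; a non-converged run is
    still returned, flagged.
    """
    dt = settings.dt
    if abs(waveform.dt - dt) > 1e-9 * dt:
        raise ValueError(
            f"waveform spacing {waveform.dt:g} s does not match solver dt {dt:g} s; "
            "interpolate_to_solver_grid first"
        )
    bound = stability_dt_bound(config, max(waveform.mean, 0.0))
    if dt > 0.8 * bound and not settings.auto_substep:
        raise ValueError(
            f"dt = {dt:g} s exceeds 0.8x the explicit stability bound {bound:g} s; "
            "reduce dt or enable auto_substep"
        )

    arr = _solver_arrays(config)
    r_t = config.terminal.r_t
    p_atm = config.p_atrium
    n = waveform.times.size
    q_in = waveform.flows

    p_branch = np.full(4, settings.initial_pressure, dtype=float)
    p_common = settings.initial_pressure

    rec_pa = np.empty(n)
    rec_qj = np.empty((4, n))
    rec_qo = np.empty((4, n))
    rec_pb = np.empty((4, n))
    rec_pc = np.empty(n)

    safe = 0.8 * 2.0  # fraction of the explicit bound 2*tau used per sub-step
    delta = math.inf
    cycles = 0
    for cycle in range(settings.max_cycles):
        prev_state = np.append(p_branch, p_common)
        for k in range(n):
            qk = q_in[k]
            remaining = dt
            while True:
                p_a, q_j, q_out, q_t, dpb, dpc = _derivs(
                    arr, p_branch, p_common, p_atm, r_t, qk
                )
                if remaining == dt:
                    rec_pa[k] = p_a
                    rec_qj[:, k] = q_j
                    rec_qo[:, k] = q_out
                    rec_pb[:, k] = p_branch
                    rec_pc[k] = p_common
                h = remaining
                if settings.auto_substep:
                    h = min(h, safe * _local_tau(arr, r_t, q_out))
                p_branch = p_branch + h * dpb
                p_common = p_common + h * dpc
                remaining -= h
                if remaining <= 1e-15:
                    break
            if np.any(np.abs(p_branch) > 1e6) or abs(p_common) > 1e6:
                raise SolverInstabilityError(
                    f"pressure exceeded 1e6 Pa in cycle {cycle + 1}, step {k}"
                )
        cycles = cycle + 1
        delta = float(np.max(np.abs(np.append(p_branch, p_common) - prev_state)))
        logger.info("cycle %d: max cycle-to-cycle pressure change %.4g Pa", cycles, delta)
        if delta < settings.periodicity_tol:
            break

    converged = delta < settings.periodicity_tol
    if not converged:
        logger.warning(
            "no periodic regime within %d cycles (last delta %.3g Pa)",
            settings.max_cycles,
            delta,
        )
    return SimulationResult(
        times=waveform.times.copy(),
        q_in=q_in.copy(),
        p_aorta=rec_pa,
        q_junction=rec_qj,
        q_out=rec_qo,
        p_branch=rec_pb,
        p_common=rec_pc,
        cycles_run=cycles,
        final_delta=delta,
        converged=converged,
        config=config,
        period=waveform.period,
    )


def _steady_split(config: LPNConfig, q_in: float, tol: float = 1e-12):
    """Steady-state junction-to-common pressure drop and branch flows.

    Solves Σ_j Q_j(D) = q_in by bisection on the common drop D, where each
    branch sees its series law with r_internal folded into the linear term.
    """
    arr = config.branch_arrays()
    a = arr["a"]
    brt = arr["brt"] + arr["r_int"]

    def total(D):
        return _series_flow(a, brt, D).sum()

    lo, hi = 0.0, 1.0
    while total(hi) < q_in:
        hi *= 2.0
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if total(mid) < q_in:
            lo = mid
        else:
            hi = mid
    D = 0.5 * (lo + hi)
    return D, _series_flow(a, brt, D)


def steady_state_pressure(config: LPNConfig, q_in: float):
    """Algebraic steady solution for constant inflow: (p_aorta, branch flows).

    p_common = p_atrium + r_t·q_in; the junction pressure adds the common
    drop that balances the branch series laws against q_in.
    """
    if q_in < 0:
        raise ValueError("q_in must be non-negative")
    if q_in == 0:
        return config.p_atrium, np.zeros(4)
    D, q = _steady_split(config, q_in)
    return config.p_atrium + config.terminal.r_t * q_in + D, q


def wss_poiseuille(q: float, radius: float, viscosity: float) -> float:
    """Wall shear stress τ_w = 4·μ·q/(π·r³) of fully developed laminar pipe flow.

    A cross-section-level estimate; it cannot reproduce localised 3D wall
    shear concentrations.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    return 4.0 * viscosity * q / (math.pi * radius**3)


def power_dissipation(
    result: SimulationResult,
    config: LPNConfig | None = None,
    outlet_areas: np.ndarray | None = None,
) -> float:
    """Cycle-averaged power dissipated between the inlet and the atrial return (W).

    Total-pressure bookkeeping: cycle-mean of (p + ½ρv²)·q at the junction
    inlet minus the static outflow power at the atrial reservoir minus the
    kinetic outflow power at the four branch outlets. Outlet areas default
    to the inlet area split by the branches' mean flow fractions (outlet
    diameters are not part of the network description).
    """
    if not result.converged:
        raise NotConvergedError("power dissipation requires a periodic (converged) result")
    config = config or result.config
    rho = config.fluid.density
    area_in = math.pi * (config.inlet_diameter / 2.0) ** 2
    if outlet_areas is None:
        frac = result.q_junction.mean(axis=1) / result.q_in.mean()
        outlet_areas = area_in * frac
    outlet_areas = np.asarray(outlet_areas, dtype=float)

    v_in = result.q_in / area_in
    p_total_in = result.p_aorta + 0.5 * rho * v_in**2
    power_in = float(np.mean(p_total_in * result.q_in))

    q_t = (result.p_common - config.p_atrium) / config.terminal.r_t
    power_out_static = config.p_atrium * float(np.mean(q_t))
    v_out = result.q_out / outlet_areas[:, None]
    power_out_kinetic = float(np.mean(0.5 * rho * v_out**2 * result.q_out, axis=1).sum())
    return power_in - power_out_static - power_out_kinetic
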