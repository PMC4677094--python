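"""Pulsatile inlet waveform synthesis and measurement-chain emulation.

The physical loop is driven by a piston pulsatile pump whose ejection phase
is well approximated by a half-sine; the inlet flow curve used as the
simulation boundary condition was measured by gated 2D phase-contrast MR at
29.9 ms temporal resolution and then interpolated onto the solver grid.
This module generates such a waveform, emulates the gated-PCMR sampling
(phase-bin averaging plus optional Gaussian noise), and resamples onto the
uniform integration grid.

All randomness in the package lives here, behind an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lpn_model import LMIN_TO_M3S

__all__ = [
    "FlowWaveform",
    "PumpSettings",
    "TGA_PUMP",
    "CONTROL_PUMP",
    "generate_pump_waveform",
    "emulate_pcmr_sampling",
    "interpolate_to_solver_grid",
    "flow_to_velocity",
]


@dataclass(frozen=True)
class FlowWaveform:
    """One period of a uniformly sampled volumetric flow curve.

    ``times`` start at 0 and cover [0, period) with uniform spacing
    period/n; because sampling is periodic, the plain sample mean equals the
    cycle time-average exactly.
    """

    times: np.ndarray  # s
    flows: np.ndarray  # m³/s
    period: float  # s

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flows, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)
        if t.ndim != 1 or t.size < 2 or q.shape != t.shape:
            raise ValueError("times and flows must be 1-D arrays of equal length >= 2")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if t[0] != 0.0:
            raise ValueError("first sample must be at t = 0")
        dt = self.period / t.size
        if not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform with spacing period/n")

    @property
    def dt(self) -> float:
        return self.period / self.times.size

    @property
    def mean(self) -> float:
        """Cycle-mean flow (exact for uniform periodic sampling)."""
        return float(self.flows.mean())

    @property
    def stroke_volume(self) -> float:
        """Volume ejected per cycle (m³)."""
        return self.mean * self.period


@dataclass(frozen=True)
class PumpSettings:
    """Pulsatile-pump configuration.

    cardiac_output is the cycle-mean flow (m³/s); systolic_fraction the
    portion of the cycle with forward ejection; backflow_fraction the
    amplitude of an optional brief regurgitant lobe after valve closure,
    relative to peak ejection flow.
    """

    cardiac_output: float  # m³/s
    period: float = 0.8  # s
    systolic_fraction: float = 0.5
    backflow_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.cardiac_output > 0:
            raise ValueError("cardiac_output must be positive")
        if not self.period > 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie strictly between 0 and 1")
        if not 0.0 <= self.backflow_fraction <= 0.15:
            raise ValueError("backflow_fraction must lie in [0, 0.15]")


#: Run presets: cardiac output equals the sum of the respective mean outlet flows.
TGA_PUMP = PumpSettings(cardiac_output=5.48 * LMIN_TO_M3S)
CONTROL_PUMP = PumpSettings(cardiac_output=5.25 * LMIN_TO_M3S)


def generate_pump_waveform(settings: PumpSettings, n_samples: int = 8000) -> FlowWaveform:
    """Synthesise one cycle of the pump waveform.

    Half-sine ejection over [0, f_s·T], an optional short negative lobe
    (quarter of systole long) immediately after, zero flow for the rest of
    diastole. Samples are rescaled so the cycle mean equals the configured
    cardiac output exactly.
    """
    if n_samples < 16:
        raise ValueError("n_samples must be at least 16")
    T = settings.period
    t_sys = settings.systolic_fraction * T
    t = np.arange(n_samples) * (T / n_samples)
    # continuous-time peak: cycle mean of the half-sine is (2/π)·f_s·Q_peak
    q_peak = settings.cardiac_output * np.pi / (2.0 * settings.systolic_fraction)
    q = np.where(t < t_sys, q_peak * np.sin(np.pi * t / t_sys), 0.0)
    if settings.backflow_fraction > 0:
        t_back = 0.25 * t_sys
        in_lobe = (t >= t_sys) & (t < t_sys + t_back)
        q = np.where(
            in_lobe,
            -settings.backflow_fraction * q_peak * np.sin(np.pi * (t - t_sys) / t_back),
            q,
        )
    q *= settings.cardiac_output / q.mean()  # exact discrete mean
    return FlowWaveform(times=t, flows=q, period=T)


def emulate_pcmr_sampling(
    w: FlowWaveform, dt_sample: float, noise_sd: float = 0.0, seed: int = 0
) -> FlowWaveform:
    """Emulate gated phase-contrast MR measurement of a flow curve.

    Retrospective gating reconstructs one averaged cycle at a coarse
    temporal resolution; this is modelled as phase-bin averaging of the
    native samples onto round(T/dt_sample) uniform bins, followed by
    additive Gaussian noise of standard deviation ``noise_sd`` (m³/s) drawn
    from a generator seeded with ``seed``.
    """
    if dt_sample >= w.period:
        raise ValueError("dt_sample must be smaller than the period")
    if dt_sample < w.dt * (1 - 1e-9):
        raise ValueError("dt_sample must be at least the native sample spacing")
    n_bins = max(1, round(w.period / dt_sample))
    dt_eff = w.period / n_bins
    n = w.times.size
    bins = (np.arange(n) * n_bins) // n  # exact uniform phase binning
    sums = np.bincount(bins, weights=w.flows, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    flows = sums / counts
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        flows = flows + rng.normal(0.0, noise_sd, size=n_bins)
    return FlowWaveform(times=np.arange(n_bins) * dt_eff, flows=flows, period=w.period)


def interpolate_to_solver_grid(w: FlowWaveform, dt: float = 1e-4) -> FlowWaveform:
    """Periodic linear interpolation onto the uniform solver grid.

    The curve wraps: the value at t = T equals the value at t = 0.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    n = max(2, round(w.period / dt))
    t_new = np.arange(n) * (w.period / n)
    t_ext = np.concatenate([w.times, [w.period]])
    q_ext = np.concatenate([w.flows, [w.flows[0]]])
    return FlowWaveform(times=t_new, flows=np.interp(t_new, t_ext, q_ext), period=w.period)


def flow_to_velocity(q: float, diameter: float) -> float:
    """Cross-section mean velocity (m/s) of flow ``q`` through a circular lumen."""
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    return q / (np.pi * (diameter / 2.0) ** 2)
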