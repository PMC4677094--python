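"""Experimental-vs-computational comparison statistics.

Implements the summary quantities used to validate the simulated loop
against measured data: waveform features (cycle mean, peak, minimum,
values at chosen instants), outlet flow-split tables, percent errors,
squared Pearson correlation and Bland-Altman limits of agreement, plus a
report assembler and the published reference values of the original
bench/CFD comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .lpn_model import BRANCH_LABELS, MMHG_TO_PA, LMIN_TO_M3S
from .coupled_simulator import SimulationResult

__all__ = [
    "WaveformFeatures",
    "SplitTable",
    "AgreementStats",
    "ComparisonReport",
    "MeasuredSummary",
    "waveform_features",
    "flow_split",
    "percent_error",
    "max_split_error",
    "r_squared",
    "bland_altman",
    "build_report",
    "paper_statistics",
    "REFERENCE_SPLITS",
    "REFERENCE_PRESSURES",
]

# Published reference comparison: mean outlet flows (L/min) and bracketed flow
# splits (%) from 2D PCMR quantification vs the CFD solution, per anatomy.
REFERENCE_SPLITS = {
    "tga": {
        "cmr": {"lmin": (0.92, 0.54, 1.17, 2.92), "pct": (16.7, 9.9, 21.4, 53.1)},
        "cfd": {"lmin": (0.86, 0.56, 0.98, 3.02), "pct": (15.7, 10.3, 17.8, 55.1)},
    },
    "control": {
        "cmr": {"lmin": (0.85, 0.59, 0.92, 3.39), "pct": (14.6, 10.2, 15.9, 57.9)},
        "cfd": {"lmin": (0.88, 0.58, 0.88, 2.91), "pct": (16.7, 11.1, 16.9, 55.3)},
    },
}

# Published aortic pressures (mmHg): measured mean / CFD mean, and the measured
# peak-systolic and minimum-diastolic values.
REFERENCE_PRESSURES = {
    "tga": {"measured_mean": 84.6, "cfd_mean": 85.7, "peak": 106.0, "minimum": 60.0},
    "control": {"measured_mean": 87.0, "cfd_mean": 83.2, "peak": 105.0, "minimum": 66.0},
}

#: Cycle instants (s) representing early/peak/late systole and diastole.
COMPARISON_INSTANTS = (0.1, 0.2, 0.4, 0.6)


@dataclass(frozen=True)
class WaveformFeatures:
    cycle_mean: float
    peak: float
    minimum: float
    values_at: dict[float, float]


@dataclass(frozen=True)
class SplitTable:
    """Per-branch mean flows (L/min) and their percentages of a reference flow."""

    flows_lmin: tuple[float, ...]
    percentages: tuple[float, ...]
    reference_lmin: float


@dataclass(frozen=True)
class AgreementStats:
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class MeasuredSummary:
    """Measured side of a comparison: mean outlet flows and pressure features.

    ``flow_series_lmin``, if given, maps branch labels to per-branch flow
    time series (uniform grid over one cycle) used for the correlation and
    Bland-Altman statistics.
    """

    mean_flows_lmin: tuple[float, float, float, float]
    mean_pressure_mmhg: float | None = None
    reference_flow_lmin: float | None = None  # None -> sum of branch means
    flow_series_lmin: dict[str, np.ndarray] | None = None
    series_period: float | None = None


@dataclass(frozen=True)
class ComparisonReport:
    measured_split: SplitTable
    simulated_split: SplitTable
    split_differences_pct: tuple[float, ...]  # measured − simulated, per branch
    max_split_error_pct: float
    max_split_error_branch: str
    pressure_percent_error: float | None
    pressure_features_mmhg: WaveformFeatures
    agreement: dict[str, AgreementStats]
    sampled_flows_lmin: dict[str, dict[float, float]]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pressure_features_mmhg"] = {
            "cycle_mean": self.pressure_features_mmhg.cycle_mean,
            "peak": self.pressure_features_mmhg.peak,
            "minimum": self.pressure_features_mmhg.minimum,
            "values_at": {str(k): v for k, v in self.pressure_features_mmhg.values_at.items()},
        }
        d["sampled_flows_lmin"] = {
            lbl: {str(k): v for k, v in vals.items()}
            for lbl, vals in self.sampled_flows_lmin.items()
        }
        return d


def waveform_features(series, times, sample_at=COMPARISON_INSTANTS) -> WaveformFeatures:
    """Cycle mean, extrema and periodically interpolated values of a series.

    The series must uniformly sample one full cycle (first instant 0), so
    the plain mean is the time average; requested instants wrap modulo the
    period and are linearly interpolated.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size == 0 or series.shape != times.shape:
        raise ValueError("series and times must be non-empty equal-length arrays")
    n = times.size
    period = times[1] - times[0] if n > 1 else 1.0
    period = n * period
    t_ext = np.concatenate([times, [period]])
    y_ext = np.concatenate([series, [series[0]]])
    values_at = {
        float(t): float(np.interp(float(t) % period, t_ext, y_ext)) for t in sample_at
    }
    return WaveformFeatures(
        cycle_mean=float(series.mean()),
        peak=float(series.max()),
        minimum=float(series.min()),
        values_at=values_at,
    )


def flow_split(mean_flows, reference="sum") -> SplitTable:
    """Percentage of a reference flow carried by each branch.

    ``reference`` is either a mean flow in the same units or the string
    "sum" (percentages then total 100 by construction).
    """
    flows = tuple(float(f) for f in mean_flows)
    if any(f < 0 for f in flows):
        raise ValueError("mean flows must be non-negative")
    ref = sum(flows) if isinstance(reference, str) and reference == "sum" else float(reference)
    if ref <= 0:
        raise ValueError("reference flow must be positive")
    return SplitTable(
        flows_lmin=flows,
        percentages=tuple(100.0 * f / ref for f in flows),
        reference_lmin=ref,
    )


def percent_error(measured: float, simulated: float) -> float:
    """Relative discrepancy 100·|simulated − measured| / |measured| (%)."""
    if measured == 0:
        raise ValueError("percent error is undefined for a zero measured value")
    return 100.0 * abs(simulated - measured) / abs(measured)


def max_split_error(measured_pct, simulated_pct):
    """Largest per-branch flow-split discrepancy in percentage points.

    Returns (value, branch label); ties resolve to the first branch in
    canonical order.
    """
    m = np.asarray(measured_pct, dtype=float)
    s = np.asarray(simulated_pct, dtype=float)
    if m.shape != (4,) or s.shape != (4,):
        raise ValueError("expected four percentages per side")
    diffs = np.abs(m - s)
    idx = int(np.argmax(diffs))  # argmax returns the first maximum
    return float(diffs[idx]), BRANCH_LABELS[idx]


def r_squared(x, y) -> float:
    """Squared Pearson correlation of paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 samples")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("r_squared is undefined for a constant series")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def bland_altman(x, y) -> AgreementStats:
    """Agreement between two paired series: bias and 1.96·SD limits.

    bias = mean(x − y); limits of agreement are bias ± 1.96 times the
    sample standard deviation (n−1 denominator) of the differences.
    r_squared of the pair is included when both series are non-degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length series of at least 3 samples")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r2 = r_squared(x, y)
    except ValueError:
        r2 = 1.0 if np.allclose(x, y) else 0.0
    return AgreementStats(
        r_squared=r2, bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd
    )


def _resample_periodic(times, series, period, t_new):
    t_ext = np.concatenate([times, [period]])
    y_ext = np.concatenate([series, [series[0]]])
    return np.interp(np.asarray(t_new) % period, t_ext, y_ext)


def build_report(
    measured: MeasuredSummary,
    simulated: SimulationResult,
    sample_at=COMPARISON_INSTANTS,
) -> ComparisonReport:
    """Assemble the full measured-vs-simulated comparison.

    The simulated flow split is referenced to the cycle-mean inlet flow
    (identical to the outlet sum at periodicity, by mass conservation); the
    measured split uses the explicit reference if one is given, else the sum
    of the measured branch means.
    """
    sim_flows_lmin = simulated.q_junction.mean(axis=1) / LMIN_TO_M3S
    sim_ref = simulated.q_in.mean() / LMIN_TO_M3S
    simulated_split = flow_split(sim_flows_lmin, reference=sim_ref)
    measured_split = flow_split(
        measured.mean_flows_lmin,
        reference="sum" if measured.reference_flow_lmin is None else measured.reference_flow_lmin,
    )
    diffs = tuple(
        m - s for m, s in zip(measured_split.percentages, simulated_split.percentages)
    )
    err, branch = max_split_error(measured_split.percentages, simulated_split.percentages)

    p_mmhg = simulated.p_aorta / MMHG_TO_PA
    p_features = waveform_features(p_mmhg, simulated.times, sample_at)
    p_err = (
        percent_error(measured.mean_pressure_mmhg, p_features.cycle_mean)
        if measured.mean_pressure_mmhg is not None
        else None
    )

    sampled = {}
    agreement = {}
    for i, lbl in enumerate(BRANCH_LABELS):
        q_lmin = simulated.q_junction[i] / LMIN_TO_M3S
        feats = waveform_features(q_lmin, simulated.times, sample_at)
        sampled[lbl] = feats.values_at
        if measured.flow_series_lmin and lbl in measured.flow_series_lmin:
            meas = np.asarray(measured.flow_series_lmin[lbl], dtype=float)
            period = measured.series_period or simulated.period
            t_meas = np.arange(meas.size) * (period / meas.size)
            sim_on_meas = _resample_periodic(simulated.times, q_lmin, simulated.period, t_meas)
            agreement[lbl] = bland_altman(meas, sim_on_meas)
    return ComparisonReport(
        measured_split=measured_split,
        simulated_split=simulated_split,
        split_differences_pct=diffs,
        max_split_error_pct=err,
        max_split_error_branch=branch,
        pressure_percent_error=p_err,
        pressure_features_mmhg=p_features,
        agreement=agreement,
        sampled_flows_lmin=sampled,
    )


def paper_statistics() -> dict:
    """Recompute the published validation statistics from the bundled
    reference tables (mean-pressure percent errors and the largest
    flow-split discrepancy per anatomy)."""
    out = {}
    for model in ("tga", "control"):
        press = REFERENCE_PRESSURES[model]
        err, branch = max_split_error(
            REFERENCE_SPLITS[model]["cmr"]["pct"], REFERENCE_SPLITS[model]["cfd"]["pct"]
        )
        out[model] = {
            "pressure_percent_error": round(
                percent_error(press["measured_mean"], press["cfd_mean"]), 1
            ),
            "max_split_error_pct": round(err, 1),
            "max_split_error_branch": branch,
            "mean_pressure_measured_mmhg": press["measured_mean"],
            "mean_pressure_cfd_mmhg": press["cfd_mean"],
        }
    return out
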