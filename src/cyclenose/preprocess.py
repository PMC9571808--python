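"""Cycle segmentation, smoothing, per-cycle auto-scaling and virtual sensors.

The raw trace is cut into fixed-length temperature cycles (1100 samples for
the default program).  Baseline correction is smoothing followed by per-cycle
auto-scaling: each cycle is centred and scaled to sample standard deviation
100, which removes additive baseline drift exactly and multiplicative gain
drift up to first order.  The "virtual sensors" are the per-plateau mean
signals tracked across consecutive cycles — one virtual sensor per plateau
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .sensor_sim import CARRIER, SensorTrace, TemperatureProgram

__all__ = [
    "Cycle",
    "VirtualSensorSet",
    "PreprocessParams",
    "segment_cycles",
    "sg_smooth",
    "autoscale_cycle",
    "relative_response",
    "virtual_sensors",
    "preprocess_trace",
    "observation_cycles",
    "cycles_to_frame",
]

# phase ordering used for majority-rule tie-breaks (ties go to the later phase)
_PHASES = ("baseline", "exposure", "recovery")


class DegenerateCycleError(ValueError):
    """Cycle has zero variance; auto-scaling is undefined."""


@dataclass
class Cycle:
    """One temperature cycle, raw or standardized."""

    values: np.ndarray
    cycle_index: int
    raw_mean: float
    gas: str
    conc_ppb: float
    phase: str
    standardized: bool = False

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class VirtualSensorSet:
    """Per-plateau mean signal across consecutive cycles.

    ``values[i, p]`` is the mean of cycle ``i`` within plateau ``p``'s window.
    """

    plateau_temps_c: tuple[float, ...]
    values: np.ndarray  # (n_cycles, n_plateaus)
    cycle_indices: np.ndarray

    @property
    def n_sensors(self) -> int:
        return len(self.plateau_temps_c)

    def series(self, p: int) -> np.ndarray:
        return self.values[:, p]


def relative_response(i_air, i_gas):
    """Relative response (%) = |I_air − I_gas| / I_air × 100.

    ``i_air`` must be positive; accepts scalars or arrays.
    """
    air = np.asarray(i_air, float)
    if np.any(air <= 0):
        raise ValueError("i_air must be positive")
    out = np.abs(air - np.asarray(i_gas, float)) / air * 100.0
    return float(out) if out.ndim == 0 else out


def sg_smooth(y: np.ndarray, window_length: int = 11, polyorder: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing; preserves polynomials of degree <= polyorder."""
    y = np.asarray(y, float)
    if window_length % 2 == 0:
        raise ValueError("window_length must be odd")
    if window_length <= polyorder:
        raise ValueError("window_length must exceed polyorder")
    if window_length > len(y):
        raise ValueError("window_length exceeds signal length")
    return savgol_filter(y, window_length, polyorder)


def autoscale_cycle(cycle: Cycle) -> Cycle:
    """Auto-scale: (y − ȳ) / s × 100 with the (n−1)-denominator sample SD.

    Output has mean 0 and sample standard deviation 100.  Raises
    DegenerateCycleError for a constant cycle.
    """
    y = np.asarray(cycle.values, float)
    mean = y.mean()
    sd = y.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateCycleError(
            f"cycle {cycle.cycle_index} has zero variance; cannot auto-scale"
        )
    return replace(cycle, values=(y - mean) / sd * 100.0, raw_mean=float(mean), standardized=True)


def _sample_phases(trace: SensorTrace) -> np.ndarray:
    """Per-sample phase: SA before any VOC is baseline, VOC is exposure,
    SA after a VOC segment is recovery."""
    is_voc = np.asarray(trace.gas, object) != CARRIER
    phase = np.where(is_voc, "exposure", "baseline").astype(object)
    if is_voc.any():
        after = np.maximum.accumulate(is_voc)
        phase[(~is_voc) & after] = "recovery"
    return phase


def _majority(values: np.ndarray, prefer_order: tuple | None = None):
    """Most frequent value; ties broken toward the later entry of prefer_order,
    or toward the later-appearing value."""
    uniq, counts = np.unique(values.astype(str), return_counts=True)
    best = counts.max()
    cands = [u for u, c in zip(uniq, counts) if c == best]
    if len(cands) == 1:
        return cands[0]
    if prefer_order is not None:
        cands.sort(key=lambda v: prefer_order.index(v) if v in prefer_order else -1)
        return cands[-1]
    # later-appearing wins
    last_pos = {v: np.max(np.nonzero(values.astype(str) == v)[0]) for v in cands}
    return max(cands, key=lambda v: last_pos[v])


def segment_cycles(trace: SensorTrace, program: TemperatureProgram) -> list[Cycle]:
    """Cut a trace (assumed to start on a cycle boundary) into whole cycles.

    Returns floor(len/n) cycles; a trailing partial cycle is discarded.  Each
    cycle is tagged with the majority (gas, concentration, phase) of its span;
    phase ties go to the later phase.
    """
    n = program.cycle_length_samples
    if len(trace) < n:
        raise ValueError(f"trace ({len(trace)} samples) shorter than one cycle ({n})")
    n_cycles = len(trace) // n
    phases = _sample_phases(trace)
    cycles = []
    for i in range(n_cycles):
        sl = slice(i * n, (i + 1) * n)
        y = np.asarray(trace.current[sl], float)
        gas = _majority(np.asarray(trace.gas[sl], object))
        phase = _majority(phases[sl], prefer_order=_PHASES)
        conc_vals = np.asarray(trace.conc_ppb[sl], float)
        conc = float(_majority(conc_vals))
        cycles.append(
            Cycle(values=y, cycle_index=i, raw_mean=float(y.mean()),
                  gas=str(gas), conc_ppb=conc, phase=str(phase))
        )
    return cycles


def virtual_sensors(
    cycles: list[Cycle],
    program: TemperatureProgram,
    window_fraction: float = 1.0,
) -> VirtualSensorSet:
    """Per-plateau mean signal for each cycle (one series per plateau).

    ``window_fraction`` < 1 uses only the trailing part of each plateau,
    excluding the temperature-step transient.
    """
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    w = program.samples_per_plateau
    skip = w - max(1, int(round(window_fraction * w)))
    vals = np.empty((len(cycles), program.n_plateaus))
    for i, c in enumerate(cycles):
        if c.n != program.cycle_length_samples:
            raise ValueError("cycle length does not match program")
        for p in range(program.n_plateaus):
            sl = program.plateau_slice(p)
            vals[i, p] = c.values[sl.start + skip: sl.stop].mean()
    return VirtualSensorSet(
        plateau_temps_c=tuple(program.plateau_temps_c),
        values=vals,
        cycle_indices=np.array([c.cycle_index for c in cycles]),
    )


@dataclass(frozen=True)
class PreprocessParams:
    """Smoothing and observation-selection parameters.

    SG defaults (11-sample window ≈ 1.1 s, cubic) suppress 10 Hz noise while
    leaving the 22 s plateau structure untouched.  ``settle_cycles`` exposure
    (and baseline) cycles are discarded per exposure to let the first-order
    gas transient settle before cycles are used as observations.
    """

    sg_window: int = 11
    sg_polyorder: int = 3
    smooth: bool = True
    settle_cycles: int = 2
    vs_window_fraction: float = 1.0


def preprocess_trace(
    trace: SensorTrace,
    program: TemperatureProgram,
    params: PreprocessParams = PreprocessParams(),
) -> list[Cycle]:
    """Smooth → segment → auto-scale: standardized cycles for one trace.

    The order matters (auto-scaling a smoothed cycle is not the same as
    smoothing a standardized one); smoothing runs on the whole trace first.
    """
    if params.smooth:
        smoothed = sg_smooth(trace.current, params.sg_window, params.sg_polyorder)
        trace = SensorTrace(
            trace.time_s, smoothed, trace.t_set_c, trace.t_meas_c,
            trace.gas, trace.conc_ppb, trace.sampling_rate_hz,
        )
    return [autoscale_cycle(c) for c in segment_cycles(trace, program)]


def observation_cycles(
    traces: list[SensorTrace],
    program: TemperatureProgram,
    params: PreprocessParams = PreprocessParams(),
    include_carrier: bool = True,
    carrier_per_trace: int | None = None,
) -> list[Cycle]:
    """Standardized observation cycles from a study's traces.

    Exposure-phase cycles after the first ``settle_cycles`` of each exposure
    become VOC observations; baseline-phase cycles after the same settling
    window become carrier (SA) observations, optionally capped per trace.
    """
    k = params.settle_cycles
    obs: list[Cycle] = []
    for trace in traces:
        cycles = preprocess_trace(trace, program, params)
        expo = [c for c in cycles if c.phase == "exposure"]
        obs.extend(expo[k:])
        if include_carrier:
            base = [c for c in cycles if c.phase == "baseline"][k:]
            if carrier_per_trace is not None:
                base = base[-carrier_per_trace:] if carrier_per_trace > 0 else []
            obs.extend(base)
    return obs


def cycles_to_frame(cycles: list[Cycle]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(cycle matrix, metadata) DataFrames for CSV export."""
    mat = pd.DataFrame(np.stack([c.values for c in cycles]))
    meta = pd.DataFrame(
        {
            "cycle_idx": [c.cycle_index for c in cycles],
            "gas": [c.gas for c in cycles],
            "conc_ppb": [c.conc_ppb for c in cycles],
            "phase": [c.phase for c in cycles],
        }
    )
    return mat, meta
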