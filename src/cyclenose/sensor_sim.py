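"""Synthetic temperature-cycled gas-sensor traces.

A single field-effect gas sensor driven through a repeating temperature
program behaves like an array of "virtual" sensors: each temperature plateau
responds differently to each analyte.  This module emulates such a device —
an Ir-gate SiCFET cycled over five plateaus between 240 and 360 °C at 10 Hz —
exposed to short-chain oxygenated VOCs (formaldehyde CH2O, formic acid
CH2O2, acetic acid CH3COOH) diluted in synthetic air (SA).

The model is phenomenological, not an adsorption-kinetics model: per-plateau
amplitude coefficients, a sub-linear power-law isotherm, first-order
transients at temperature steps and gas switches, slow multiplicative
drift, and lognormal measurement noise.  At zero noise/drift and zero time
constants the generated steady-state relative response equals the isotherm
formula exactly, which the preprocessing oracle tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "GASES",
    "CARRIER",
    "TemperatureProgram",
    "ExposureSegment",
    "ExposurePlan",
    "GasResponseModel",
    "SensorTrace",
    "StudyConfig",
    "Study",
    "simulate_trace",
    "make_study",
]

CARRIER = "SA"
GASES = (CARRIER, "CH2O", "CH2O2", "CH3COOH")


class SimulationError(ValueError):
    """Invalid simulator configuration or inputs."""


@dataclass(frozen=True)
class TemperatureProgram:
    """Repeating plateau temperature cycle.

    Defaults are five 30 °C steps descending 360→240 °C, 22 s per plateau,
    sampled at 10 Hz: a 110 s, 1100-sample cycle.
    """

    plateau_temps_c: tuple[float, ...] = (360.0, 330.0, 300.0, 270.0, 240.0)
    plateau_duration_s: float = 22.0
    sampling_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if len(self.plateau_temps_c) == 0:
            raise SimulationError("program needs at least one plateau")
        if self.plateau_duration_s <= 0:
            raise SimulationError("plateau_duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise SimulationError("sampling_rate_hz must be positive")
        spp = self.plateau_duration_s * self.sampling_rate_hz
        if abs(spp - round(spp)) > 1e-9 or round(spp) < 1:
            raise SimulationError(
                "plateau_duration_s x sampling_rate_hz must be a positive integer"
            )

    @property
    def n_plateaus(self) -> int:
        return len(self.plateau_temps_c)

    @property
    def samples_per_plateau(self) -> int:
        return int(round(self.plateau_duration_s * self.sampling_rate_hz))

    @property
    def cycle_length_samples(self) -> int:
        return self.n_plateaus * self.samples_per_plateau

    @property
    def cycle_duration_s(self) -> float:
        return self.n_plateaus * self.plateau_duration_s

    def set_temperature_cycle(self) -> np.ndarray:
        """Set-point temperature for one cycle (length ``cycle_length_samples``)."""
        return np.repeat(np.asarray(self.plateau_temps_c, float), self.samples_per_plateau)

    def plateau_slice(self, p: int) -> slice:
        """Sample window of plateau ``p`` within a cycle (half-open)."""
        w = self.samples_per_plateau
        return slice(p * w, (p + 1) * w)


@dataclass(frozen=True)
class ExposureSegment:
    gas: str
    concentration_ppb: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.gas not in GASES:
            raise SimulationError(f"unknown gas_id {self.gas!r}; expected one of {GASES}")
        if self.duration_s <= 0:
            raise SimulationError("segment duration must be positive")
        if self.concentration_ppb < 0:
            raise SimulationError("concentration must be non-negative")
        if self.gas == CARRIER and self.concentration_ppb != 0:
            raise SimulationError("carrier (SA) segments must have zero concentration")


@dataclass(frozen=True)
class ExposurePlan:
    """Ordered gas-exposure schedule: (gas, concentration ppb, duration s)."""

    segments: tuple[ExposureSegment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise SimulationError("exposure plan must contain at least one segment")

    @classmethod
    def from_tuples(cls, segs: Sequence[tuple[str, float, float]]) -> "ExposurePlan":
        return cls(tuple(ExposureSegment(g, c, d) for g, c, d in segs))

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def boundaries_s(self) -> np.ndarray:
        """Cumulative segment end times."""
        return np.cumsum([s.duration_s for s in self.segments])


# Per-plateau relative-response amplitudes (% at the 1000 ppb reference),
# listed for ascending temperature. CH2O strongest, CH3COOH weakest at
# every plateau, and each gas has its own temperature optimum (monotone
# rise for CH2O, mid-range peak for CH2O2, weak rise for CH3COOH): the
# gas-specific per-plateau pattern is what temperature-cycled operation
# exploits for discrimination.
_DEFAULT_TEMPS = (240.0, 270.0, 300.0, 330.0, 360.0)
_DEFAULT_AMPLITUDES: dict[str, tuple[float, ...]] = {
    "CH2O": (5.0, 8.0, 11.0, 13.0, 14.0),
    "CH2O2": (4.0, 6.5, 8.5, 7.5, 6.0),
    "CH3COOH": (1.5, 2.5, 3.5, 4.5, 5.5),
}


@dataclass(frozen=True)
class GasResponseModel:
    """Phenomenological gas-response model.

    Steady-state relative response (percent) of gas ``g`` at plateau
    temperature ``T`` and concentration ``c``:

        R(g, T, c) = A(g, T) * (c / c_ref) ** beta

    with ``A`` interpolated over ``temps_c``.  The sensor current is

        I(t) = I0(T_meas) * (1 + sign * sum_g R_g(t)/100) * drift(t) * noise(t)

    where the effective concentration of each gas follows a first-order lag
    (``tau_gas_s``), the measured temperature lags the set-point
    (``tau_temp_s``), drift is linear-in-time plus an optional random walk,
    and noise is multiplicative lognormal so the current stays positive.
    """

    temps_c: tuple[float, ...] = _DEFAULT_TEMPS
    amplitudes_pct: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_AMPLITUDES)
    )
    beta: float = 0.7
    c_ref_ppb: float = 1000.0
    tau_gas_s: float = 60.0
    tau_temp_s: float = 2.0
    drift_per_hour: float = 0.005
    drift_rw_sd: float = 0.0
    noise_sd: float = 0.001
    response_sign: float = -1.0
    baseline_current: float = 100.0
    baseline_temp_coeff: float = 0.3

    def __post_init__(self) -> None:
        for g, amps in self.amplitudes_pct.items():
            if g == CARRIER:
                raise SimulationError("carrier gas has no response amplitudes")
            if g not in GASES:
                raise SimulationError(f"unknown gas_id {g!r} in amplitudes")
            if len(amps) != len(self.temps_c):
                raise SimulationError("amplitude list length must match temps_c")
            if any(a < 0 for a in amps):
                raise SimulationError("amplitudes must be non-negative")
        if self.beta <= 0 or self.c_ref_ppb <= 0:
            raise SimulationError("beta and c_ref_ppb must be positive")
        if min(self.tau_gas_s, self.tau_temp_s) < 0:
            raise SimulationError("time constants must be non-negative")

    def amplitude(self, gas: str, temp_c: float | np.ndarray) -> np.ndarray:
        """A(gas, T) in percent, interpolated over the model's temperature grid."""
        order = np.argsort(self.temps_c)
        t = np.asarray(self.temps_c, float)[order]
        a = np.asarray(self.amplitudes_pct[gas], float)[order]
        return np.interp(temp_c, t, a)

    def relative_response(
        self, gas: str, temp_c: float | np.ndarray, conc_ppb: float | np.ndarray
    ) -> np.ndarray:
        """Steady-state relative response R(gas, T, c) in percent."""
        if gas == CARRIER:
            return np.zeros(np.broadcast(np.asarray(temp_c), np.asarray(conc_ppb)).shape)
        c = np.asarray(conc_ppb, float)
        return self.amplitude(gas, temp_c) * (c / self.c_ref_ppb) ** self.beta

    def baseline(self, temp_c: float | np.ndarray) -> np.ndarray:
        """Clean baseline current as a smooth function of temperature."""
        t = np.asarray(temp_c, float)
        return self.baseline_current * np.exp(self.baseline_temp_coeff * (t - 300.0) / 100.0)


@dataclass
class SensorTrace:
    """Sampled sensor time series with exposure annotations.

    All channels share one time base with constant step 1/sampling_rate.
    """

    time_s: np.ndarray
    current: np.ndarray
    t_set_c: np.ndarray
    t_meas_c: np.ndarray
    gas: np.ndarray          # per-sample nominal gas id
    conc_ppb: np.ndarray     # per-sample nominal concentration
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for ch in (self.current, self.t_set_c, self.t_meas_c, self.gas, self.conc_ppb):
            if len(ch) != n:
                raise SimulationError("all trace channels must have equal length")

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "current": self.current,
                "T_set_C": self.t_set_c,
                "T_meas_C": self.t_meas_c,
                "gas": self.gas,
                "conc_ppb": self.conc_ppb,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorTrace":
        df = pd.read_csv(path)
        dt = np.diff(df["time_s"].to_numpy())
        rate = 1.0 / np.median(dt) if len(dt) else 10.0
        return cls(
            time_s=df["time_s"].to_numpy(float),
            current=df["current"].to_numpy(float),
            t_set_c=df["T_set_C"].to_numpy(float),
            t_meas_c=df["T_meas_C"].to_numpy(float),
            gas=df["gas"].to_numpy(object),
            conc_ppb=df["conc_ppb"].to_numpy(float),
            sampling_rate_hz=float(round(rate, 6)),
        )


def _first_order(x: np.ndarray, tau_s: float, dt: float, y0: float) -> np.ndarray:
    """Discrete first-order lag toward x with time constant tau (exact ZOH step)."""
    if tau_s == 0:
        return x.astype(float, copy=True)
    alpha = 1.0 - math.exp(-dt / tau_s)
    # y[k] = (1-alpha) y[k-1] + alpha x[k], started at y0
    y, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * y0])
    return y


def simulate_trace(
    program: TemperatureProgram,
    plan: ExposurePlan,
    model: GasResponseModel | None = None,
    seed: int = 0,
) -> SensorTrace:
    """Simulate a sensor trace for an exposure plan.

    Deterministic given ``seed``.  The trace starts at a cycle boundary and
    contains ``round(plan_duration * rate)`` samples; the plan must cover at
    least one full temperature cycle.
    """
    model = model or GasResponseModel()
    rate = program.sampling_rate_hz
    dt = 1.0 / rate
    n = int(round(plan.total_duration_s * rate))
    if n < program.cycle_length_samples:
        raise SimulationError("exposure plan must cover at least one full cycle")
    rng = np.random.default_rng(seed)

    t = np.arange(n) * dt
    n_cycles = -(-n // program.cycle_length_samples)  # ceil
    t_set = np.tile(program.set_temperature_cycle(), n_cycles)[:n]
    t_meas = _first_order(t_set, model.tau_temp_s, dt, t_set[0])

    # nominal per-sample gas / concentration from the segment schedule
    seg_idx = np.searchsorted(plan.boundaries_s(), t, side="right")
    seg_idx = np.minimum(seg_idx, len(plan.segments) - 1)
    gas = np.array([plan.segments[i].gas for i in seg_idx], dtype=object)
    conc = np.array([plan.segments[i].concentration_ppb for i in seg_idx], float)

    # response: each VOC's effective concentration lags its nominal one
    resp = np.zeros(n)
    for g in sorted(set(gas) - {CARRIER}):
        c_nom = np.where(gas == g, conc, 0.0)
        c_eff = _first_order(c_nom, model.tau_gas_s, dt, 0.0)
        amp = model.amplitude(g, t_set)
        resp += model.response_sign * amp / 100.0 * (c_eff / model.c_ref_ppb) ** model.beta

    drift = 1.0 + model.drift_per_hour * t / 3600.0
    if model.drift_rw_sd > 0:
        drift = drift + np.cumsum(rng.normal(0.0, model.drift_rw_sd, n))
    if model.noise_sd > 0:
        noise = np.exp(model.noise_sd * rng.standard_normal(n))
    else:
        noise = 1.0

    current = model.baseline(t_meas) * (1.0 + resp) * drift * noise
    return SensorTrace(t, current, t_set, t_meas, gas, conc, rate)


@dataclass(frozen=True)
class StudyConfig:
    """A scaled-down exposure study: for each (gas, concentration, repetition)
    one trace of SA baseline → gas exposure → SA recovery, with concentration
    order randomized within each gas to avoid sequential-memory artefacts.
    """

    gases: tuple[str, ...] = ("CH2O", "CH2O2", "CH3COOH")
    concentrations_ppb: tuple[float, ...] = (250, 500, 1000, 1500, 2000, 2500, 3000)
    repetitions: int = 1
    baseline_cycles: int = 10
    exposure_cycles: int = 12
    recovery_cycles: int = 4
    seed: int = 0
    program: TemperatureProgram = field(default_factory=TemperatureProgram)
    model: GasResponseModel = field(default_factory=GasResponseModel)

    def __post_init__(self) -> None:
        if len(self.gases) == 0:
            raise SimulationError("study needs at least one gas")
        for g in self.gases:
            if g not in GASES or g == CARRIER:
                raise SimulationError(f"invalid study gas {g!r}")
        if len(self.concentrations_ppb) == 0:
            raise SimulationError("study needs at least one concentration")
        if self.repetitions < 1:
            raise SimulationError("repetitions must be >= 1")
        if min(self.baseline_cycles, self.exposure_cycles) < 1 or self.recovery_cycles < 0:
            raise SimulationError("phase cycle counts invalid")

    def with_model(self, **kw) -> "StudyConfig":
        return replace(self, model=replace(self.model, **kw))


@dataclass
class Study:
    traces: list[SensorTrace]
    labels: pd.DataFrame  # exposure, gas, conc_ppb, seed
    config: StudyConfig


def make_study(config: StudyConfig) -> Study:
    """Simulate one trace per exposure plus the exposure label table."""
    prog, model = config.program, config.model
    cyc = prog.cycle_duration_s
    ss = np.random.SeedSequence(config.seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])

    exposures: list[tuple[str, float]] = []
    for gas in config.gases:
        for _ in range(config.repetitions):
            concs = np.asarray(config.concentrations_ppb, float)
            order_rng.shuffle(concs)
            exposures.extend((gas, float(c)) for c in concs)

    trace_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(exposures) + 1)[1:]]
    traces, rows = [], []
    for i, ((gas, c), s) in enumerate(zip(exposures, trace_seeds)):
        segs = [(CARRIER, 0.0, config.baseline_cycles * cyc), (gas, c, config.exposure_cycles * cyc)]
        if config.recovery_cycles > 0:
            segs.append((CARRIER, 0.0, config.recovery_cycles * cyc))
        plan = ExposurePlan.from_tuples(segs)
        traces.append(simulate_trace(prog, plan, model, seed=s))
        rows.append({"exposure": i, "gas": gas, "conc_ppb": c, "seed": s})
    return Study(traces, pd.DataFrame(rows), config)
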