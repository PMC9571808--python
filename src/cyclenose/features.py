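"""Per-cycle feature catalog: windowed means, slopes, FFT magnitudes,
cycle integral and lifting.

For the default program (1100 samples at 10 Hz) the catalog is
55 means (2 s windows) + 220 slopes (0.5 s windows) + 22 FFT values
(5 s windows) + 1 integral + 1 lifting = 299 features.  Window families
tile the cycle exactly with contiguous, non-overlapping, half-open windows;
counts scale as cycle_duration / window_duration for other programs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Cycle
from .sensor_sim import TemperatureProgram

__all__ = [
    "FeatureCatalog",
    "windowed_means",
    "windowed_slopes",
    "windowed_ffts",
    "cycle_integral",
    "lifting",
    "extract_features",
]

MEAN_WINDOW_S = 2.0
SLOPE_WINDOW_S = 0.5
FFT_WINDOW_S = 5.0


def _window_samples(window_s: float, rate_hz: float, n: int, family: str) -> int:
    w = window_s * rate_hz
    if abs(w - round(w)) > 1e-9 or round(w) < 1:
        raise ValueError(f"{family} window of {window_s}s is not a whole number of samples")
    w = int(round(w))
    if n % w != 0:
        raise ValueError(f"cycle length {n} not divisible by {family} window ({w} samples)")
    return w


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered feature names and their sample windows for one program."""

    cycle_length: int
    sampling_rate_hz: float
    mean_window: int
    slope_window: int
    fft_window: int
    fft_bin: int = 1

    @classmethod
    def for_program(cls, program: TemperatureProgram, fft_bin: int = 1) -> "FeatureCatalog":
        n, rate = program.cycle_length_samples, program.sampling_rate_hz
        return cls(
            cycle_length=n,
            sampling_rate_hz=rate,
            mean_window=_window_samples(MEAN_WINDOW_S, rate, n, "mean"),
            slope_window=_window_samples(SLOPE_WINDOW_S, rate, n, "slope"),
            fft_window=_window_samples(FFT_WINDOW_S, rate, n, "fft"),
            fft_bin=fft_bin,
        )

    @property
    def n_means(self) -> int:
        return self.cycle_length // self.mean_window

    @property
    def n_slopes(self) -> int:
        return self.cycle_length // self.slope_window

    @property
    def n_ffts(self) -> int:
        return self.cycle_length // self.fft_window

    @property
    def n_features(self) -> int:
        return self.n_means + self.n_slopes + self.n_ffts + 2

    @property
    def names(self) -> list[str]:
        wm = len(str(self.n_means))
        ws = len(str(self.n_slopes))
        wf = len(str(self.n_ffts))
        return (
            [f"mean_{i + 1:0{wm}d}" for i in range(self.n_means)]
            + [f"slope_{i + 1:0{ws}d}" for i in range(self.n_slopes)]
            + [f"fft_{i + 1:0{wf}d}" for i in range(self.n_ffts)]
            + ["integral", "lifting"]
        )

    def windows(self) -> dict[str, tuple[int, int]]:
        """Feature name → half-open 0-based sample window."""
        out: dict[str, tuple[int, int]] = {}
        names = self.names
        i = 0
        for w, count in (
            (self.mean_window, self.n_means),
            (self.slope_window, self.n_slopes),
            (self.fft_window, self.n_ffts),
        ):
            for k in range(count):
                out[names[i]] = (k * w, (k + 1) * w)
                i += 1
        out["integral"] = (0, self.cycle_length)
        out["lifting"] = (0, self.cycle_length)
        return out


def _as_matrix(cycles, n: int) -> np.ndarray:
    if isinstance(cycles, Cycle):
        cycles = [cycles]
    mat = np.stack([np.asarray(c.values, float) for c in cycles])
    if mat.shape[1] != n:
        raise ValueError(f"cycle length {mat.shape[1]} does not match catalog ({n})")
    return mat


def windowed_means(cycle, catalog: FeatureCatalog) -> np.ndarray:
    """Arithmetic mean of each tiling window (default: 55 two-second windows)."""
    mat = _as_matrix(cycle, catalog.cycle_length)
    out = mat.reshape(mat.shape[0], catalog.n_means, catalog.mean_window).mean(axis=2)
    return out[0] if isinstance(cycle, Cycle) else out


def windowed_slopes(cycle, catalog: FeatureCatalog) -> np.ndarray:
    """OLS slope of each tiling window, in signal units per second
    (default: 220 half-second windows of 5 samples)."""
    mat = _as_matrix(cycle, catalog.cycle_length)
    w = catalog.slope_window
    y = mat.reshape(mat.shape[0], catalog.n_slopes, w)
    t = np.arange(w) / catalog.sampling_rate_hz
    tc = t - t.mean()
    out = (y * tc).sum(axis=2) / (tc**2).sum()
    return out[0] if isinstance(cycle, Cycle) else out


def windowed_ffts(cycle, catalog: FeatureCatalog) -> np.ndarray:
    """Magnitude of one DFT coefficient (unnormalized transform) per tiling
    window (default: 22 five-second windows of 50 samples, first non-DC bin).

    The DC bin is redundant with the windowed means, so the default
    summarizes each window by its slowest oscillatory component.
    """
    mat = _as_matrix(cycle, catalog.cycle_length)
    w = catalog.fft_window
    y = mat.reshape(mat.shape[0], catalog.n_ffts, w)
    spec = np.fft.rfft(y, axis=2)
    if not 0 <= catalog.fft_bin < spec.shape[2]:
        raise ValueError(f"fft_bin {catalog.fft_bin} out of range for window {w}")
    out = np.abs(spec[:, :, catalog.fft_bin])
    return out[0] if isinstance(cycle, Cycle) else out


def cycle_integral(cycle, catalog: FeatureCatalog) -> np.ndarray | float:
    """Trapezoidal area under the cycle vs time (signal units · s)."""
    mat = _as_matrix(cycle, catalog.cycle_length)
    out = np.trapezoid(mat, dx=1.0 / catalog.sampling_rate_hz, axis=1)
    return float(out[0]) if isinstance(cycle, Cycle) else out


def lifting(cycle, catalog: FeatureCatalog) -> np.ndarray | float:
    """Difference between the cycle's end points, taken as last − first
    (positive lifting = the cycle ends above where it started)."""
    mat = _as_matrix(cycle, catalog.cycle_length)
    out = mat[:, -1] - mat[:, 0]
    return float(out[0]) if isinstance(cycle, Cycle) else out


def extract_features(
    cycles: list[Cycle],
    catalog: FeatureCatalog | None = None,
    program: TemperatureProgram | None = None,
) -> pd.DataFrame:
    """Feature matrix: one row per cycle, catalog-ordered feature columns
    plus ``gas`` and ``conc_ppb`` label columns."""
    if catalog is None:
        catalog = FeatureCatalog.for_program(program or TemperatureProgram())
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    lengths = {c.n for c in cycles}
    if len(lengths) != 1:
        raise ValueError(f"mixed cycle lengths {sorted(lengths)}")
    blocks = np.hstack(
        [
            windowed_means(cycles, catalog),
            windowed_slopes(cycles, catalog),
            windowed_ffts(cycles, catalog),
            cycle_integral(cycles, catalog)[:, None],
            lifting(cycles, catalog)[:, None],
        ]
    )
    df = pd.DataFrame(blocks, columns=catalog.names)
    df["gas"] = [c.gas for c in cycles]
    df["conc_ppb"] = [c.conc_ppb for c in cycles]
    return df


def split_features_labels(df: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """(X, labels, feature names) from an extract_features frame."""
    label_cols = [c for c in ("gas", "conc_ppb") if c in df.columns]
    feat_cols = [c for c in df.columns if c not in label_cols]
    return df[feat_cols].to_numpy(float), df[label_cols], feat_cols
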