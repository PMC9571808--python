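"""From standardized cycles to the 299-feature vector.

Each 1100-sample cycle is smoothed (Savitzky–Golay), auto-scaled to mean 0 /
SD 100 (which removes baseline drift), and summarized by 55 window means,
220 window slopes, 22 window FFT magnitudes, the cycle integral and the
lifting (last − first sample).
"""

from cyclenose import (
    ExposurePlan,
    FeatureCatalog,
    GasResponseModel,
    TemperatureProgram,
    extract_features,
    simulate_trace,
)
from cyclenose.preprocess import preprocess_trace

program = TemperatureProgram()
plan = ExposurePlan.from_tuples([("SA", 0.0, 220.0), ("CH2O", 1500.0, 330.0)])
trace = simulate_trace(program, plan, GasResponseModel(tau_gas_s=10.0), seed=1)

cycles = preprocess_trace(trace, program)
print(f"{len(cycles)} standardized cycles; first cycle mean={cycles[0].values.mean():.2e}, "
      f"SD={cycles[0].values.std(ddof=1):.1f} (auto-scaled to 0 / 100)")

catalog = FeatureCatalog.for_program(program)
table = extract_features(cycles, catalog)
print(f"feature matrix: {table.shape[0]} cycles x {catalog.n_features} features "
      f"({catalog.n_means} means + {catalog.n_slopes} slopes + {catalog.n_ffts} FFTs "
      f"+ integral + lifting)")
last = table.iloc[-1]
print("gas cycle example:  mean_01=%.1f  slope_001=%.2f  fft_01=%.1f  "
      "integral=%.0f  lifting=%.1f" % (
          last["mean_01"], last["slope_001"], last["fft_01"],
          last["integral"], last["lifting"]))
print("Units are standardized-signal units (per second for slopes, x s for the integral).")
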