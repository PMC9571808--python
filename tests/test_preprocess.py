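"""Segmentation, smoothing, auto-scaling, relative response, virtual sensors."""

import numpy as np
import pytest

from cyclenose import (
    ExposurePlan,
    SensorTrace,
    autoscale_cycle,
    relative_response,
    segment_cycles,
    sg_smooth,
    simulate_trace,
    virtual_sensors,
)
from cyclenose.preprocess import DegenerateCycleError, preprocess_trace

from conftest import air_then_gas_plan, make_cycle


def _sa_trace(program, model, n_cycles=2, seed=0, extra=0):
    plan = ExposurePlan.from_tuples([("SA", 0.0, n_cycles * 110.0 + extra / 10.0)])
    return simulate_trace(program, plan, model, seed=seed)


class TestSegmentation:
    def test_whole_cycles(self, program, clean_model):
        trace = _sa_trace(program, clean_model, 2)
        assert len(segment_cycles(trace, program)) == 2

    def test_trailing_partial_cycle_dropped(self, program, clean_model):
        trace = _sa_trace(program, clean_model, 2, extra=150)
        assert len(trace) == 2350
        cycles = segment_cycles(trace, program)
        assert len(cycles) == 2
        assert all(c.n == 1100 for c in cycles)

    def test_short_trace_errors(self, program, clean_model):
        trace = _sa_trace(program, clean_model, 1)
        short = SensorTrace(
            trace.time_s[:500], trace.current[:500], trace.t_set_c[:500],
            trace.t_meas_c[:500], trace.gas[:500], trace.conc_ppb[:500],
            trace.sampling_rate_hz,
        )
        with pytest.raises(ValueError):
            segment_cycles(short, program)

    @pytest.mark.parametrize(
        "sa_s,expected_phase",
        [(55.0, "exposure"),   # 50/50 split: tie goes to the later phase
         (66.0, "baseline"),   # 60% baseline majority
         (44.0, "exposure")],  # 60% exposure majority
    )
    def test_gas_switch_cycle_majority_rule(self, program, clean_model, sa_s, expected_phase):
        plan = ExposurePlan.from_tuples(
            [("SA", 0.0, sa_s), ("CH2O", 1000.0, 330.0 - sa_s)]
        )
        cycles = segment_cycles(simulate_trace(program, plan, clean_model, seed=0), program)
        assert cycles[0].phase == expected_phase

    def test_segment_of_concatenated_cycles_is_identity(self, program, clean_model):
        trace = simulate_trace(program, air_then_gas_plan(gas_cycles=2), clean_model, seed=0)
        cycles = segment_cycles(trace, program)
        rebuilt = SensorTrace(
            trace.time_s, np.concatenate([c.values for c in cycles]),
            trace.t_set_c, trace.t_meas_c, trace.gas, trace.conc_ppb,
            trace.sampling_rate_hz,
        )
        again = segment_cycles(rebuilt, program)
        assert len(again) == len(cycles)
        for a, b in zip(cycles, again):
            np.testing.assert_array_equal(a.values, b.values)
            assert (a.gas, a.conc_ppb, a.phase) == (b.gas, b.conc_ppb, b.phase)


class TestSmoothing:
    def test_polynomial_passthrough(self):
        t = np.linspace(0, 1, 201)
        y = 3.0 * t**2 - 2.0 * t + 1.0
        np.testing.assert_allclose(sg_smooth(y, 11, 2), y, atol=1e-9)

    def test_constant_unchanged(self):
        y = np.full(100, 7.5)
        np.testing.assert_allclose(sg_smooth(y), y, atol=1e-12)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=2000)
        assert sg_smooth(y).var() < y.var()

    def test_invalid_windows_rejected(self):
        y = np.arange(50.0)
        with pytest.raises(ValueError):
            sg_smooth(y, window_length=10)
        with pytest.raises(ValueError):
            sg_smooth(y, window_length=3, polyorder=3)
        with pytest.raises(ValueError):
            sg_smooth(y, window_length=51)


class TestAutoscaling:
    def test_worked_example(self):
        out = autoscale_cycle(make_cycle([1.0, 2.0, 3.0], standardized=False))
        np.testing.assert_allclose(out.values, [-100.0, 0.0, 100.0], atol=1e-12)
        assert out.standardized

    def test_mean_zero_sd_hundred(self, random_cycle):
        out = autoscale_cycle(random_cycle)
        assert abs(out.values.mean()) < 1e-9 * 100
        np.testing.assert_allclose(out.values.std(ddof=1), 100.0, rtol=1e-9)

    def test_affine_invariance(self, random_cycle):
        y = random_cycle.values
        base = autoscale_cycle(make_cycle(y)).values
        scaled = autoscale_cycle(make_cycle(3.7 * y + 12.0)).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_additive_drift_removed_exactly(self, random_cycle):
        y = random_cycle.values
        np.testing.assert_allclose(
            autoscale_cycle(make_cycle(y + 123.456)).values,
            autoscale_cycle(make_cycle(y)).values,
            atol=1e-9,
        )

    def test_constant_cycle_rejected(self):
        with pytest.raises(DegenerateCycleError):
            autoscale_cycle(make_cycle(np.ones(100)))


class TestRelativeResponse:
    @pytest.mark.parametrize(
        "air,gas,expected", [(1.0, 0.9, 10.0), (5.0, 5.0, 0.0), (2.0, 2.5, 25.0)]
    )
    def test_worked_values(self, air, gas, expected):
        assert relative_response(air, gas) == pytest.approx(expected)

    def test_nonpositive_air_rejected(self):
        with pytest.raises(ValueError):
            relative_response(0.0, 1.0)
        with pytest.raises(ValueError):
            relative_response(-1.0, 1.0)


class TestVirtualSensors:
    def test_five_series_for_default_program(self, program, clean_model):
        cycles = segment_cycles(_sa_trace(program, clean_model, 3), program)
        vs = virtual_sensors(cycles, program)
        assert vs.n_sensors == 5
        assert vs.values.shape == (3, 5)

    def test_constant_cycle_gives_constant_sensors(self, program):
        cycles = [make_cycle(np.full(program.cycle_length_samples, 4.2))]
        vs = virtual_sensors(cycles, program)
        np.testing.assert_allclose(vs.values, 4.2, atol=1e-12)

    def test_zero_noise_response_recovery(self, program, clean_model):
        """Per-plateau relative response from virtual sensors equals the
        generating isotherm R(gas, T, c) to 1e-6 relative."""
        for gas, conc in (("CH2O", 1000.0), ("CH3COOH", 700.0)):
            trace = simulate_trace(
                program, air_then_gas_plan(gas=gas, conc=conc), clean_model, seed=0
            )
            vs = virtual_sensors(segment_cycles(trace, program), program)
            recovered = relative_response(vs.values[0], vs.values[1])
            expected = clean_model.relative_response(
                gas, np.array(program.plateau_temps_c), conc
            )
            np.testing.assert_allclose(recovered, expected, rtol=1e-6)


class TestPipelineOrder:
    def test_smooth_then_standardize(self, program, noisy_model):
        """preprocess_trace smooths first, then auto-scales per cycle."""
        trace = _sa_trace(program, noisy_model, 2, seed=9)
        got = preprocess_trace(trace, program)
        smoothed = sg_smooth(trace.current, 11, 3)
        manual_trace = SensorTrace(
            trace.time_s, smoothed, trace.t_set_c, trace.t_meas_c,
            trace.gas, trace.conc_ppb, trace.sampling_rate_hz,
        )
        manual = [autoscale_cycle(c) for c in segment_cycles(manual_trace, program)]
        for g, m in zip(got, manual):
            np.testing.assert_allclose(g.values, m.values, atol=1e-9)
        # reversing the order (standardize, then smooth) is a different signal
        reversed_order = sg_smooth(
            autoscale_cycle(segment_cycles(trace, program)[0]).values, 11, 3
        )
        assert not np.allclose(reversed_order, got[0].values)
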