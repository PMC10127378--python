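"""Intrinsic-property estimators: closed-form inputs, brute-force oracles,
invariances, and generator round trips."""

import numpy as np
import pytest

from slicephys.core import InsufficientDataError, Trace
from slicephys.intrinsic import (
    ap_metrics,
    detect_spikes,
    firing_rate,
    input_resistance_from_steps,
    measure_rmp,
    rheobase_from_ramp,
)
from slicephys.synth import (
    RampProtocolSpec,
    StepProtocolSpec,
    make_protocol_sweeps,
    make_ramp_stimulus,
    simulate_eif,
)
from slicephys.synth.dataset import ground_truth_from_targets

FS = 20_000.0


def flat(v, dur=1.0, fs=FS):
    return Trace(np.full(int(dur * fs), float(v)), fs=fs, kind="voltage_cc")


class TestRMP:
    def test_constant_trace(self):
        rmp, ok = measure_rmp(flat(-68.0), (0.0, 0.5))
        assert rmp == -68.0 and ok

    def test_qc_flag_outside_band(self):
        rmp, ok = measure_rmp(flat(-80.0), (0.0, 0.5))
        assert rmp == -80.0 and not ok

    def test_window_bounds_error(self):
        with pytest.raises(InsufficientDataError):
            measure_rmp(flat(-68.0, dur=0.1), (0.0, 0.5))


class TestSpikeDetection:
    def test_flat_trace_has_no_spikes(self):
        assert detect_spikes(flat(-68.0)).size == 0

    def test_constructed_spikes_at_known_times(self):
        v = np.full(int(4 * FS), -68.0)
        for t in (1.0, 2.0, 3.0):
            i = int(t * FS)
            v[i : i + 20] = 20.0
        spikes = detect_spikes(Trace(v, fs=FS, kind="voltage_cc"))
        np.testing.assert_allclose(spikes, [1.0, 2.0, 3.0], atol=1.5 / FS)

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(11)
        v = -60.0 + 8.0 * rng.standard_normal(int(1 * FS))
        tr = Trace(v, fs=FS, kind="voltage_cc")
        got = detect_spikes(tr, threshold=-40.0)
        # brute force: every upward crossing, then the same 2-ms lockout
        crossings = [i for i in range(1, v.size)
                     if v[i] >= -40.0 and v[i - 1] < -40.0]
        lock = int(0.002 * FS)
        kept = []
        for i in crossings:
            if not kept or i - kept[-1] >= lock:
                kept.append(i)
        np.testing.assert_allclose(got, np.asarray(kept) / FS, atol=1e-12)


class TestInputResistance:
    def test_exact_line(self):
        """dV = 0.1 mV/pA exactly -> 100 MOhm."""
        sweeps = []
        spec = StepProtocolSpec()
        for amp in (-200.0, -150.0, -100.0, -50.0):
            n_base = int(spec.baseline * FS)
            n_step = int(spec.step_duration * FS)
            stim = np.zeros(2 * n_base + n_step)
            stim[n_base : n_base + n_step] = amp
            v = np.full_like(stim, -68.0)
            v[n_base : n_base + n_step] += 0.1 * amp
            s = Trace(stim, fs=FS, kind="current_stim",
                      meta={"amplitude_pA": amp,
                            "step_window_s": (spec.baseline, spec.baseline + 1.0)})
            sweeps.append((s, Trace(v, fs=FS, kind="voltage_cc")))
        assert input_resistance_from_steps(sweeps) == pytest.approx(100.0)

    def test_noiseless_generator_round_trip(self):
        gt = ground_truth_from_targets(-68.0, 143.6, 87.0, noise_sigma=0.0)
        sweeps = make_protocol_sweeps(gt, StepProtocolSpec(), seed=1)
        assert input_resistance_from_steps(sweeps) == pytest.approx(143.6, rel=0.01)

    def test_offset_invariance(self):
        gt = ground_truth_from_targets(-68.0, 143.6, 87.0, noise_sigma=0.0)
        sweeps = make_protocol_sweeps(gt, StepProtocolSpec(), seed=1)
        shifted = [(s, Trace(v.samples + 10.0, fs=v.fs, kind=v.kind, meta=v.meta))
                   for s, v in sweeps]
        assert input_resistance_from_steps(shifted) == pytest.approx(
            input_resistance_from_steps(sweeps), rel=1e-9)

    def test_insufficient_sweeps_error(self):
        gt = ground_truth_from_targets(-68.0, 143.6, 87.0, noise_sigma=0.0)
        sweeps = make_protocol_sweeps(gt, StepProtocolSpec(n_steps=2), seed=1)
        with pytest.raises(InsufficientDataError):
            input_resistance_from_steps(sweeps)


class TestRheobase:
    def test_constructed_spike_reads_stimulus_at_crossing(self):
        stim = make_ramp_stimulus(RampProtocolSpec())
        v = np.full(stim.n, -68.0)
        # inject a spike at the sample where the ramp reaches 120 pA
        idx = int(np.argmin(np.abs(stim.samples - 120.0)))
        v[idx : idx + 30] = 10.0
        rb = rheobase_from_ramp(stim, Trace(v, fs=stim.fs, kind="voltage_cc"))
        assert rb == pytest.approx(120.0, abs=0.1)

    def test_no_spike_flags_absent(self):
        stim = make_ramp_stimulus(RampProtocolSpec(ramp_cap=10.0))
        gt = ground_truth_from_targets(-68.0, 143.6, 150.0, noise_sigma=0.0)
        volt, _ = simulate_eif(gt, stim, seed=0)
        assert rheobase_from_ramp(stim, volt) is None

    def test_noiseless_dynamic_overshoot_is_bounded(self):
        """The ramp reads above the static rheobase (lag + escape delay) but
        within ~30% for a control-range cell."""
        gt = ground_truth_from_targets(-68.0, 143.6, 87.0, noise_sigma=0.0)
        stim = make_ramp_stimulus(RampProtocolSpec())
        volt, _ = simulate_eif(gt, stim, seed=0)
        rb = rheobase_from_ramp(stim, volt)
        assert gt.static_rheobase < rb < 1.3 * gt.static_rheobase

    def test_monotone_in_resting_potential(self):
        """Depolarised cells need less ramp current."""
        values = []
        for em in (-75.0, -70.0, -65.0, -60.0):
            gt = ground_truth_from_targets(em, 143.6, 87.0, noise_sigma=0.0)
            stim = make_ramp_stimulus(RampProtocolSpec())
            volt, _ = simulate_eif(gt, stim, seed=0)
            values.append(rheobase_from_ramp(stim, volt))
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestFiringRateAndAPs:
    def test_rate_is_count_over_duration(self):
        v = np.full(int(40 * FS), -68.0)
        for k in range(80):
            i = int((0.25 + 0.5 * k) * FS)
            v[i : i + 20] = 10.0
        assert firing_rate(Trace(v, fs=FS, kind="voltage_cc")) == pytest.approx(2.0)

    def test_triangular_spike_metrics(self):
        """A 40 mV triangular spike, 1 ms wide at half height."""
        fs = FS
        v = np.full(int(0.2 * fs), -20.0)
        rise = np.linspace(-20.0, 20.0, int(0.001 * fs) + 1)
        fall = rise[::-1]
        i = int(0.1 * fs)
        v[i : i + rise.size] = rise
        v[i + rise.size : i + rise.size + fall.size - 1] = fall[1:]
        tr = Trace(v, fs=fs, kind="voltage_cc")
        spikes = np.array([i / fs])
        amp, hw = ap_metrics(tr, spikes, threshold=-20.0)
        assert amp == pytest.approx(40.0, rel=0.02)
        assert hw == pytest.approx(1.0, rel=0.05)

    def test_metrics_invariant_to_baseline_shift(self):
        gt = ground_truth_from_targets(-68.0, 143.6, 60.0, noise_sigma=0.0)
        from slicephys.synth import OUStimulusSpec
        stim, volt = make_protocol_sweeps(
            gt, OUStimulusSpec(1.0, 1.0, 5.0, seed=3, gain=90.0), seed=3)[0]
        spikes = detect_spikes(volt)
        assert spikes.size >= 1
        amp0, hw0 = ap_metrics(volt, spikes)
        shifted = Trace(volt.samples + 10.0, fs=volt.fs, kind=volt.kind)
        amp1, hw1 = ap_metrics(shifted, spikes, threshold=-10.0)
        assert amp1 == pytest.approx(amp0, rel=0.05)
        assert hw1 == pytest.approx(hw0, rel=0.05)

    def test_no_spikes_returns_absent(self):
        assert ap_metrics(flat(-68.0), np.array([])) == (None, None)
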