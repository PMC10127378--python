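"""Dynamic I-V method: capacitance oracles, curve construction against the
generator's own force term, EIF parameter recovery, refractory fitting and
spike-prediction scoring."""

import numpy as np
import pytest

from slicephys.core import InsufficientDataError, Trace
from slicephys.dynamic_iv import (
    DynamicIVCurve,
    EIFFit,
    EIFParams,
    _neg_force,
    build_dynamic_iv,
    estimate_capacitance,
    fit_cell,
    fit_eif,
    fit_refractory,
    predict_spikes,
    spike_coincidence,
)
from slicephys.intrinsic import detect_spikes
from slicephys.synth import (
    EIFGroundTruth,
    OUStimulusSpec,
    RefractorySpec,
    make_ou_current,
    simulate_eif,
)
from slicephys.synth.dataset import ground_truth_from_targets, naturalistic_spec

FS = 20_000.0


@pytest.fixture(scope="module")
def noiseless_sweep():
    gt = ground_truth_from_targets(-68.0, 143.6, 71.0, noise_sigma=0.0)
    stim = make_ou_current(naturalistic_spec(76.0, seed=42), FS)
    volt, spikes = simulate_eif(gt, stim, seed=0)
    return gt, stim, volt, spikes


class TestCapacitance:
    def test_noiseless_recovery(self, noiseless_sweep):
        gt, stim, volt, _ = noiseless_sweep
        for method in ("regression", "variance"):
            c = estimate_capacitance(stim, volt, method=method)
            assert c == pytest.approx(100.0, abs=2.0)

    def test_variance_closed_form_equals_grid_search(self, noiseless_sweep):
        """Closed form vs brute-force grid over C in [10, 400] pF (0.5 pF)
        minimising Var(I - C dV/dt) on the same restricted samples."""
        gt, stim, volt, _ = noiseless_sweep
        c_closed = estimate_capacitance(stim, volt, method="variance")

        from slicephys.dynamic_iv import _dvdt, exclusion_mask
        spikes = detect_spikes(volt)
        keep = exclusion_mask(volt, spikes)
        v_rest = np.median(volt.samples[keep])
        sel = keep & (np.abs(volt.samples - v_rest) <= 2.0)
        d = _dvdt(volt)[sel]
        i = stim.samples[sel]
        grid = np.arange(10.0, 400.0, 0.5)
        losses = [np.var(i - c * d) for c in grid]
        c_grid = grid[int(np.argmin(losses))]
        assert abs(c_closed - c_grid) <= 0.5

    def test_scale_invariance(self, noiseless_sweep):
        """Scaling I and V jointly by 2 leaves the estimate unchanged."""
        gt, stim, volt, _ = noiseless_sweep
        c0 = estimate_capacitance(stim, volt)
        stim2 = Trace(stim.samples * 2, fs=FS, kind="current_stim")
        volt2 = Trace(volt.samples * 2, fs=FS, kind="voltage_cc")
        # jointly doubling I and dV/dt cancels in the ratio
        c1 = estimate_capacitance(stim2, volt2,
                                  spikes=detect_spikes(volt))
        assert c1 == pytest.approx(c0, rel=0.02)


class TestCurve:
    def test_passive_leak_cell_gives_linear_curve(self):
        """With the exponential disabled (distant VT) the curve is linear,
        gradient C/tau_m, zero crossing at Em."""
        gt = EIFGroundTruth(C=100.0, Em=-68.0, Rin=143.6, VT=-10.0,
                            DeltaT=1.0, noise_sigma=0.0)
        stim = make_ou_current(naturalistic_spec(60.0, seed=3, duration=20.0), FS)
        volt, _ = simulate_eif(gt, stim, seed=0)
        curve = build_dynamic_iv(stim, volt, 100.0)
        coeffs = np.polyfit(curve.v_centers, curve.i_ion_mean, 1)
        g = coeffs[0]  # pA/mV
        em_cross = -coeffs[1] / coeffs[0]
        assert g == pytest.approx(100.0 / gt.tau_m, rel=0.01)
        assert em_cross == pytest.approx(-68.0, abs=0.3)

    def test_noiseless_curve_matches_generator_force_term(self, noiseless_sweep):
        gt, stim, volt, _ = noiseless_sweep
        curve = build_dynamic_iv(stim, volt, gt.C)
        sub = curve.v_centers <= gt.VT - 2.0
        expected = -gt.C * -_neg_force(curve.v_centers[sub], gt.tau_m, gt.Em,
                                       gt.VT, gt.DeltaT)
        # i_ion = -C*F(V); _neg_force returns -F
        expected = gt.C * _neg_force(curve.v_centers[sub], gt.tau_m, gt.Em,
                                     gt.VT, gt.DeltaT)
        scale = np.maximum(np.abs(expected), 20.0)
        assert np.all(np.abs(curve.i_ion_mean[sub] - expected) / scale < 0.02)

    def test_bin_width_robustness(self, noiseless_sweep):
        gt, stim, volt, _ = noiseless_sweep
        f1 = fit_eif(build_dynamic_iv(stim, volt, gt.C, bin_width=1.0))
        f2 = fit_eif(build_dynamic_iv(stim, volt, gt.C, bin_width=2.0))
        assert f2.params.tau_m == pytest.approx(f1.params.tau_m, rel=0.01)
        assert f2.params.Em == pytest.approx(f1.params.Em, abs=0.2)

    def test_underoccupied_bins_error(self, noiseless_sweep):
        _, stim, volt, _ = noiseless_sweep
        with pytest.raises(InsufficientDataError):
            build_dynamic_iv(stim, volt, 100.0, min_count=10 ** 9)


class TestFitEIF:
    def test_exact_synthetic_curve_recovers_parameters(self):
        v = np.arange(-80.0, -50.0, 1.0)
        y = _neg_force(v, 14.36, -68.0, -54.0, 1.5) * 100.0  # i_ion for C=100
        curve = DynamicIVCurve(v_centers=v, i_ion_mean=y,
                               i_ion_sem=np.full(v.size, 0.5),
                               counts=np.full(v.size, 1000), C_used=100.0,
                               excluded_windows=[])
        fit = fit_eif(curve)
        assert fit.params.tau_m == pytest.approx(14.36, rel=1e-3)
        assert fit.params.Em == pytest.approx(-68.0, abs=0.01)
        assert fit.params.VT == pytest.approx(-54.0, abs=0.05)
        assert fit.params.DeltaT == pytest.approx(1.5, rel=0.01)

    def test_noiseless_recovery_within_tolerances(self, noiseless_sweep):
        gt, stim, volt, _ = noiseless_sweep
        c = estimate_capacitance(stim, volt)
        fit = fit_eif(build_dynamic_iv(stim, volt, c))
        p = fit.params
        assert p.C == pytest.approx(gt.C, rel=0.05)
        assert p.tau_m == pytest.approx(gt.tau_m, rel=0.05)
        assert p.Em == pytest.approx(gt.Em, abs=abs(gt.Em) * 0.05)
        assert p.Rin == pytest.approx(gt.Rin, rel=0.05)
        assert p.VT == pytest.approx(gt.VT, abs=1.0)
        assert p.DeltaT == pytest.approx(gt.DeltaT, rel=0.15)

    def test_too_few_bins_error(self):
        v = np.arange(-70.0, -66.0, 1.0)
        curve = DynamicIVCurve(v_centers=v, i_ion_mean=np.zeros(v.size),
                               i_ion_sem=np.ones(v.size),
                               counts=np.full(v.size, 100), C_used=100.0,
                               excluded_windows=[])
        with pytest.raises(InsufficientDataError):
            fit_eif(curve)


class TestRefractory:
    def test_round_trip_recovery(self):
        """Jump 8 mV, decay 30 ms ground truth recovered within 25%."""
        ref = RefractorySpec(threshold_jump=8.0, threshold_decay_tau=30.0)
        gt = EIFGroundTruth(C=100.0, Em=-68.0, Rin=143.6, VT=-55.0,
                            DeltaT=1.5, refractory=ref, noise_sigma=30.0)
        stim = make_ou_current(naturalistic_spec(80.0, seed=12, duration=60.0), FS)
        volt, _ = simulate_eif(gt, stim, seed=5)
        spikes = detect_spikes(volt)
        assert spikes.size >= 60
        c = estimate_capacitance(stim, volt)
        base = fit_eif(build_dynamic_iv(stim, volt, c))
        rf = fit_refractory(stim, volt, spikes, c, base)
        assert rf is not None
        assert rf.threshold_jump == pytest.approx(8.0, rel=0.25)
        assert rf.decay_tau == pytest.approx(30.0, rel=0.5)

    def test_zero_jump_ground_truth_reads_null(self):
        ref = RefractorySpec(threshold_jump=0.0, threshold_decay_tau=30.0)
        gt = EIFGroundTruth(C=100.0, Em=-68.0, Rin=143.6, VT=-55.0,
                            DeltaT=1.5, refractory=ref, noise_sigma=30.0)
        stim = make_ou_current(naturalistic_spec(70.0, seed=13, duration=60.0), FS)
        volt, _ = simulate_eif(gt, stim, seed=6)
        spikes = detect_spikes(volt)
        c = estimate_capacitance(stim, volt)
        base = fit_eif(build_dynamic_iv(stim, volt, c))
        rf = fit_refractory(stim, volt, spikes, c, base)
        # either no positive jump is found, or it is indistinguishable from 0
        assert rf is None or abs(rf.threshold_jump) < 2.0 * max(rf.jump_se, 0.5)

    def test_too_few_spikes_flags_absent(self, noiseless_sweep):
        gt, stim, volt, spikes = noiseless_sweep
        base = EIFFit(params=EIFParams(C=100.0, tau_m=14.4, Em=-68.0,
                                       VT=-55.0, DeltaT=1.5))
        assert fit_refractory(stim, volt, spikes[:5], 100.0, base) is None


class TestPrediction:
    def test_self_prediction_is_exact(self, noiseless_sweep):
        gt, stim, volt, spikes = noiseless_sweep
        fit = EIFFit(params=EIFParams(C=gt.C, tau_m=gt.tau_m, Em=gt.Em,
                                      VT=gt.VT, DeltaT=gt.DeltaT))
        from slicephys.dynamic_iv import RefractoryFit
        fit.refractory = RefractoryFit(
            threshold_jump=gt.refractory.threshold_jump,
            decay_tau=gt.refractory.threshold_decay_tau, jump_se=0.0,
            vt_inf=gt.VT)
        pred = predict_spikes(fit, stim)
        np.testing.assert_allclose(pred, spikes, atol=1e-12)

    def test_zero_stimulus_predicts_nothing(self):
        fit = EIFFit(params=EIFParams(C=100.0, tau_m=14.4, Em=-68.0,
                                      VT=-54.0, DeltaT=1.5))
        stim = Trace(np.zeros(int(2 * FS)), fs=FS, kind="current_stim")
        assert predict_spikes(fit, stim).size == 0


class TestCoincidence:
    def test_identical_trains_score_one(self):
        t = np.array([0.1, 0.5, 1.2, 3.0])
        frac, gamma = spike_coincidence(t, t, duration=4.0)
        assert frac == 1.0
        assert gamma > 0.9

    def test_shifted_beyond_window_scores_zero(self):
        t = np.arange(0.1, 4.0, 0.25)
        frac, _ = spike_coincidence(t, t + 0.020, window_ms=5.0, duration=4.0)
        assert frac == 0.0

    def test_empty_observed_is_undefined(self):
        frac, gamma = spike_coincidence(np.array([]), np.array([0.1]))
        assert np.isnan(frac) and np.isnan(gamma)

    def test_greedy_matching_is_one_to_one(self):
        obs = np.array([1.000, 1.004])
        pred = np.array([1.002])
        frac, _ = spike_coincidence(obs, pred, duration=2.0)
        assert frac == pytest.approx(0.5)


class TestEndToEnd:
    def test_prediction_degrades_with_intrinsic_noise(self, ou_gain):
        """Noise-free self-prediction is perfect; intrinsic noise lowers the
        score monotonically in a coarse 3-point check."""
        base = ground_truth_from_targets(-68.0, 143.6, 71.0, noise_sigma=0.0)
        stim = make_ou_current(naturalistic_spec(ou_gain, seed=77), FS)
        scores = []
        for sigma in (0.0, 60.0, 200.0):
            gt = base.with_noise(sigma)
            volt, spikes = simulate_eif(gt, stim, seed=9)
            fit = EIFFit(params=EIFParams(C=base.C, tau_m=base.tau_m,
                                          Em=base.Em, VT=base.VT,
                                          DeltaT=base.DeltaT))
            from slicephys.dynamic_iv import RefractoryFit
            fit.refractory = RefractoryFit(
                threshold_jump=base.refractory.threshold_jump,
                decay_tau=base.refractory.threshold_decay_tau,
                jump_se=0.0, vt_inf=base.VT)
            pred = predict_spikes(fit, stim)
            frac, _ = spike_coincidence(detect_spikes(volt), pred,
                                        duration=volt.duration)
            scores.append(frac)
        assert scores[0] == pytest.approx(1.0)
        assert scores[0] >= scores[1] >= scores[2]
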