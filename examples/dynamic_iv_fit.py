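"""Parameterise a neuron from one naturalistic sweep and predict a second.

Simulates a noisy control neuron driven by summed Ornstein-Uhlenbeck
current (3 ms + 10 ms components), extracts capacitance, the dynamic I-V
curve, the EIF parameters and the post-spike threshold dynamics from that
single 40-s sweep, then integrates the fitted model deterministically
under a fresh sweep and scores the predicted spike train against the
observed one.
"""

from slicephys.dynamic_iv import detect_spikes, fit_cell, predict_spikes
from slicephys.synth import get_preset, make_ou_current, simulate_eif
from slicephys.synth.dataset import (
    calibrate_ou_gain,
    ground_truth_from_targets,
    naturalistic_spec,
)
from slicephys.synth.presets import RAMP_RHEOBASE_CORRECTION_PA

gain = calibrate_ou_gain(seed=0)
p = get_preset("control")
cell = ground_truth_from_targets(
    p.em.mean, p.rin.mean, p.rheobase.mean - RAMP_RHEOBASE_CORRECTION_PA)

fit_stim = make_ou_current(naturalistic_spec(gain, seed=1), 20_000.0)
fit_volt, _ = simulate_eif(cell, fit_stim, seed=2)
new_stim = make_ou_current(naturalistic_spec(gain, seed=11), 20_000.0)
new_volt, _ = simulate_eif(cell, new_stim, seed=12)

fit = fit_cell(fit_stim, fit_volt, holdout=(new_stim, new_volt))
q = fit.params
print(f"truth : C {cell.C:5.1f} pF  tau_m {cell.tau_m:5.2f} ms  Em {cell.Em:6.1f} mV  "
      f"Rin {cell.Rin:5.1f} MOhm  VT {cell.VT:6.2f} mV  DeltaT {cell.DeltaT:.2f} mV")
print(f"fitted: C {q.C:5.1f} pF  tau_m {q.tau_m:5.2f} ms  Em {q.Em:6.1f} mV  "
      f"Rin {q.Rin:5.1f} MOhm  VT {q.VT:6.2f} mV  DeltaT {q.DeltaT:.2f} mV")
if fit.refractory:
    r = fit.refractory
    print(f"post-spike threshold: jump {r.threshold_jump:.1f} mV decaying with "
          f"tau {r.decay_tau:.0f} ms (truth 8 mV / 120 ms)")
obs = detect_spikes(new_volt)
pred = predict_spikes(fit, new_stim)
print(f"held-out sweep: {obs.size} observed vs {pred.size} predicted spikes")
print(f"matched fraction (+-5 ms, greedy) {fit.prediction_score:.2f}; "
      f"chance-corrected Gamma {fit.gamma:.2f}")
print("a fraction in the 0.7-0.8 range means the reduced model reproduces "
      "most of the cell's spike timing")
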