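"""Theta-band analysis of a simulated carbachol-induced oscillation.

A CA3 field trace has a quiet baseline, then a 4-7 Hz oscillation that
emerges after a latency from the carbachol marker.  The analysis computes
Welch PSDs (Hanning, 2048-point FFT, resolution 4.883 Hz at 10 kHz),
subtracts the baseline spectrum, reports peak theta power, and detects
oscillation onset from the smoothed theta-band envelope.
"""

from slicephys.oscillations import compute_psd, summarize_oscillation
from slicephys.synth import OscGenSpec, make_oscillation_trace

spec = OscGenSpec(baseline_duration=120.0, post_carbachol_duration=400.0,
                  onset_latency=100.0, theta_amp=0.10, theta_freq=5.0, seed=8)
trace = make_oscillation_trace(spec)

psd = compute_psd(trace, (300.0, 500.0))
print(f"PSD resolution {psd.resolution:.6g} Hz (prints as {psd.resolution:.3f})")
print(f"theta-band (4-7 Hz) power of the oscillatory epoch: "
      f"{psd.theta_power:.2e} mV^2")

s = summarize_oscillation(trace, window_length=180.0)
print(f"peak baseline-subtracted theta power {s.peak_theta_power:.2e} mV^2 "
      f"over window {tuple(round(x) for x in s.peak_window)} s")
print(f"baseline theta power {s.baseline_theta_power:.2e} mV^2")
print(f"onset latency {s.onset_latency:.1f} s after carbachol "
      f"(generator {spec.onset_latency} s)")
print("stronger and earlier theta reflects a more excitable network")
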