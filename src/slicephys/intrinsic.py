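"""Passive and active single-neuron properties from current-clamp sweeps.

Resting membrane potential from the pre-stimulus baseline, input resistance
from the fitted gradient of steady-state voltage deflection against step
current, rheobase from the ramp protocol (stimulus value at the first
spike), firing rate from naturalistic sweeps, and action-potential shape
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, Trace, check_aligned

RMP_QC_BAND = (-75.0, -55.0)  # mV acceptance band at whole-cell breakthrough
SPIKE_THRESHOLD_MV = -20.0
SPIKE_LOCKOUT_MS = 2.0
STEADY_STATE_WINDOW_S = 0.2  # last 200 ms of a 1-s step


@dataclass
class IntrinsicSummary:
    """Per-cell intrinsic property roll-up."""

    rmp: float  # mV
    input_resistance: float  # MOhm
    rheobase: float | None  # pA; None when the ramp evoked no spike
    firing_rate: float  # Hz
    ap_amplitude: float | None  # mV
    ap_halfwidth: float | None  # ms
    rmp_qc_pass: bool = True


def measure_rmp(voltage: Trace, baseline_window: tuple[float, float]) -> tuple[float, bool]:
    """Mean voltage over a pre-stimulus window; QC flag False outside -75..-55 mV."""
    seg = voltage.slice_time(*baseline_window)
    rmp = float(np.mean(seg))
    return rmp, RMP_QC_BAND[0] <= rmp <= RMP_QC_BAND[1]


def detect_spikes(voltage: Trace, threshold: float = SPIKE_THRESHOLD_MV,
                  lockout_ms: float = SPIKE_LOCKOUT_MS) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout; times in s."""
    v = voltage.samples
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    if up.size == 0:
        return np.empty(0)
    lock = max(1, int(round(lockout_ms / 1000.0 * voltage.fs)))
    keep = [int(up[0])]
    for i in up[1:]:
        if i - keep[-1] >= lock:
            keep.append(int(i))
    return voltage.t0 + np.asarray(keep) / voltage.fs


def input_resistance_from_steps(
    sweeps: list[tuple[Trace, Trace]],
    baseline_window: tuple[float, float] | None = None,
    max_current: float = 10.0,
) -> float:
    """OLS gradient of steady-state dV against step current, in MOhm.

    Sweeps that spike and steps above ``max_current`` pA (outside the
    linear region around rest) are excluded; at least 3 usable sweeps are
    required.  The fit of dV [mV] vs dI [pA] yields the resistance via
    R [MOhm] = 1000 * gradient.
    """
    di, dv = [], []
    for stim, volt in sweeps:
        check_aligned(stim, volt)
        amp = stim.meta.get("amplitude_pA")
        win = stim.meta.get("step_window_s")
        if amp is None or win is None:
            raise InsufficientDataError("sweep lacks step metadata")
        if amp > max_current:
            continue
        # only spikes during the step (with margin) disqualify the sweep;
        # a stray baseline spike in a hyperexcitable cell does not
        spikes = detect_spikes(volt)
        if np.any((spikes >= win[0] - 0.05) & (spikes <= win[1] + 0.05)):
            continue
        base_win = baseline_window or (max(win[0] - 0.2, 0.0), win[0])
        v0 = float(np.median(volt.slice_time(*base_win)))
        vss = float(np.mean(volt.slice_time(win[1] - STEADY_STATE_WINDOW_S, win[1])))
        di.append(amp)
        dv.append(vss - v0)
    if len(di) < 3:
        raise InsufficientDataError(f"only {len(di)} usable subthreshold sweeps (need >= 3)")
    gradient = np.polyfit(np.asarray(di), np.asarray(dv), 1)[0]  # mV/pA
    return float(gradient * 1000.0)


def rheobase_from_ramp(stimulus: Trace, voltage: Trace,
                       threshold: float = SPIKE_THRESHOLD_MV) -> float | None:
    """Stimulus current at the first spike's threshold crossing, in pA.

    Returns None when the ramp evokes no spike (flagged by the caller).
    """
    check_aligned(stimulus, voltage)
    spikes = detect_spikes(voltage, threshold)
    if spikes.size == 0:
        return None
    idx = voltage.index_of(float(spikes[0]))
    return float(stimulus.samples[idx])


def firing_rate(voltage: Trace, threshold: float = SPIKE_THRESHOLD_MV) -> float:
    """Spike count divided by sweep duration, Hz."""
    return detect_spikes(voltage, threshold).size / voltage.duration


def ap_metrics(voltage: Trace, spikes: np.ndarray,
               threshold: float = SPIKE_THRESHOLD_MV,
               window_ms: float = 5.0) -> tuple[float | None, float | None]:
    """Mean action-potential amplitude (mV) and half-width (ms).

    Amplitude is peak minus the voltage at the threshold crossing; width is
    measured at half that amplitude by linear interpolation of the two
    half-amplitude crossings around the peak.  Both are baseline-shift
    invariant.  Returns (None, None) when no spikes are given.
    """
    if spikes is None or len(spikes) == 0:
        return None, None
    v = voltage.samples
    fs = voltage.fs
    half_n = int(round(window_ms / 1000.0 * fs))
    amps, widths = [], []
    for t in spikes:
        i = voltage.index_of(float(t))
        j0, j1 = max(i - half_n, 0), min(i + half_n, v.size)
        seg = v[j0:j1]
        pk = int(np.argmax(seg))
        v_cross = v[i]
        amp = seg[pk] - v_cross
        if amp <= 0:
            continue
        half = v_cross + 0.5 * amp
        # walk out from the peak to the half-amplitude crossings
        a = pk
        while a > 0 and seg[a] > half:
            a -= 1
        b = pk
        while b < seg.size - 1 and seg[b] > half:
            b += 1
        if seg[a] > half or seg[b] > half:
            continue
        ta = a + (half - seg[a]) / (seg[a + 1] - seg[a]) if seg[a + 1] != seg[a] else a
        tb = b - 1 + (half - seg[b - 1]) / (seg[b] - seg[b - 1]) if seg[b] != seg[b - 1] else b
        amps.append(amp)
        widths.append((tb - ta) * 1000.0 / fs)
    if not amps:
        return None, None
    return float(np.mean(amps)), float(np.mean(widths))


def summarize_cell(step_sweeps, ramp_sweep, ou_sweep,
                   baseline_window: tuple[float, float] = (0.0, 0.2)) -> IntrinsicSummary:
    """Full intrinsic summary for one cell's protocol set."""
    _, first_volt = step_sweeps[0]
    rmp, qc = measure_rmp(first_volt, baseline_window)
    rin = input_resistance_from_steps(step_sweeps)
    rheo = rheobase_from_ramp(*ramp_sweep)
    ou_stim, ou_volt = ou_sweep
    fr = firing_rate(ou_volt)
    spikes = detect_spikes(ou_volt)
    amp, hw = ap_metrics(ou_volt, spikes)
    return IntrinsicSummary(rmp=rmp, input_resistance=rin, rheobase=rheo,
                            firing_rate=fr, ap_amplitude=amp, ap_halfwidth=hw,
                            rmp_qc_pass=qc)
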