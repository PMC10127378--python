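"""Synthetic voltage-clamp mEPSC traces.

Events occur as a Poisson process; each adds a peak-normalised biexponential
inward (negative-going at -60 mV holding) current of sampled amplitude;
Gaussian baseline noise is added on top.  Generation applies no amplitude
cut-off: the >6 pA acceptance rule belongs to detection, and the returned
ground-truth table records every generated event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import SpecificationError, Trace

VC_FS = 10_000.0  # Hz; sufficient to resolve 0.5 ms rise kinetics


@dataclass(frozen=True)
class MepscGenSpec:
    mean_interval: float  # s
    amplitude_mean: float  # pA (positive magnitude)
    duration: float  # s
    seed: int
    amplitude_cv: float = 0.3  # lognormal CV
    rise_tau: float = 0.5  # ms
    decay_tau: float = 5.0  # ms
    noise_rms: float = 2.0  # pA
    holding: float = -60.0  # mV, metadata only

    def __post_init__(self) -> None:
        if self.mean_interval <= 0 or self.amplitude_mean <= 0 or self.duration <= 0:
            raise SpecificationError("interval, amplitude and duration must be positive")
        if self.decay_tau <= self.rise_tau:
            raise SpecificationError("decay_tau must exceed rise_tau")


def biexp_kernel(rise_tau: float, decay_tau: float, fs: float, length_ms: float = 60.0) -> np.ndarray:
    """Peak-normalised biexponential kernel sampled at fs (unit peak)."""
    t = np.arange(int(round(length_ms / 1000.0 * fs))) * 1000.0 / fs
    g = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    g_max = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return g / g_max


def make_mepsc_trace(spec: MepscGenSpec, fs: float = VC_FS) -> tuple[Trace, pd.DataFrame]:
    """Generate one voltage-clamp current trace plus its ground-truth events.

    Returns the ``current_vc`` trace (pA) and a DataFrame with columns
    ``time`` (s, event onset) and ``amplitude`` (pA, positive magnitude).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * fs))
    if n < 2:
        raise SpecificationError("duration too short at this sampling rate")
    # Poisson event times: exponential inter-event intervals
    times = []
    t = rng.exponential(spec.mean_interval)
    while t < spec.duration:
        times.append(t)
        t += rng.exponential(spec.mean_interval)
    times = np.asarray(times)
    # lognormal amplitudes with the requested mean and CV
    cv = max(spec.amplitude_cv, 0.0)
    if cv > 0:
        sig2 = np.log(1.0 + cv * cv)
        amps = rng.lognormal(np.log(spec.amplitude_mean) - 0.5 * sig2, np.sqrt(sig2), times.size)
    else:
        amps = np.full(times.size, spec.amplitude_mean)
    samples = rng.standard_normal(n) * spec.noise_rms if spec.noise_rms > 0 else np.zeros(n)
    kernel = biexp_kernel(spec.rise_tau, spec.decay_tau, fs,
                          length_ms=max(60.0, 10.0 * spec.decay_tau))
    for t_ev, a in zip(times, amps):
        i0 = int(round(t_ev * fs))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            samples[i0 : i0 + seg] -= a * kernel[:seg]
    trace = Trace(samples, fs=fs, kind="current_vc", meta={
        "holding_mV": spec.holding, "seed": spec.seed,
        "mean_interval_s": spec.mean_interval,
        "rise_tau_ms": spec.rise_tau, "decay_tau_ms": spec.decay_tau,
        "noise_rms_pA": spec.noise_rms,
    })
    truth = pd.DataFrame({"time": times, "amplitude": amps})
    return trace, truth
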