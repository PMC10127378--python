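"""Synthetic carbachol-induced theta oscillation recordings.

A field trace with a quiet baseline epoch; from the carbachol marker plus
an onset latency, a theta-band (4-7 Hz) sinusoid grows with an exponential
envelope on top of 1/f-coloured background noise.  Phenomenological only:
no network model stands behind the oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import SpecificationError, Trace

OSC_FS = 10_000.0  # Hz


@dataclass(frozen=True)
class OscGenSpec:
    baseline_duration: float  # s before carbachol
    post_carbachol_duration: float  # s after carbachol
    onset_latency: float  # s from carbachol to oscillation onset
    theta_amp: float  # mV
    seed: int
    theta_freq: float = 5.0  # Hz, within the 4-7 Hz theta band
    envelope_tau: float = 15.0  # s
    noise_rms: float = 0.02  # mV
    noise_color: str = "pink"  # "pink" or "white"
    fs: float = OSC_FS

    def __post_init__(self) -> None:
        if not 4.0 <= self.theta_freq <= 7.0:
            raise SpecificationError("theta frequency must lie in the 4-7 Hz band")
        if self.onset_latency >= self.post_carbachol_duration:
            raise SpecificationError("onset latency must fall inside the post-carbachol epoch")
        if self.baseline_duration <= 0 or self.post_carbachol_duration <= 0:
            raise SpecificationError("epoch durations must be positive")


def _colored_noise(n: int, rms: float, color: str, rng: np.random.Generator) -> np.ndarray:
    if rms <= 0:
        return np.zeros(n)
    w = rng.standard_normal(n)
    if color == "white":
        return w * rms
    if color != "pink":
        raise SpecificationError(f"unknown noise colour {color!r}")
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / np.std(x))


def make_oscillation_trace(spec: OscGenSpec) -> Trace:
    """Generate the field trace; carbachol time is in ``meta['carbachol_time_s']``."""
    n = int(round((spec.baseline_duration + spec.post_carbachol_duration) * spec.fs))
    rng = np.random.default_rng(spec.seed)
    samples = _colored_noise(n, spec.noise_rms, spec.noise_color, rng)
    t = np.arange(n) / spec.fs
    onset = spec.baseline_duration + spec.onset_latency
    rel = t - onset
    env = np.where(rel > 0, 1.0 - np.exp(-np.clip(rel, 0, None) / spec.envelope_tau), 0.0)
    phase = rng.uniform(0, 2 * np.pi)
    samples = samples + spec.theta_amp * env * np.sin(2 * np.pi * spec.theta_freq * t + phase)
    return Trace(samples, fs=spec.fs, kind="field", meta={
        "carbachol_time_s": spec.baseline_duration,
        "carbachol_uM": 50.0,
        "seed": spec.seed,
        "theta_freq_hz": spec.theta_freq,
        "onset_latency_s": spec.onset_latency,
    })
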