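"""Naturalistic current waveforms: summed Ornstein-Uhlenbeck processes.

The fluctuating drive mimicking synaptic bombardment is the sum of two OU
processes with fast (3 ms) and slow (10 ms) correlation times, mimicking
AMPA- and GABA-receptor channel kinetics.  Each component follows

    dx = -x/tau dt + sigma * sqrt(2/tau) dW

and is discretised with the exact stationary update

    x[k+1] = x[k] * a + sigma * sqrt(1 - a^2) * z,   a = exp(-dt/tau)

so the sampled process has exactly the stationary variance sigma^2 and
autocorrelation exp(-|lag|/tau) at any step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from ..core import SpecificationError, Trace


@dataclass(frozen=True)
class OUStimulusSpec:
    """Summed two-component OU current stimulus.

    ``mean`` is a constant bias in pA (not scaled by ``gain``); ``gain``
    multiplies both fluctuating components, matching the experimental
    convention of injecting a waveform "of the same gain" into every cell.
    """

    sigma_fast: float  # pA, stationary SD of the fast component (at gain 1)
    sigma_slow: float  # pA
    duration: float  # s
    seed: int
    tau_fast: float = 3.0  # ms
    tau_slow: float = 10.0  # ms
    mean: float = 0.0  # pA
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise SpecificationError("OU time constants must be positive")
        if self.duration <= 0:
            raise SpecificationError("OU duration must be positive")
        if self.sigma_fast < 0 or self.sigma_slow < 0:
            raise SpecificationError("OU sigmas must be non-negative")


def _ou_path(n: int, dt_ms: float, tau_ms: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Exact-discretisation OU path of length n, stationary initial state."""
    a = np.exp(-dt_ms / tau_ms)
    if sigma == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n) * (sigma * np.sqrt(1.0 - a * a))
    x0 = rng.standard_normal() * sigma
    # x[k] = a x[k-1] + w[k]; seed the recursion with the stationary draw
    x, _ = lfilter([1.0], [1.0, -a], w, zi=[a * x0])
    return x


def make_ou_current(spec: OUStimulusSpec, fs: float) -> Trace:
    """Generate the summed-OU current trace at sampling rate ``fs`` (Hz).

    Returns a ``current_stim`` trace equal to
    ``mean + gain * (x_fast + x_slow)``; identical spec and seed give a
    bit-identical trace.
    """
    if fs < 1000:
        raise SpecificationError("naturalistic stimulus needs fs >= 1 kHz")
    n = int(round(spec.duration * fs))
    if n < 2:
        raise SpecificationError("duration too short for this sampling rate")
    dt_ms = 1000.0 / fs
    rng = np.random.default_rng(spec.seed)
    x = _ou_path(n, dt_ms, spec.tau_fast, spec.sigma_fast, rng)
    x = x + _ou_path(n, dt_ms, spec.tau_slow, spec.sigma_slow, rng)
    samples = spec.mean + spec.gain * x
    return Trace(
        samples,
        fs=fs,
        kind="current_stim",
        meta={
            "protocol": "ou",
            "tau_fast_ms": spec.tau_fast,
            "tau_slow_ms": spec.tau_slow,
            "sigma_fast_pA": spec.sigma_fast,
            "sigma_slow_pA": spec.sigma_slow,
            "mean_pA": spec.mean,
            "gain": spec.gain,
            "seed": spec.seed,
        },
    )
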