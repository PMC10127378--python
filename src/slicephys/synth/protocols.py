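"""Current-clamp stimulation protocols: step families, rheobase ramp, OU.

All stimuli are emitted at 20 kHz by default, the digitisation rate of the
whole-cell recordings, and integration runs at the stimulus rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import SpecificationError, Trace
from .eif import EIFGroundTruth, simulate_eif
from .ou import OUStimulusSpec, make_ou_current

CC_FS = 20_000.0  # Hz


@dataclass(frozen=True)
class StepProtocolSpec:
    """Standard current-voltage step family, -200 pA upward."""

    start: float = -200.0  # pA
    increment: float = 50.0  # pA (50 or 100 in practice)
    step_duration: float = 1.0  # s
    n_steps: int = 7
    baseline: float = 0.25  # s of zero current before and after the step

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise SpecificationError("step duration must be positive")
        if self.n_steps < 2:
            raise SpecificationError("need at least 2 steps")


@dataclass(frozen=True)
class RampProtocolSpec:
    """Rheobase ramp: pre-ramp to -100 pA then 0.33 pA/ms up to 200 pA."""

    pre_ramp_target: float = -100.0  # pA
    pre_ramp_duration: float = 100.0  # ms
    ramp_rate: float = 0.33  # pA/ms
    ramp_cap: float = 200.0  # pA
    baseline: float = 0.2  # s of zero current flanking the ramp

    def __post_init__(self) -> None:
        if self.ramp_rate <= 0:
            raise SpecificationError("ramp rate must be positive")
        if self.ramp_cap <= self.pre_ramp_target:
            raise SpecificationError("ramp cap must exceed the pre-ramp target")


def make_step_stimulus(spec: StepProtocolSpec, amplitude: float, fs: float = CC_FS) -> Trace:
    """Single step sweep: baseline, ``amplitude`` pA for step_duration, baseline."""
    n_base = int(round(spec.baseline * fs))
    n_step = int(round(spec.step_duration * fs))
    samples = np.zeros(2 * n_base + n_step)
    samples[n_base : n_base + n_step] = amplitude
    return Trace(samples, fs=fs, kind="current_stim", meta={
        "protocol": "step", "amplitude_pA": amplitude,
        "step_window_s": (spec.baseline, spec.baseline + spec.step_duration),
    })


def make_ramp_stimulus(spec: RampProtocolSpec, fs: float = CC_FS) -> Trace:
    """Rheobase ramp sweep, then a step back to zero current."""
    n_base = int(round(spec.baseline * fs))
    n_pre = int(round(spec.pre_ramp_duration / 1000.0 * fs))
    ramp_ms = (spec.ramp_cap - spec.pre_ramp_target) / spec.ramp_rate
    n_ramp = int(round(ramp_ms / 1000.0 * fs))
    pre = np.linspace(0.0, spec.pre_ramp_target, n_pre, endpoint=False)
    t_ms = np.arange(n_ramp) * 1000.0 / fs
    ramp = spec.pre_ramp_target + spec.ramp_rate * t_ms
    samples = np.concatenate([
        np.zeros(n_base), pre, ramp, np.zeros(n_base),
    ])
    ramp_start = (n_base + n_pre) / fs
    return Trace(samples, fs=fs, kind="current_stim", meta={
        "protocol": "ramp", "ramp_rate_pA_per_ms": spec.ramp_rate,
        "ramp_window_s": (ramp_start, ramp_start + n_ramp / fs),
    })


def make_protocol_sweeps(
    gt: EIFGroundTruth,
    proto: StepProtocolSpec | RampProtocolSpec | OUStimulusSpec,
    seed: int = 0,
    fs: float = CC_FS,
) -> list[tuple[Trace, Trace]]:
    """Simulate one cell under a protocol; list of (stimulus, voltage) sweeps.

    Steps give one sweep per amplitude, the ramp and OU protocols one sweep.
    The same seed yields bit-identical sweeps.
    """
    sweeps: list[tuple[Trace, Trace]] = []
    if isinstance(proto, StepProtocolSpec):
        for i in range(proto.n_steps):
            amp = proto.start + i * proto.increment
            stim = make_step_stimulus(proto, amp, fs)
            volt, _ = simulate_eif(gt, stim, seed=seed * 1009 + i)
            sweeps.append((stim, volt))
    elif isinstance(proto, RampProtocolSpec):
        stim = make_ramp_stimulus(proto, fs)
        volt, _ = simulate_eif(gt, stim, seed=seed)
        sweeps.append((stim, volt))
    elif isinstance(proto, OUStimulusSpec):
        stim = make_ou_current(proto, fs)
        volt, _ = simulate_eif(gt, stim, seed=seed + 1)
        sweeps.append((stim, volt))
    else:
        raise SpecificationError(f"unknown protocol {type(proto).__name__}")
    return sweeps
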