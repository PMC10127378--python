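"""Core data carrier and error types.

Unit conventions, fixed package-wide: voltage in mV, current in pA,
capacitance in pF, resistance in MOhm, time constants in ms, absolute time
and sampling in s / Hz.  With these units the identities

    Rin [MOhm] = 1000 * tau_m [ms] / C [pF]
    dV [mV]    = I [pA] * R [MOhm] / 1000

hold exactly and are asserted where used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TRACE_KINDS = ("voltage_cc", "current_stim", "current_vc", "field")


class SlicephysError(Exception):
    """Base class for package errors."""


class SpecificationError(SlicephysError, ValueError):
    """A generator or protocol specification is invalid."""


class InsufficientDataError(SlicephysError, ValueError):
    """Not enough usable data for the requested measurement."""


class AlignmentError(SlicephysError, ValueError):
    """Paired traces do not share a time base."""


class SimulationError(SlicephysError, RuntimeError):
    """Numerical integration diverged."""


class FitError(SlicephysError, RuntimeError):
    """Nonlinear fit failed to converge; carries diagnostics."""


@dataclass
class Trace:
    """A uniformly sampled recording channel.

    Parameters
    ----------
    samples : ndarray
        Signal values (mV for voltage/field kinds, pA for current kinds).
    fs : float
        Sampling rate in Hz.
    kind : str
        One of ``voltage_cc``, ``current_stim``, ``current_vc``, ``field``.
    t0 : float
        Time of the first sample in seconds.
    meta : dict
        Free-form metadata (protocol spec, seed, condition label, markers).
    """

    samples: np.ndarray
    fs: float
    kind: str
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise SpecificationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise SpecificationError("trace needs at least 2 samples in one channel")
        if not np.all(np.isfinite(self.samples)):
            raise SpecificationError("trace contains non-finite samples")
        if self.kind not in TRACE_KINDS:
            raise SpecificationError(f"unknown trace kind {self.kind!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (s), bounds-checked."""
        i = int(round((t - self.t0) * self.fs))
        if i < 0 or i >= self.n:
            raise InsufficientDataError(f"time {t} s outside trace [{self.t0}, {self.t0 + self.duration}] s")
        return i

    def slice_time(self, start: float, end: float) -> np.ndarray:
        """Samples in the half-open time window [start, end) seconds."""
        i0 = self.index_of(start)
        i1 = int(round((end - self.t0) * self.fs))
        if i1 <= i0 or i1 > self.n:
            raise InsufficientDataError(f"window [{start}, {end}] s outside trace")
        return self.samples[i0:i1]


def check_aligned(a: Trace, b: Trace) -> None:
    """Raise AlignmentError unless two traces share fs, t0 and length."""
    if a.fs != b.fs or a.n != b.n or abs(a.t0 - b.t0) * a.fs > 0.5:
        raise AlignmentError(
            f"traces misaligned: fs {a.fs}/{b.fs}, n {a.n}/{b.n}, t0 {a.t0}/{b.t0}"
        )


def derive_seed(master: int, *stream: int) -> np.random.Generator:
    """Deterministic child generator from a master seed and stream ids."""
    return np.random.default_rng(np.random.SeedSequence([int(master) & 0x7FFFFFFF, *map(int, stream)]))
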