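"""Synthetic extracellular field-potential sweeps.

Each evoked sweep contains a brief biphasic stimulus artefact, a fast
negative fibre-volley deflection, and a negative-going fEPSP whose initial
segment is linear with a programmed slope (mV/ms) before an exponential
return to baseline.  Input-output families, paired-pulse pairs (second
response scaled by the programmed ratio) and 80-min LTP time courses
(20-min baseline, high-frequency stimulation marker, saturating rise to a
plateau) are assembled from these sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import SpecificationError, Trace
from .presets import ConditionPreset

FIELD_FS = 10_000.0  # Hz, field digitisation rate
STIM_RATE_HZ = 1.0 / 30.0  # evoked every 30 s
FV_DELAY_MS = 1.5  # stimulus artefact to fibre-volley trough
FEPSP_ONSET_MS = 1.9  # stimulus artefact to fEPSP onset
FEPSP_LINEAR_MS = 2.5  # duration of the linear rising phase
FEPSP_DECAY_MS = 8.0


@dataclass(frozen=True)
class FieldGenSpec:
    """One slice's field-potential generation parameters."""

    io_curve: dict  # stimulus V -> (fEPSP slope mV/ms, fibre volley mV)
    ppf: dict  # interval ms -> paired-pulse ratio
    base_slope: float  # mV/ms for PPF/LTP sweeps (the ~40%-of-max level)
    base_fv: float  # mV
    ltp_plateau: float  # normalised plateau (>= 1)
    seed: int
    ltp_baseline_min: float = 20.0
    ltp_followup_min: float = 60.0
    ltp_onset_tau_min: float = 8.0
    ltp_transient: float = 0.6  # post-tetanic transient amplitude (normalised)
    ltp_transient_tau_min: float = 1.5
    noise_rms: float = 0.01  # mV additive trace noise
    sweep_jitter: float = 0.04  # multiplicative SD of per-sweep response size
    stim_rate: float = STIM_RATE_HZ

    def __post_init__(self) -> None:
        if any(s < 0 for s, _ in self.io_curve.values()):
            raise SpecificationError("fEPSP slopes must be non-negative")
        if any(r <= 0 for r in self.ppf.values()):
            raise SpecificationError("paired-pulse ratios must be positive")
        if self.ltp_plateau < 1.0:
            raise SpecificationError("LTP plateau must be >= 1 (normalised)")


def _add_response(samples: np.ndarray, fs: float, t_stim: float,
                  slope: float, fv_amp: float) -> None:
    """Add artefact + fibre volley + fEPSP starting at ``t_stim`` (s)."""
    dt_ms = 1000.0 / fs
    i0 = int(round(t_stim * fs))
    n = samples.size
    # biphasic stimulus artefact, 0.3 ms total
    n_half = max(1, int(round(0.15 / dt_ms)))
    samples[i0 : min(i0 + n_half, n)] += 0.5
    samples[min(i0 + n_half, n) : min(i0 + 2 * n_half, n)] -= 0.5
    t_ms = (np.arange(n - i0)) * dt_ms  # ms since artefact
    # fibre volley: narrow gaussian trough
    samples[i0:] -= fv_amp * np.exp(-0.5 * ((t_ms - FV_DELAY_MS) / 0.12) ** 2)
    # fEPSP: linear descent then exponential recovery
    rel = t_ms - FEPSP_ONSET_MS
    wave = np.zeros_like(rel)
    lin = (rel >= 0) & (rel < FEPSP_LINEAR_MS)
    wave[lin] = -slope * rel[lin]
    tail = rel >= FEPSP_LINEAR_MS
    depth = -slope * FEPSP_LINEAR_MS
    wave[tail] = depth * np.exp(-(rel[tail] - FEPSP_LINEAR_MS) / FEPSP_DECAY_MS)
    samples[i0:] += wave


def make_field_sweep(slope: float, fv_amp: float, *, fs: float = FIELD_FS,
                     t_stim: float = 0.05, duration: float = 0.12,
                     noise_rms: float = 0.0,
                     rng: np.random.Generator | None = None,
                     extra_stims: list[tuple[float, float, float]] = ()) -> Trace:
    """One evoked field sweep; ``extra_stims`` is [(t_stim, slope, fv), ...]."""
    n = int(round(duration * fs))
    samples = np.zeros(n)
    if noise_rms > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        samples += rng.standard_normal(n) * noise_rms
    _add_response(samples, fs, t_stim, slope, fv_amp)
    stim_times = [t_stim]
    for t2, s2, f2 in extra_stims:
        _add_response(samples, fs, t2, s2, f2)
        stim_times.append(t2)
    return Trace(samples, fs=fs, kind="field", meta={
        "stim_times_s": stim_times, "programmed_slope_mv_per_ms": slope,
        "programmed_fv_mv": fv_amp,
    })


@dataclass
class FieldSliceData:
    """All field recordings generated for one slice."""

    label: str
    spec: FieldGenSpec
    io_sweeps: list  # (stimulus V, Trace)
    ppf_pairs: dict  # interval ms -> Trace with two stimuli
    ppf_template: Trace  # single-pulse sweep at the PPF stimulus strength
    ltp_times_min: np.ndarray  # sweep times, minutes
    ltp_sweeps: list
    hfs_time_min: float
    manifest: dict = field(default_factory=dict)


def default_io_curve(slope_3v: float, fv_4v: float,
                     stims: tuple = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)) -> dict:
    """Saturating input-output mapping anchored at the 3 V slope value."""
    def f(v: float) -> float:
        return v ** 2.5 / (v ** 2.5 + 3.2 ** 2.5)
    return {v: (slope_3v * f(v) / f(3.0), fv_4v * v / 4.0) for v in stims}


def default_ppf_curve(ratio_100ms: float,
                      intervals: tuple = (20.0, 50.0, 100.0, 200.0, 300.0, 500.0)) -> dict:
    """Facilitation peaking near 100 ms, decaying toward 1 at long intervals."""
    def g(d: float) -> float:
        return (d / 100.0) * np.exp(1.0 - d / 100.0)
    return {d: 1.0 + (ratio_100ms - 1.0) * g(d) / g(100.0) for d in intervals}


def field_spec_from_preset(preset: ConditionPreset, rng: np.random.Generator,
                           seed: int) -> FieldGenSpec:
    """Draw one slice's field spec from a condition preset (slice variability)."""
    slope3 = max(rng.normal(preset.fepsp_slope_3v.mean, preset.fepsp_slope_3v.cell_sd), 0.02)
    fv4 = max(rng.normal(preset.fibre_volley_4v.mean, preset.fibre_volley_4v.cell_sd), 0.02)
    ppf100 = max(rng.normal(preset.ppf_100ms.mean, preset.ppf_100ms.cell_sd), 0.2)
    plateau = max(rng.normal(preset.ltp_55_60.mean, preset.ltp_55_60.cell_sd), 1.0)
    return FieldGenSpec(
        io_curve=default_io_curve(slope3, fv4),
        ppf=default_ppf_curve(ppf100),
        base_slope=0.4 * slope3 / 0.52,  # ~40% of the saturated maximum
        base_fv=fv4 * 0.6,
        ltp_plateau=plateau,
        seed=seed,
    )


def ltp_profile(t_min: np.ndarray, hfs_min: float, spec: FieldGenSpec) -> np.ndarray:
    """Normalised slope time course: 1 at baseline, saturating rise after HFS."""
    out = np.ones_like(t_min, dtype=float)
    post = t_min > hfs_min
    dt = t_min[post] - hfs_min
    out[post] = (1.0
                 + (spec.ltp_plateau - 1.0) * (1.0 - np.exp(-dt / spec.ltp_onset_tau_min))
                 + spec.ltp_transient * np.exp(-dt / spec.ltp_transient_tau_min))
    return out


def make_field_dataset(spec: FieldGenSpec, label: str = "") -> FieldSliceData:
    """Generate the IO family, PPF pairs and the LTP time course for one slice."""
    rng = np.random.default_rng(spec.seed)

    io_sweeps = []
    for v, (s, fv) in sorted(spec.io_curve.items()):
        jit = 1.0 + rng.standard_normal() * spec.sweep_jitter
        io_sweeps.append((v, make_field_sweep(s * jit, fv * jit, noise_rms=spec.noise_rms, rng=rng)))

    ppf_template = make_field_sweep(spec.base_slope, spec.base_fv,
                                    noise_rms=spec.noise_rms, rng=rng, duration=0.3)
    ppf_pairs = {}
    for interval, ratio in sorted(spec.ppf.items()):
        jit = 1.0 + rng.standard_normal() * spec.sweep_jitter
        s1 = spec.base_slope * jit
        t2 = 0.05 + interval / 1000.0
        sweep = make_field_sweep(
            s1, spec.base_fv * jit, noise_rms=spec.noise_rms, rng=rng,
            duration=t2 + 0.15,
            extra_stims=[(t2, s1 * ratio, spec.base_fv * jit)],
        )
        sweep.meta["interval_ms"] = interval
        ppf_pairs[interval] = sweep

    total_min = spec.ltp_baseline_min + spec.ltp_followup_min
    times = np.arange(0.0, total_min, 1.0 / (spec.stim_rate * 60.0))
    hfs_min = spec.ltp_baseline_min
    profile = ltp_profile(times, hfs_min, spec)
    ltp_sweeps = []
    for t, norm in zip(times, profile):
        jit = 1.0 + rng.standard_normal() * spec.sweep_jitter
        sw = make_field_sweep(spec.base_slope * norm * jit, spec.base_fv,
                              noise_rms=spec.noise_rms, rng=rng)
        sw.meta["time_min"] = float(t)
        ltp_sweeps.append(sw)

    return FieldSliceData(
        label=label, spec=spec, io_sweeps=io_sweeps, ppf_pairs=ppf_pairs,
        ppf_template=ppf_template, ltp_times_min=times, ltp_sweeps=ltp_sweeps,
        hfs_time_min=hfs_min,
        manifest={"seed": spec.seed, "hfs": "100 stimuli at 100 Hz",
                  "stim_rate_Hz": spec.stim_rate},
    )
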