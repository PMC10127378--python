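"""Condition-level dataset assembly.

Derives per-cell ground truths from a condition preset, calibrates the
shared naturalistic-drive gain on the control condition, and generates
whichever recording modalities are requested.  Every stream of randomness
is a deterministic function of the master seed, so a dataset regenerates
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import SpecificationError, Trace, derive_seed
from .eif import EIFGroundTruth, RefractorySpec, simulate_eif
from .field import FieldSliceData, field_spec_from_preset, make_field_dataset
from .mepsc import MepscGenSpec, make_mepsc_trace
from .oscillation import OscGenSpec, make_oscillation_trace
from .ou import OUStimulusSpec, make_ou_current
from .presets import (
    DEFAULT_C_PF,
    DEFAULT_DELTAT_MV,
    INTRINSIC_NOISE_SIGMA,
    OU_BASE_SIGMA_FAST,
    OU_BASE_SIGMA_SLOW,
    OU_MEAN_PA,
    RAMP_RHEOBASE_CORRECTION_PA,
    ConditionPreset,
    get_preset,
)
from .protocols import CC_FS, RampProtocolSpec, StepProtocolSpec, make_protocol_sweeps

REFRACTORY_DEFAULT = RefractorySpec(threshold_jump=8.0, threshold_decay_tau=120.0,
                                    reset_offset=5.0, absolute_ref=2.0)
NATURALISTIC_DURATION_S = 40.0

# stream ids for deterministic child seeds
_STREAMS = {"cells": 1, "steps": 2, "ramp": 3, "ou": 4, "mepsc": 5,
            "field": 6, "osc": 7, "calibration": 8}


def naturalistic_spec(gain: float, seed: int,
                      duration: float = NATURALISTIC_DURATION_S) -> OUStimulusSpec:
    """The shared naturalistic drive: summed OU at the calibrated gain."""
    return OUStimulusSpec(sigma_fast=OU_BASE_SIGMA_FAST, sigma_slow=OU_BASE_SIGMA_SLOW,
                          mean=OU_MEAN_PA, gain=gain, duration=duration, seed=seed)


def ground_truth_from_targets(em: float, rin: float, rheobase: float,
                              C: float = DEFAULT_C_PF,
                              DeltaT: float = DEFAULT_DELTAT_MV,
                              noise_sigma: float = INTRINSIC_NOISE_SIGMA,
                              refractory: RefractorySpec = REFRACTORY_DEFAULT) -> EIFGroundTruth:
    """EIF parameters whose static rheobase equals the target:
    VT = Em + DeltaT + rheobase*Rin/1000."""
    vt = em + DeltaT + rheobase * rin / 1000.0
    return EIFGroundTruth(C=C, Em=em, Rin=rin, VT=vt, DeltaT=DeltaT,
                          refractory=refractory, noise_sigma=noise_sigma)


RHEOBASE_FLOOR_PA = 25.0  # lower draws would make tonically firing cells


def _truncated_location(target: float, sd: float, lo: float) -> float:
    """Location mu such that a normal(mu, sd) truncated below at ``lo`` has
    mean ``target`` (keeps the truncation from inflating the group mean)."""
    from scipy.stats import norm
    mu = target
    for _ in range(30):
        a = (lo - mu) / sd
        mean = mu + sd * norm.pdf(a) / max(norm.sf(a), 1e-12)
        mu -= 0.8 * (mean - target)
        if abs(mean - target) < 1e-6:
            break
    return mu


def draw_cells(preset: ConditionPreset, n_cells: int, seed: int) -> list[EIFGroundTruth]:
    """Per-cell ground truths with between-cell SD = printed SEM * sqrt(printed n)."""
    if n_cells < 1:
        raise SpecificationError("need at least one cell")
    rng = derive_seed(seed, _STREAMS["cells"])
    mu_rheo = _truncated_location(preset.rheobase.mean, preset.rheobase.cell_sd,
                                  RHEOBASE_FLOOR_PA)
    cells = []
    for _ in range(n_cells):
        em = rng.normal(preset.em.mean, preset.em.cell_sd)
        rin = max(rng.normal(preset.rin.mean, preset.rin.cell_sd), 40.0)
        rheo = RHEOBASE_FLOOR_PA - 1.0
        while rheo < RHEOBASE_FLOOR_PA:
            rheo = rng.normal(mu_rheo, preset.rheobase.cell_sd)
        # the preset rheobase is what the ramp assay should recover, so the
        # static saddle-node target is lowered by the known ramp overshoot
        cells.append(ground_truth_from_targets(
            em, rin, rheo - RAMP_RHEOBASE_CORRECTION_PA))
    return cells


def mean_firing_rate(cells: list[EIFGroundTruth], gain: float, seed: int,
                     duration: float = NATURALISTIC_DURATION_S,
                     fs: float = CC_FS, sweeps_per_cell: int = 1) -> float:
    """Mean spike rate of the cells under the shared drive at this gain."""
    rates = []
    for i, gt in enumerate(cells):
        for j in range(sweeps_per_cell):
            stim = make_ou_current(
                naturalistic_spec(gain, seed * 131 + 7 * i + j, duration), fs)
            _, spikes = simulate_eif(gt, stim, seed=seed * 977 + 5 * i + j)
            rates.append(spikes.size / duration)
    return float(np.mean(rates))


def calibrate_ou_gain(control_preset: ConditionPreset | None = None, seed: int = 0,
                      n_sweeps: int = 6, tol_hz: float = 0.05,
                      lo: float = 5.0, hi: float = 400.0) -> float:
    """Bisect the OU gain until the control-mean neuron hits its rate target.

    The gain is a fixed experimental input -- the same waveform gain is
    used for every recording and every condition -- so it is calibrated on
    the control preset's mean-parameter neuron (averaging ``n_sweeps``
    independent 40-s sweeps), not on a random cell draw whose sampling
    luck would otherwise leak into every downstream rate measurement.
    """
    preset = control_preset or get_preset("control")
    cal_seed = int(derive_seed(seed, _STREAMS["calibration"]).integers(2**31))
    cell = ground_truth_from_targets(
        preset.em.mean, preset.rin.mean,
        preset.rheobase.mean - RAMP_RHEOBASE_CORRECTION_PA)
    target = preset.firing_rate.mean
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        r = mean_firing_rate([cell], mid, cal_seed, sweeps_per_cell=n_sweeps)
        if abs(r - target) < tol_hz:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    return mid


@dataclass
class CellRecording:
    """One simulated cell: ground truth plus its protocol sweeps."""

    ground_truth: EIFGroundTruth
    step_sweeps: list = field(default_factory=list)  # (stim, voltage)
    ramp_sweep: tuple | None = None
    ou_sweeps: list = field(default_factory=list)  # fit + held-out sweep


@dataclass
class ConditionDataset:
    """All simulated recordings for one condition."""

    label: str
    preset: ConditionPreset
    seed: int
    ou_gain: float
    cells: list = field(default_factory=list)  # CellRecording
    mepsc_slices: list = field(default_factory=list)  # (Trace, truth DataFrame)
    field_slices: list = field(default_factory=list)  # FieldSliceData
    osc_slices: list = field(default_factory=list)  # Trace
    manifest: dict = field(default_factory=dict)


def make_condition_dataset(
    preset: ConditionPreset | str,
    seed: int,
    n_cells: int = 0,
    n_mepsc_slices: int = 0,
    n_field_slices: int = 0,
    n_osc_slices: int = 0,
    ou_gain: float | None = None,
    mepsc_duration: float = 1200.0,
    osc_baseline: float = 120.0,
    osc_post: float = 400.0,
    n_ou_sweeps: int = 2,
) -> ConditionDataset:
    """Generate a labelled dataset for one condition.

    Modalities with n = 0 are skipped.  If ``ou_gain`` is not given it is
    calibrated on the control preset with the same master seed (pass the
    cached value to reuse one calibration across conditions).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if n_cells and ou_gain is None:
        ou_gain = calibrate_ou_gain(seed=seed)
    ds = ConditionDataset(label=preset.label, preset=preset, seed=seed,
                          ou_gain=float(ou_gain or 0.0))
    if n_cells:
        cells = draw_cells(preset, n_cells, seed)
        step_spec, ramp_spec = StepProtocolSpec(), RampProtocolSpec()
        for i, gt in enumerate(cells):
            rec = CellRecording(ground_truth=gt)
            rec.step_sweeps = make_protocol_sweeps(gt, step_spec, seed=seed * 7919 + i)
            rec.ramp_sweep = make_protocol_sweeps(gt, ramp_spec, seed=seed * 6007 + i)[0]
            for j in range(n_ou_sweeps):
                spec = naturalistic_spec(ds.ou_gain, seed * 4001 + 97 * i + j)
                rec.ou_sweeps.append(
                    make_protocol_sweeps(gt, spec, seed=seed * 3001 + 89 * i + j)[0])
            ds.cells.append(rec)
    if n_mepsc_slices:
        rng = derive_seed(seed, _STREAMS["mepsc"])
        for i in range(n_mepsc_slices):
            interval = max(rng.normal(preset.mepsc_interval.mean,
                                      preset.mepsc_interval.cell_sd), 0.05)
            amp = max(rng.normal(preset.mepsc_amplitude.mean,
                                 preset.mepsc_amplitude.cell_sd), 7.0)
            spec = MepscGenSpec(mean_interval=interval, amplitude_mean=amp,
                                duration=mepsc_duration,
                                seed=int(rng.integers(2**31)))
            ds.mepsc_slices.append(make_mepsc_trace(spec))
    if n_field_slices:
        rng = derive_seed(seed, _STREAMS["field"])
        for i in range(n_field_slices):
            fspec = field_spec_from_preset(preset, rng, seed=int(rng.integers(2**31)))
            ds.field_slices.append(make_field_dataset(fspec, label=preset.label))
    if n_osc_slices:
        rng = derive_seed(seed, _STREAMS["osc"])
        base_amp = 0.06  # mV control peak theta amplitude
        for i in range(n_osc_slices):
            amp = base_amp * np.sqrt(preset.theta_power_scale) * max(rng.normal(1.0, 0.15), 0.3)
            latency = max(rng.normal(preset.theta_onset_latency, 0.15 * preset.theta_onset_latency), 10.0)
            latency = min(latency, osc_post - 60.0)
            spec = OscGenSpec(baseline_duration=osc_baseline,
                              post_carbachol_duration=osc_post,
                              onset_latency=latency, theta_amp=amp,
                              seed=int(rng.integers(2**31)))
            ds.osc_slices.append(make_oscillation_trace(spec))
    ds.manifest = {
        "label": preset.label, "seed": seed, "ou_gain": ds.ou_gain,
        "n_cells": n_cells, "n_mepsc_slices": n_mepsc_slices,
        "n_field_slices": n_field_slices, "n_osc_slices": n_osc_slices,
        "mepsc_duration_s": mepsc_duration,
        "intrinsic_noise_sigma": INTRINSIC_NOISE_SIGMA,
        "refractory": {"threshold_jump_mV": REFRACTORY_DEFAULT.threshold_jump,
                       "threshold_decay_tau_ms": REFRACTORY_DEFAULT.threshold_decay_tau,
                       "reset_offset_mV": REFRACTORY_DEFAULT.reset_offset,
                       "absolute_ref_ms": REFRACTORY_DEFAULT.absolute_ref},
    }
    return ds
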