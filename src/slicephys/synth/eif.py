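"""Refractory exponential integrate-and-fire (rEIF) neuron simulation.

Membrane equation (units: mV, pA, pF, ms; see core module docstring)

    C dV/dt = (C/tau_m)(Em - V) + (C DeltaT/tau_m) exp((V - VT_eff)/DeltaT)
              + I(t) + xi(t)

integrated with fixed-step Euler-Maruyama at the stimulus sampling rate.
A numerical spike is emitted when V reaches the spike-cut voltage
VT + 5*DeltaT; V is then reset and the effective threshold VT_eff is
elevated by a jump that decays exponentially (the refractory part of the
rEIF model), with an absolute refractory clamp at the reset potential.

Because the numerical spike cut truncates the action potential far below
its biological peak, the emitted voltage trace has a stereotyped spike
waveform pasted over the absolute refractory window at each spike, so that
downstream threshold detectors and AP-shape measurements see realistic
action potentials.  The pasted waveform does not feed back into the
dynamics (the state is clamped at reset during that window anyway).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from ..core import SimulationError, SpecificationError, Trace

SPIKE_CUT_DELTAT_MULTIPLE = 5.0  # numerical spike cut at VT + 5*DeltaT
AP_PEAK_MV = 35.0  # stereotyped pasted action-potential peak
AP_RISE_MS = 0.3


@dataclass(frozen=True)
class RefractorySpec:
    """Post-spike dynamics of the rEIF model."""

    threshold_jump: float = 8.0  # mV added to VT at each spike
    threshold_decay_tau: float = 30.0  # ms
    reset_offset: float = 5.0  # reset to Em + reset_offset (mV)
    absolute_ref: float = 2.0  # ms clamped at reset


@dataclass(frozen=True)
class EIFGroundTruth:
    """Generative single-neuron parameter set.

    ``tau_m`` is derived from Rin and C (tau_m = Rin*C/1000) and the
    identity is validated on construction.
    """

    C: float  # pF
    Em: float  # mV
    Rin: float  # MOhm
    VT: float  # mV
    DeltaT: float = 1.5  # mV
    refractory: RefractorySpec = field(default_factory=RefractorySpec)
    noise_sigma: float = 0.0  # pA sqrt(ms); intrinsic white current noise

    def __post_init__(self) -> None:
        if self.C <= 0 or self.Rin <= 0 or self.DeltaT <= 0:
            raise SpecificationError("C, Rin and DeltaT must be positive")
        if self.VT <= self.Em:
            raise SpecificationError("spike threshold must exceed rest")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms (= Rin*C/1000)."""
        return self.Rin * self.C / 1000.0

    @property
    def static_rheobase(self) -> float:
        """Saddle-node rheobase of the EIF: (VT - Em - DeltaT)*1000/Rin, pA."""
        return (self.VT - self.Em - self.DeltaT) * 1000.0 / self.Rin

    @property
    def spike_cut(self) -> float:
        return self.VT + SPIKE_CUT_DELTAT_MULTIPLE * self.DeltaT

    @property
    def reset_V(self) -> float:
        return self.Em + self.refractory.reset_offset

    def with_noise(self, noise_sigma: float) -> "EIFGroundTruth":
        return replace(self, noise_sigma=noise_sigma)


@njit(cache=True)
def _eif_loop(I, dt, C, tau_m, Em, DeltaT, VT, v_cut, v_reset,
              jump, jump_tau, n_ref, noise, v0):  # pragma: no cover - numba
    n = I.size
    V = np.empty(n)
    V[0] = v0
    v = v0
    theta_extra = 0.0
    decay = math.exp(-dt / jump_tau)
    refr = 0
    spikes = np.empty(n, dtype=np.int64)
    n_sp = 0
    inv_tm = dt / tau_m
    for k in range(n - 1):
        theta_extra *= decay
        if refr > 0:
            refr -= 1
            v = v_reset
        else:
            ex = (v - (VT + theta_extra)) / DeltaT
            if ex > 40.0:
                ex = 40.0
            v = (v + inv_tm * (Em - v) + inv_tm * DeltaT * math.exp(ex)
                 + dt * I[k] / C + noise[k])
            if v >= v_cut:
                spikes[n_sp] = k + 1
                n_sp += 1
                v = v_reset
                theta_extra += jump
                refr = n_ref
        V[k + 1] = v
    return V, spikes[:n_sp]


def _paste_ap(V: np.ndarray, spike_idx: np.ndarray, fs: float, v_reset: float) -> None:
    """Overwrite samples after each spike with a stereotyped AP waveform."""
    dt_ms = 1000.0 / fs
    n_rise = max(1, int(round(AP_RISE_MS / dt_ms)))
    n_fall = max(2, int(round(1.2 / dt_ms)))
    for s in spike_idx:
        v_on = V[s - 1] if s > 0 else v_reset
        up = v_on + (AP_PEAK_MV - v_on) * np.sin(
            0.5 * np.pi * np.arange(1, n_rise + 1) / n_rise
        )
        down = v_reset + (AP_PEAK_MV - v_reset) * np.exp(
            -np.arange(1, n_fall + 1) * dt_ms / 0.4
        )
        wave = np.concatenate([up, down])
        end = min(s + wave.size, V.size)
        V[s:end] = wave[: end - s]


def simulate_eif(
    gt: EIFGroundTruth,
    stimulus: Trace,
    seed: int | None = 0,
    v0: float | None = None,
    paste_aps: bool = True,
) -> tuple[Trace, np.ndarray]:
    """Integrate the rEIF model under a current stimulus.

    Returns the voltage trace (same fs as the stimulus) and spike times in
    seconds, taken at the sample where V crossed the numerical spike cut.
    ``seed`` drives the intrinsic current noise only; with
    ``gt.noise_sigma == 0`` the integration is deterministic.
    """
    if stimulus.kind != "current_stim":
        raise SpecificationError("stimulus trace must be of kind 'current_stim'")
    fs = stimulus.fs
    dt = 1000.0 / fs  # ms
    n = stimulus.n
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n) * (gt.noise_sigma / gt.C * np.sqrt(dt))
    else:
        noise = np.zeros(n)
    ref = gt.refractory
    V, spike_idx = _eif_loop(
        np.ascontiguousarray(stimulus.samples), dt, gt.C, gt.tau_m, gt.Em,
        gt.DeltaT, gt.VT, gt.spike_cut, gt.reset_V,
        ref.threshold_jump, max(ref.threshold_decay_tau, 1e-9),
        int(round(ref.absolute_ref / dt)), noise, gt.Em if v0 is None else v0,
    )
    if not np.all(np.isfinite(V)):
        bad = int(np.flatnonzero(~np.isfinite(V))[0])
        raise SimulationError(f"membrane potential diverged at step {bad}")
    if paste_aps and spike_idx.size:
        _paste_ap(V, spike_idx, fs, gt.reset_V)
    voltage = Trace(
        V, fs=fs, kind="voltage_cc", t0=stimulus.t0,
        meta={"seed": seed, "noise_sigma_pA": gt.noise_sigma, **{
            k: v for k, v in stimulus.meta.items() if k == "protocol"}},
    )
    return voltage, stimulus.t0 + spike_idx / fs
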