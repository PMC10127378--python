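"""Per-condition generator presets.

Each preset encodes the group-level summary values of one slice-incubation
condition (control aCSF, CSF-tau, CSF-tau immunodepleted for tau, and the
mock-depletion control) together with the printed SEM and group size behind
each value.  Between-cell/slice variability is reconstructed as Gaussian
with SD = SEM * sqrt(n), which reproduces the printed group SEM at the
printed n.

``dilution_scale`` linearly interpolates every effect field between the
control value (scale 0) and the condition's full-effect value (scale 1,
the 1:15 CSF dilution used throughout); it models the dilution series used
to pick the working concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from ..core import SpecificationError

CONDITION_LABELS = ("control", "csf_tau", "csf_tau_depleted", "csf_mock_depleted")

# Frozen naturalistic-drive constants (see docs/methods.md, "Drive calibration").
# Base component SDs are 1 pA so the calibrated gain is the component SD in pA.
OU_BASE_SIGMA_FAST = 1.0
OU_BASE_SIGMA_SLOW = 1.0
OU_MEAN_PA = 0.0
INTRINSIC_NOISE_SIGMA = 40.0  # pA sqrt(ms)
DEFAULT_C_PF = 100.0
DEFAULT_DELTAT_MV = 3.0
# The 0.33 pA/ms ramp assay reads ~19 pA above the EIF saddle-node rheobase
# (ramp lag plus dynamic escape delay, measured on preset-range cells); cell
# thresholds are derived from the preset rheobase minus this correction so
# the assay recovers the preset value.
RAMP_RHEOBASE_CORRECTION_PA = 19.0


@dataclass(frozen=True)
class GroupValue:
    """A printed group summary: mean, SEM and group size."""

    mean: float
    sem: float
    n: int

    @property
    def cell_sd(self) -> float:
        """Between-cell SD reconstructed as SEM * sqrt(n)."""
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class ConditionPreset:
    """Calibration targets for one experimental condition."""

    label: str
    em: GroupValue  # resting membrane potential, mV
    rin: GroupValue  # input resistance, MOhm
    rheobase: GroupValue  # pA
    firing_rate: GroupValue  # Hz, under the shared naturalistic drive
    mepsc_interval: GroupValue  # s
    mepsc_amplitude: GroupValue  # pA
    ppf_100ms: GroupValue  # paired-pulse ratio at 100 ms
    ltp_55_60: GroupValue  # normalised fEPSP slope 55-60 min post HFS
    fepsp_slope_3v: GroupValue  # mV/ms at 3 V stimulus
    fibre_volley_4v: GroupValue  # mV at 4 V stimulus
    theta_power_scale: float  # peak theta power relative to control
    theta_onset_latency: float  # s from carbachol to oscillation onset
    dilution_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in CONDITION_LABELS:
            raise SpecificationError(f"unknown condition label {self.label!r}")
        if not 0.0 <= self.dilution_scale <= 1.0:
            raise SpecificationError("dilution_scale must lie in [0, 1]")
        for f in ("rin", "rheobase", "firing_rate", "mepsc_interval",
                  "mepsc_amplitude", "ppf_100ms", "ltp_55_60", "fepsp_slope_3v",
                  "fibre_volley_4v"):
            if getattr(self, f).mean <= 0:
                raise SpecificationError(f"{f} must be positive")


_PRESETS: dict[str, ConditionPreset] = {}


def _register(p: ConditionPreset) -> ConditionPreset:
    _PRESETS[p.label] = p
    return p


CONTROL = _register(ConditionPreset(
    label="control",
    em=GroupValue(-68.0, 0.92, 10),
    rin=GroupValue(143.6, 5.2, 10),
    rheobase=GroupValue(87.0, 6.8, 10),
    firing_rate=GroupValue(2.3, 0.5, 10),
    mepsc_interval=GroupValue(17.6, 1.04, 6),
    mepsc_amplitude=GroupValue(18.9, 0.33, 6),
    ppf_100ms=GroupValue(1.94, 0.07, 10),
    ltp_55_60=GroupValue(1.51, 0.06, 8),
    fepsp_slope_3v=GroupValue(0.25, 0.04, 10),
    fibre_volley_4v=GroupValue(0.15, 0.02, 10),
    theta_power_scale=1.0,
    theta_onset_latency=180.0,
))

CSF_TAU = _register(ConditionPreset(
    label="csf_tau",
    em=GroupValue(-63.0, 0.79, 11),
    rin=GroupValue(167.0, 7.2, 11),
    rheobase=GroupValue(52.0, 6.6, 11),
    firing_rate=GroupValue(4.2, 0.6, 11),
    mepsc_interval=GroupValue(1.9, 0.09, 8),
    mepsc_amplitude=GroupValue(22.5, 0.39, 8),
    ppf_100ms=GroupValue(2.23, 0.10, 8),
    ltp_55_60=GroupValue(1.76, 0.09, 8),
    fepsp_slope_3v=GroupValue(0.46, 0.06, 8),
    fibre_volley_4v=GroupValue(0.29, 0.03, 8),
    theta_power_scale=3.0,
    theta_onset_latency=100.0,
))

# Depleted mEPSC interval/amplitude and theta values are not printed as numbers;
# they are set to reflect the reported pattern (frequency effect only partially
# reversed; amplitude and network effects prevented).
CSF_TAU_DEPLETED = _register(ConditionPreset(
    label="csf_tau_depleted",
    em=GroupValue(-69.0, 1.09, 10),
    rin=GroupValue(126.0, 9.9, 10),
    rheobase=GroupValue(74.0, 6.9, 10),
    firing_rate=GroupValue(2.1, 0.3, 10),
    mepsc_interval=GroupValue(3.0, 0.35, 8),
    mepsc_amplitude=GroupValue(19.0, 0.35, 8),
    ppf_100ms=GroupValue(1.87, 0.04, 8),
    ltp_55_60=GroupValue(1.46, 0.07, 8),
    fepsp_slope_3v=GroupValue(0.22, 0.03, 12),
    fibre_volley_4v=GroupValue(0.15, 0.02, 12),
    theta_power_scale=1.2,
    theta_onset_latency=170.0,
))

# Mock depletion (IgG/neurogranin antibodies) leaves the tau effects intact.
CSF_MOCK_DEPLETED = _register(replace(CSF_TAU, label="csf_mock_depleted"))


def _interp_gv(control: GroupValue, full: GroupValue, s: float) -> GroupValue:
    return GroupValue(control.mean + s * (full.mean - control.mean),
                      control.sem + s * (full.sem - control.sem), full.n)


def get_preset(label: str, dilution_scale: float = 1.0) -> ConditionPreset:
    """Look up a condition preset, optionally scaled by CSF dilution.

    ``dilution_scale=1`` is the 1:15 working dilution (full printed effect);
    ``dilution_scale=0`` collapses every effect field to the control values.
    """
    if label not in _PRESETS:
        raise SpecificationError(f"unknown condition label {label!r}")
    full = _PRESETS[label]
    s = float(dilution_scale)
    if s == 1.0:
        return full
    if not 0.0 <= s <= 1.0:
        raise SpecificationError("dilution_scale must lie in [0, 1]")
    ctrl = _PRESETS["control"]
    kwargs = {"label": full.label, "dilution_scale": s,
              "theta_power_scale": ctrl.theta_power_scale + s * (full.theta_power_scale - ctrl.theta_power_scale),
              "theta_onset_latency": ctrl.theta_onset_latency + s * (full.theta_onset_latency - ctrl.theta_onset_latency)}
    for f in fields(ConditionPreset):
        if f.name in kwargs:
            continue
        kwargs[f.name] = _interp_gv(getattr(ctrl, f.name), getattr(full, f.name), s)
    return ConditionPreset(**kwargs)
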