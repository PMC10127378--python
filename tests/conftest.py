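"""Shared fixtures: calibrated drive gain and reference cells.

Session-scoped because gain calibration and cell simulation dominate the
suite's runtime; every fixture is seeded, so the suite is deterministic.
"""

import warnings

import numpy as np
import pytest

from slicephys.synth import get_preset, make_ou_current, simulate_eif
from slicephys.synth.dataset import (
    calibrate_ou_gain,
    ground_truth_from_targets,
    naturalistic_spec,
)
from slicephys.synth.presets import RAMP_RHEOBASE_CORRECTION_PA

warnings.filterwarnings("ignore", message=".*Covariance.*")

MASTER_SEED = 20240

CC_FS = 20_000.0


@pytest.fixture(scope="session")
def ou_gain() -> float:
    """Naturalistic-drive gain calibrated on the control condition."""
    return calibrate_ou_gain(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def control_cell():
    """A control-preset-mean neuron (intrinsic noise on)."""
    p = get_preset("control")
    return ground_truth_from_targets(
        p.em.mean, p.rin.mean, p.rheobase.mean - RAMP_RHEOBASE_CORRECTION_PA)


@pytest.fixture(scope="session")
def control_sweep_pair(control_cell, ou_gain):
    """Fit + held-out 40-s naturalistic sweeps of the control-mean neuron."""
    out = []
    for k in (0, 1):
        stim = make_ou_current(naturalistic_spec(ou_gain, seed=MASTER_SEED + 11 * k + 1), CC_FS)
        volt, spikes = simulate_eif(control_cell, stim, seed=MASTER_SEED + 13 * k + 2)
        out.append((stim, volt, spikes))
    return out


@pytest.fixture(scope="session")
def noiseless_control_sweep(control_cell):
    """A noise-free 40-s naturalistic sweep of the control-mean neuron."""
    gt0 = control_cell.with_noise(0.0)
    stim = make_ou_current(naturalistic_spec(76.0, seed=MASTER_SEED + 5), CC_FS)
    volt, spikes = simulate_eif(gt0, stim, seed=0)
    return gt0, stim, volt, spikes


def rng(*streams: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([MASTER_SEED, *streams]))
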