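"""Field-potential measurements: fEPSP slope, input-output, PPF, LTP.

The fEPSP slope is the least-squares gradient over a 1 ms window placed a
configurable offset after the fibre-volley trough (the brief presynaptic
deflection that follows the stimulus artefact); input-output curves collect
slopes across stimulus strengths; paired-pulse ratios divide the second
response's slope by the first (with template subtraction when responses
overlap); LTP time courses are normalised to the 20-min pre-induction
baseline and summarised 55-60 min after high-frequency stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import InsufficientDataError, SpecificationError, Trace

FV_SEARCH_MS = (0.5, 2.0)  # window after the artefact to find the volley trough
SLOPE_OFFSET_MS = 0.5  # slope window starts this long after the volley trough
SLOPE_WINDOW_MS = 1.0  # the slope is measured over exactly 1 ms
PPF_OVERLAP_LIMIT_MS = 50.0  # template subtraction below this interval
LTP_BASELINE_MIN = 20.0
LTP_WINDOW_MIN = (55.0, 60.0)  # post-HFS summary window


@dataclass
class FieldMeasurement:
    """One sweep's fEPSP measurement."""

    stimulus: float | None  # V (None for PPF/LTP sweeps at fixed strength)
    fepsp_slope: float | None  # mV/ms, positive magnitude; None if unmeasurable
    fibre_volley_amp: float | None  # mV, positive magnitude
    flag: str = ""  # non-empty when unmeasurable


@dataclass
class PlasticityResult:
    """Normalised LTP time course and its summary."""

    times_min: np.ndarray
    normalized: np.ndarray
    hfs_time_min: float
    potentiation_55_60: float
    baseline_mean_raw: float
    ppf_ratios: dict = field(default_factory=dict)


def _slope_fit(seg: np.ndarray, fs: float) -> float:
    t_ms = np.arange(seg.size) * 1000.0 / fs
    return float(np.polyfit(t_ms, seg, 1)[0])


def fepsp_slope(sweep: Trace, stim_time: float | None = None,
                fv_search_ms: tuple[float, float] = FV_SEARCH_MS,
                slope_offset_ms: float = SLOPE_OFFSET_MS,
                noise_floor_sd: float = 3.0) -> FieldMeasurement:
    """Measure the fibre volley and the 1-ms fEPSP slope of one sweep.

    The volley trough is the minimum in a short window after the stimulus
    artefact (time from sweep metadata unless given); the slope is the OLS
    gradient over the 1 ms starting ``slope_offset_ms`` after the trough.
    A sweep whose deflection stays within the pre-stimulus noise is flagged
    ``unmeasurable``.  Both numbers are DC-offset invariant.
    """
    if stim_time is None:
        stims = sweep.meta.get("stim_times_s")
        if not stims:
            raise InsufficientDataError("sweep lacks a stimulus-time marker")
        stim_time = stims[0]
    fs = sweep.fs
    i_stim = sweep.index_of(stim_time)
    pre = sweep.samples[max(i_stim - int(0.03 * fs), 0): i_stim]
    noise_sd = float(np.std(pre)) if pre.size > 10 else 0.0
    base = float(np.median(pre)) if pre.size else float(sweep.samples[0])

    i0 = i_stim + int(round(fv_search_ms[0] / 1000.0 * fs))
    i1 = i_stim + int(round(fv_search_ms[1] / 1000.0 * fs))
    if i1 >= sweep.n:
        raise InsufficientDataError("sweep too short after the stimulus")
    i_fv = i0 + int(np.argmin(sweep.samples[i0:i1]))
    fv_amp = base - float(sweep.samples[i_fv])

    j0 = i_fv + int(round(slope_offset_ms / 1000.0 * fs))
    j1 = j0 + int(round(SLOPE_WINDOW_MS / 1000.0 * fs))
    if j1 > sweep.n:
        raise InsufficientDataError("slope window extends past the sweep")
    seg = sweep.samples[j0:j1]
    deflection = base - sweep.samples[i0: j1 + int(0.005 * fs)].min()
    if noise_sd > 0 and deflection < noise_floor_sd * noise_sd:
        return FieldMeasurement(sweep.meta.get("stimulus_V"), None, None,
                                flag="unmeasurable")
    slope = -_slope_fit(seg, fs)  # negative-going fEPSP; report magnitude
    return FieldMeasurement(sweep.meta.get("stimulus_V"), slope,
                            max(fv_amp, 0.0))


def io_curve(sweeps: list[tuple[float, Trace]]) -> pd.DataFrame:
    """Input-output curve for one slice: stimulus -> slope and volley.

    Duplicate stimulus strengths are averaged (noted in ``attrs``); at
    least 4 strengths are required.
    """
    rows = []
    for v, sweep in sweeps:
        m = fepsp_slope(sweep)
        if m.flag:
            continue
        rows.append({"stimulus": v, "fepsp_slope": m.fepsp_slope,
                     "fibre_volley_amp": m.fibre_volley_amp})
    df = pd.DataFrame(rows)
    if df.empty or df["stimulus"].nunique() < 4:
        raise InsufficientDataError("need measurable sweeps at >= 4 stimulus strengths")
    dup = df["stimulus"].duplicated().any()
    out = df.groupby("stimulus", as_index=False).mean().sort_values("stimulus")
    out = out.reset_index(drop=True)
    out.attrs["duplicates_averaged"] = bool(dup)
    return out


def ppf_ratio(pair_sweep: Trace, interval_ms: float,
              template: Trace | None = None) -> float:
    """Paired-pulse ratio slope2/slope1 for one pair sweep.

    At intervals <= 50 ms the first response's tail overlaps the second;
    the aligned single-pulse ``template`` (same stimulus strength) is
    subtracted before the second slope is measured.
    """
    stims = pair_sweep.meta.get("stim_times_s")
    if not stims or len(stims) < 2:
        raise InsufficientDataError("pair sweep must carry two stimulus times")
    t1, t2 = stims[0], stims[1]
    m1 = fepsp_slope(pair_sweep, stim_time=t1)
    if m1.flag or not m1.fepsp_slope:
        raise InsufficientDataError("first response below the noise floor")
    if interval_ms <= PPF_OVERLAP_LIMIT_MS and template is not None:
        mt = fepsp_slope(template)
        scale = m1.fepsp_slope / mt.fepsp_slope if mt.fepsp_slope else 1.0
        t_stim_template = template.meta["stim_times_s"][0]
        shift = int(round((t1 - t_stim_template) * pair_sweep.fs))
        n = pair_sweep.n
        tmpl = np.zeros(n)
        src = template.samples - np.median(template.samples[: template.index_of(t_stim_template)])
        s0, s1 = max(shift, 0), min(shift + src.size, n)
        tmpl[s0:s1] = src[s0 - shift: s1 - shift]
        cleaned = Trace(pair_sweep.samples - scale * tmpl, fs=pair_sweep.fs,
                        kind="field", t0=pair_sweep.t0, meta=pair_sweep.meta)
        m2 = fepsp_slope(cleaned, stim_time=t2)
    else:
        m2 = fepsp_slope(pair_sweep, stim_time=t2)
    if m2.flag or not m2.fepsp_slope:
        raise InsufficientDataError("second response below the noise floor")
    return m2.fepsp_slope / m1.fepsp_slope


def ltp_quantify(slopes: np.ndarray, times_min: np.ndarray, hfs_time_min: float,
                 baseline_min: float = LTP_BASELINE_MIN,
                 window_min: tuple[float, float] = LTP_WINDOW_MIN) -> PlasticityResult:
    """Normalise an LTP slope series to baseline; summarise 55-60 min post HFS.

    Requires at least ``baseline_min`` minutes of pre-induction sweeps.
    The baseline mean of the normalised series is exactly 1 by construction.
    """
    slopes = np.asarray(slopes, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if slopes.shape != times_min.shape:
        raise SpecificationError("slope and time arrays must align")
    pre = times_min < hfs_time_min
    if not pre.any() or (hfs_time_min - times_min[pre].min()) < baseline_min - 1e-9:
        raise InsufficientDataError(
            f"baseline shorter than {baseline_min} min before induction")
    base = float(np.mean(slopes[pre]))
    if base <= 0:
        raise InsufficientDataError("non-positive baseline mean")
    norm = slopes / base
    w = (times_min >= hfs_time_min + window_min[0]) & (times_min <= hfs_time_min + window_min[1])
    if not w.any():
        raise InsufficientDataError("no sweeps in the 55-60 min summary window")
    return PlasticityResult(times_min=times_min, normalized=norm,
                            hfs_time_min=hfs_time_min,
                            potentiation_55_60=float(np.mean(norm[w])),
                            baseline_mean_raw=base)


def ltp_from_sweeps(sweeps: list[Trace], times_min: np.ndarray,
                    hfs_time_min: float, **kwargs) -> PlasticityResult:
    """Measure every sweep's slope, then quantify the time course."""
    slopes = []
    for sw in sweeps:
        m = fepsp_slope(sw)
        slopes.append(np.nan if m.flag else m.fepsp_slope)
    slopes_a = np.asarray(slopes, dtype=float)
    ok = np.isfinite(slopes_a)
    return ltp_quantify(slopes_a[ok], np.asarray(times_min)[ok], hfs_time_min, **kwargs)
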