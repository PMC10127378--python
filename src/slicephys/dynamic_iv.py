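"""Dynamic I-V neuron parameterisation and spike prediction.

The dynamic I-V method extracts a reduced neuron model from a single
naturalistic (fluctuating-current) sweep.  The transmembrane ionic current
at every sample is

    I_ion(t) = I_inj(t) - C dV/dt

Averaging I_ion in voltage bins (after excluding a window around each
spike) yields the dynamic I-V curve, whose shape over the subthreshold
range is the negative of the EIF model's force term

    F(V) = (1/tau_m)(Em - V) + (DeltaT/tau_m) exp((V - VT)/DeltaT)

so a weighted nonlinear fit of the binned curve recovers Em, tau_m
(hence Rin = 1000*tau_m/C), the spike threshold VT and the spike-onset
sharpness DeltaT.  Re-fitting VT in time-since-spike slices captures the
post-spike threshold elevation (the refractory part of the rEIF model),
and deterministic integration of the fitted model under a held-out sweep
yields predicted spike times that are scored against the observed train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .core import FitError, InsufficientDataError, Trace, check_aligned
from .intrinsic import detect_spikes
from .synth.eif import EIFGroundTruth, RefractorySpec, simulate_eif

PRE_SPIKE_EXCLUDE_MS = 1.0
POST_SPIKE_EXCLUDE_MS = 200.0
DEFAULT_BIN_WIDTH_MV = 1.0
MIN_BIN_COUNT = 50
CAPACITANCE_SLICE_HALFWIDTH_MV = 2.0
# The post-spike epoch is sliced finely at long lags: a single wide 50-200 ms
# slice mixes strongly survivorship-biased samples and corrupts its VT refit.
REFRACTORY_SLICES_MS = ((5.0, 10.0), (10.0, 20.0), (20.0, 50.0),
                        (50.0, 100.0), (100.0, 200.0))
MIN_SLICE_SAMPLES = 500
COINCIDENCE_WINDOW_MS = 5.0


@dataclass
class EIFParams:
    """Parameters recovered by the dynamic I-V fit."""

    C: float  # pF
    tau_m: float  # ms
    Em: float  # mV
    VT: float  # mV
    DeltaT: float  # mV

    @property
    def Rin(self) -> float:
        """Input resistance in MOhm (= 1000 * tau_m / C)."""
        return 1000.0 * self.tau_m / self.C


@dataclass
class RefractoryFit:
    """Post-spike threshold elevation, accumulating over spikes:
    VT(t) = VT_inf + jump * sum_j exp(-(t - t_j)/tau)."""

    threshold_jump: float  # mV
    decay_tau: float  # ms
    jump_se: float  # standard error of the jump amplitude
    vt_inf: float | None = None  # asymptotic threshold corrected for the
    # residual elevation carried by the baseline-curve samples
    slice_centers_ms: list = field(default_factory=list)
    slice_vt: list = field(default_factory=list)


@dataclass
class EIFFit:
    """Full dynamic I-V fit result."""

    params: EIFParams
    refractory: RefractoryFit | None = None
    rms_residual: float = np.nan  # pA, weighted fit residual
    prediction_score: float | None = None  # greedy matched-observed fraction
    gamma: float | None = None  # chance-corrected coincidence factor


@dataclass
class DynamicIVCurve:
    """Binned mean transmembrane current as a function of voltage."""

    v_centers: np.ndarray  # mV
    i_ion_mean: np.ndarray  # pA
    i_ion_sem: np.ndarray  # pA
    counts: np.ndarray
    C_used: float  # pF
    excluded_windows: list  # [(start, end)] in s

    def __post_init__(self) -> None:
        if not (len(self.v_centers) == len(self.i_ion_mean)
                == len(self.i_ion_sem) == len(self.counts)):
            raise InsufficientDataError("curve arrays must have equal length")
        if np.any(np.diff(self.v_centers) <= 0):
            raise InsufficientDataError("voltage bins must be strictly increasing")


def _dvdt(voltage: Trace, lag_ms: float = 0.0) -> np.ndarray:
    """Centred-difference derivative in mV/ms (endpoints one-sided).

    ``lag_ms`` widens the central difference to (V[k+m]-V[k-m])/(2m dt);
    a ~0.5 ms lag suppresses wideband intrinsic/recording noise by ~m^2
    while leaving the membrane-bandwidth signal (tau >= 3 ms) intact.
    """
    v = voltage.samples
    dt_ms = 1000.0 / voltage.fs
    m = max(1, int(round(lag_ms / dt_ms)))
    d = np.empty_like(v)
    d[m:-m] = (v[2 * m:] - v[:-2 * m]) / (2.0 * m * dt_ms)
    d[:m] = (v[1 : m + 1] - v[:m]) / dt_ms
    d[-m:] = (v[-m:] - v[-m - 1 : -1]) / dt_ms
    return d


def exclusion_mask(voltage: Trace, spikes: np.ndarray,
                   pre_ms: float = PRE_SPIKE_EXCLUDE_MS,
                   post_ms: float = POST_SPIKE_EXCLUDE_MS) -> np.ndarray:
    """Boolean mask, True where a sample is outside every spike window."""
    keep = np.ones(voltage.n, dtype=bool)
    n_pre = int(round(pre_ms / 1000.0 * voltage.fs))
    n_post = int(round(post_ms / 1000.0 * voltage.fs))
    for t in np.atleast_1d(spikes):
        i = int(round((float(t) - voltage.t0) * voltage.fs))
        keep[max(i - n_pre, 0): min(i + n_post, voltage.n)] = False
    return keep


def estimate_capacitance(stimulus: Trace, voltage: Trace,
                         spikes: np.ndarray | None = None,
                         slice_halfwidth: float = CAPACITANCE_SLICE_HALFWIDTH_MV,
                         method: str = "regression") -> float:
    """Capacitance (pF) from subthreshold samples near rest.

    Both methods restrict to samples within ``slice_halfwidth`` mV of the
    median subthreshold voltage, outside post-spike windows.

    ``method="variance"`` minimises Var(I_inj - C dV/dt); the variance is a
    parabola in C with closed-form minimiser
    ``C = Cov(I_inj, dV/dt) / Var(dV/dt)``.  This classical estimator is
    exact on clean data but reads low when wideband intrinsic current
    noise inflates Var(dV/dt).

    ``method="regression"`` (default) regresses dV/dt on (I_inj, V, 1) and
    returns 1/coefficient(I_inj).  Controlling for V absorbs the leak
    current's voltage dependence inside the slice, and intrinsic noise
    lands in the regression residual, so the estimate stays unbiased in
    the presence of membrane current noise.
    """
    check_aligned(stimulus, voltage)
    if spikes is None:
        spikes = detect_spikes(voltage)
    keep = exclusion_mask(voltage, spikes)
    v_all = voltage.samples[keep]
    if v_all.size < 100:
        raise InsufficientDataError("too few samples outside spike windows")
    v_rest = np.median(v_all)
    sel = np.abs(voltage.samples - v_rest) <= slice_halfwidth
    sel &= keep
    if sel.sum() < 100:
        raise InsufficientDataError("voltage slice around rest nearly empty")
    dvdt = _dvdt(voltage)[sel]
    i_inj = stimulus.samples[sel]
    if method == "variance":
        var = np.var(dvdt)
        if var <= 0:
            raise InsufficientDataError("flat voltage derivative in the rest slice")
        return float(np.cov(i_inj, dvdt)[0, 1] / var)
    if method != "regression":
        raise InsufficientDataError(f"unknown capacitance method {method!r}")
    X = np.column_stack([i_inj, voltage.samples[sel], np.ones(i_inj.size)])
    beta, *_ = np.linalg.lstsq(X, dvdt, rcond=None)
    if beta[0] <= 0:
        raise InsufficientDataError("non-positive current coefficient in capacitance fit")
    return float(1.0 / beta[0])


def build_dynamic_iv(stimulus: Trace, voltage: Trace, C: float,
                     bin_width: float = DEFAULT_BIN_WIDTH_MV,
                     min_count: int = MIN_BIN_COUNT,
                     spikes: np.ndarray | None = None,
                     sample_mask: np.ndarray | None = None) -> DynamicIVCurve:
    """Bin I_ion = I_inj - C dV/dt by voltage outside spike windows."""
    check_aligned(stimulus, voltage)
    if C <= 0:
        raise InsufficientDataError("capacitance must be positive")
    if spikes is None:
        spikes = detect_spikes(voltage)
    keep = exclusion_mask(voltage, spikes)
    if sample_mask is not None:
        keep &= sample_mask
    i_ion = stimulus.samples - C * _dvdt(voltage)
    v = voltage.samples[keep]
    i_ion = i_ion[keep]
    if v.size < min_count:
        raise InsufficientDataError("no samples left after spike exclusion")
    edges = np.arange(np.floor(v.min()), np.ceil(v.max()) + bin_width, bin_width)
    idx = np.digitize(v, edges) - 1
    n_bins = edges.size - 1
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    sums = np.bincount(idx, weights=i_ion, minlength=n_bins)[:n_bins]
    sq = np.bincount(idx, weights=i_ion ** 2, minlength=n_bins)[:n_bins]
    ok = counts >= min_count
    if not ok.any():
        raise InsufficientDataError(f"all voltage bins below occupancy {min_count}")
    mean = sums[ok] / counts[ok]
    var = np.maximum(sq[ok] / counts[ok] - mean ** 2, 0.0)
    sem = np.sqrt(var / counts[ok])
    centers = (edges[:-1] + 0.5 * bin_width)[ok]
    n_pre = PRE_SPIKE_EXCLUDE_MS / 1000.0
    n_post = POST_SPIKE_EXCLUDE_MS / 1000.0
    windows = [(float(t) - n_pre, float(t) + n_post) for t in np.atleast_1d(spikes)]
    return DynamicIVCurve(v_centers=centers, i_ion_mean=mean, i_ion_sem=sem,
                          counts=counts[ok], C_used=float(C),
                          excluded_windows=windows)


def _neg_force(v: np.ndarray, tau_m: float, em: float, vt: float, dT: float) -> np.ndarray:
    """-F(V) in mV/ms; i_ion/C should follow this."""
    return -((em - v) / tau_m + (dT / tau_m) * np.exp(np.clip((v - vt) / dT, -50, 50)))


def fit_eif(curve: DynamicIVCurve,
            delta_t_starts: tuple = (0.5, 1.0, 2.0, 4.0)) -> EIFFit:
    """Weighted nonlinear fit of the dynamic I-V curve to the EIF force term.

    Fits i_ion_mean/C against -F(V) with 1/SEM^2 weights (zero-SEM bins get
    the median weight), multi-starting over DeltaT and keeping the best
    residual.  Requires >= 8 occupied bins.
    """
    v = curve.v_centers
    if v.size < 8:
        raise InsufficientDataError(f"only {v.size} occupied bins (need >= 8)")
    y = curve.i_ion_mean / curve.C_used  # mV/ms
    sem = curve.i_ion_sem / curve.C_used
    pos = sem[sem > 0]
    sigma = np.where(sem > 0, sem, np.median(pos) if pos.size else 1.0)

    # initial linear estimates from the lower-voltage half of the curve
    half = v <= np.percentile(v, 60)
    slope, intercept = np.polyfit(v[half], y[half], 1)
    tau0 = 1.0 / max(slope, 1e-3)  # y ~ (v - em)/tau_m in the linear region
    em0 = -intercept * tau0
    vt0 = float(v.max())

    best, best_res = None, np.inf
    for dT0 in delta_t_starts:
        try:
            p0 = [max(tau0, 1.0), em0, vt0, dT0]
            popt, pcov = curve_fit(
                _neg_force, v, y, p0=p0, sigma=sigma, absolute_sigma=False,
                bounds=([0.5, -120.0, -80.0, 0.05], [200.0, -20.0, 20.0, 20.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        res = float(np.sqrt(np.mean(((_neg_force(v, *popt) - y) / sigma) ** 2)))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise FitError(f"EIF fit failed from all DeltaT starts {delta_t_starts}; "
                       f"bins={v.size}, range=({v.min():.1f},{v.max():.1f}) mV")
    tau_m, em, vt, dT = map(float, best)
    params = EIFParams(C=curve.C_used, tau_m=tau_m, Em=em, VT=vt, DeltaT=dT)
    rms_pa = float(np.sqrt(np.mean((( _neg_force(v, *best) - y) * curve.C_used) ** 2)))
    return EIFFit(params=params, rms_residual=rms_pa)


def _refit_vt(v: np.ndarray, y: np.ndarray, sigma: np.ndarray, base: EIFParams) -> tuple[float, float]:
    """Re-fit VT only, other parameters held at the baseline fit."""
    def f(vv, vt):
        return _neg_force(vv, base.tau_m, base.Em, vt, base.DeltaT)
    popt, pcov = curve_fit(f, v, y, p0=[base.VT], sigma=sigma,
                           absolute_sigma=False, maxfev=10000)
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def fit_refractory(stimulus: Trace, voltage: Trace, spikes: np.ndarray,
                   C: float, base_fit: EIFFit,
                   slices_ms: tuple = REFRACTORY_SLICES_MS,
                   min_samples: int = MIN_SLICE_SAMPLES) -> RefractoryFit | None:
    """Fit the post-spike threshold elevation from time-since-spike slices.

    Dynamic I-V curves are rebuilt from samples restricted to each
    time-since-spike slice; VT is re-fitted per slice with the other
    parameters held; an exponential decay through the slice thresholds
    gives the jump amplitude and its time constant.  Slices with fewer
    than ``min_samples`` usable samples are merged with their right
    neighbour (never dropped).  Returns None for trains under 20 spikes.
    """
    spikes = np.atleast_1d(spikes)
    if spikes.size < 20:
        return None
    fs = voltage.fs
    t_rel = np.full(voltage.n, np.inf)  # ms since the previous spike
    idx = np.round((spikes - voltage.t0) * fs).astype(int)
    t = np.arange(voltage.n)
    marker = np.zeros(voltage.n, dtype=np.int64)
    marker[idx] = idx
    prev = np.maximum.accumulate(np.where(marker > 0, marker, 0))
    has_prev = prev > 0
    t_rel[has_prev] = (t[has_prev] - prev[has_prev]) * 1000.0 / fs
    # The slice curves keep the approach to the next spike (that is the
    # signal an elevated threshold leaves) but drop the final millisecond:
    # the stereotyped AP waveform starts slightly before the detected
    # crossing and its upstroke would otherwise poison the slice bins.
    pre_keep = exclusion_mask(voltage, spikes, pre_ms=PRE_SPIKE_EXCLUDE_MS,
                              post_ms=0.0)

    # merge under-occupied slices to the right
    bounds = [list(s) for s in slices_ms]
    merged: list[list[float]] = []
    i = 0
    while i < len(bounds):
        lo, hi = bounds[i]
        n_in = int(np.sum((t_rel >= lo) & (t_rel < hi) & pre_keep))
        while n_in < min_samples and i + 1 < len(bounds):
            i += 1
            hi = bounds[i][1]
            n_in = int(np.sum((t_rel >= lo) & (t_rel < hi) & pre_keep))
        merged.append([lo, hi])
        i += 1
    if merged and len(merged) >= 2 and int(np.sum(
            (t_rel >= merged[-1][0]) & (t_rel < merged[-1][1]) & pre_keep)) < min_samples:
        lo = merged[-2][0]
        hi = merged[-1][1]
        merged = merged[:-2] + [[lo, hi]]

    # Slices at lags comparable to the mean ISI are dominated by samples
    # that "survived" without spiking, a selection that reads as a spurious
    # threshold elevation; restrict the fit to lags below half the mean ISI
    # (keeping at least the first three slices).
    mean_isi_ms = float(np.mean(np.diff(spikes))) * 1000.0 if spikes.size > 1 else np.inf
    kept = [s for s in merged if s[1] <= 0.7 * mean_isi_ms]
    if len(kept) < 3:
        kept = merged[:3]
    merged = kept

    centers, vts, ses, sels = [], [], [], []
    base = base_fit.params
    for lo, hi in merged:
        sel = (t_rel >= lo) & (t_rel < hi) & pre_keep
        if sel.sum() < min_samples:
            continue
        try:
            sub = build_dynamic_iv(stimulus, voltage, C, min_count=25,
                                   spikes=np.empty(0), sample_mask=sel)
            # VT is identifiable only with support near/above threshold
            if (sub.v_centers.size < 4
                    or sub.v_centers.max() < base.VT - 2.0 * base.DeltaT):
                continue
            vt, se = _refit_vt(sub.v_centers, sub.i_ion_mean / C,
                               np.where(sub.i_ion_sem > 0, sub.i_ion_sem / C, 1.0), base)
        except (InsufficientDataError, RuntimeError, ValueError):
            continue
        if not np.isfinite(vt):
            continue
        in_sel = t_rel[sel]
        centers.append(float(np.mean(in_sel)))
        vts.append(vt)
        ses.append(se)
        sels.append(sel)
    # slices whose VT refit is unconstrained (non-finite or huge SE) carry
    # no threshold information and are dropped, not merely downweighted
    keep_idx = [i for i, se in enumerate(ses)
                if np.isfinite(se) and 0 < se < 10.0]
    centers = [centers[i] for i in keep_idx]
    vts = [vts[i] for i in keep_idx]
    ses = [ses[i] for i in keep_idx]
    sels = [sels[i] for i in keep_idx]
    if len(centers) < 3:
        return None
    dvt = np.asarray(vts) - base.VT
    ses_a = np.asarray(ses)
    w = 1.0 / ses_a ** 2

    # The elevation accumulates over ALL preceding spikes (the simulator's
    # own update rule), so each slice's expected elevation is A * K_s(tau)
    # with K_s the mean summed unit kernel over the slice's samples.  A is
    # linear given tau; tau is found by a log-grid scan.
    from scipy.signal import lfilter

    dt_ms = 1000.0 / fs
    impulses = np.zeros(voltage.n)
    impulses[idx[idx < voltage.n]] = 1.0
    # samples behind the baseline curve: they too carry accumulated
    # elevation in high-rate cells, which the fitted base VT absorbed
    base_sel = exclusion_mask(voltage, spikes)
    best = None
    for tau in np.geomspace(5.0, 500.0, 25):
        a_coef = np.exp(-dt_ms / tau)
        kernel_sum = lfilter([a_coef], [1.0, -a_coef], impulses)
        k_base = float(np.mean(kernel_sum[base_sel])) if base_sel.any() else 0.0
        K = np.array([float(np.mean(kernel_sum[s])) if s.any() else 0.0
                      for s in sels]) - k_base
        denom = float(np.sum(w * K * K))
        if denom <= 0:
            continue
        A = float(np.sum(w * K * dvt) / denom)
        res = float(np.sum(w * (dvt - A * K) ** 2))
        if best is None or res < best[2]:
            se = float(np.sqrt(1.0 / denom * res / max(len(dvt) - 2, 1)))
            best = (A, tau, res, se, k_base)
    if best is None or best[0] <= 0:
        return None
    A, tau, _, se, k_base = best
    # keep the corrected asymptote physical (above rest)
    vt_inf = max(base.VT - A * k_base, base.Em + 2.0)
    return RefractoryFit(threshold_jump=A, decay_tau=tau, jump_se=se,
                         vt_inf=vt_inf,
                         slice_centers_ms=centers, slice_vt=vts)


def predict_spikes(fit: EIFFit, stimulus: Trace) -> np.ndarray:
    """Deterministic rEIF integration of the fitted model; spike times in s.

    Uses the fitted refractory threshold dynamics when available and the
    package reset convention (reset to Em + 5 mV, 2 ms absolute refractory).
    """
    p = fit.params
    vt = p.VT
    if fit.refractory is not None and fit.refractory.threshold_jump > 0:
        ref = RefractorySpec(threshold_jump=fit.refractory.threshold_jump,
                             threshold_decay_tau=fit.refractory.decay_tau)
        if fit.refractory.vt_inf is not None:
            vt = fit.refractory.vt_inf
    else:
        ref = RefractorySpec(threshold_jump=0.0, threshold_decay_tau=1.0)
    model = EIFGroundTruth(C=p.C, Em=p.Em, Rin=p.Rin, VT=vt, DeltaT=p.DeltaT,
                           refractory=ref, noise_sigma=0.0)
    _, spikes = simulate_eif(model, stimulus, seed=None, paste_aps=False)
    return spikes


def spike_coincidence(observed: np.ndarray, predicted: np.ndarray,
                      window_ms: float = COINCIDENCE_WINDOW_MS,
                      duration: float | None = None) -> tuple[float, float]:
    """Greedy one-to-one spike matching within +/- window.

    Returns ``(fraction, gamma)``: the matched-observed fraction and the
    chance-corrected coincidence factor Gamma (expected chance matches for
    a Poisson train of the predicted rate are subtracted and the count is
    normalised by the mean train length).  An empty observed train returns
    (nan, nan) -- undefined rather than zero.
    """
    if window_ms <= 0:
        raise InsufficientDataError("coincidence window must be positive")
    obs = np.sort(np.atleast_1d(observed).astype(float))
    pred = np.sort(np.atleast_1d(predicted).astype(float))
    if obs.size == 0:
        return float("nan"), float("nan")
    w = window_ms / 1000.0
    matched = 0
    j = 0
    for t in obs:
        while j < pred.size and pred[j] < t - w:
            j += 1
        if j < pred.size and abs(pred[j] - t) <= w:
            matched += 1
            j += 1
    frac = matched / obs.size
    if duration is None:
        duration = max(obs[-1], pred[-1] if pred.size else 0.0) or 1.0
    r_pred = pred.size / duration
    chance = 2.0 * r_pred * w * obs.size
    denom = 0.5 * (obs.size + pred.size) * (1.0 - 2.0 * r_pred * w)
    gamma = (matched - chance) / denom if denom > 0 else float("nan")
    return float(frac), float(gamma)


def fit_cell(stimulus: Trace, voltage: Trace,
             holdout: tuple[Trace, Trace] | None = None) -> EIFFit:
    """Full dynamic I-V workflow for one cell.

    Capacitance, dynamic I-V curve, EIF fit and refractory fit from one
    sweep; if a held-out (stimulus, voltage) pair is given, the fitted
    model predicts its spikes and the coincidence scores are attached.
    """
    spikes = detect_spikes(voltage)
    C = estimate_capacitance(stimulus, voltage, spikes)
    curve = build_dynamic_iv(stimulus, voltage, C, spikes=spikes)
    fit = fit_eif(curve)
    fit.refractory = fit_refractory(stimulus, voltage, spikes, C, fit)
    if holdout is not None:
        h_stim, h_volt = holdout
        observed = detect_spikes(h_volt)
        predicted = predict_spikes(fit, h_stim)
        fit.prediction_score, fit.gamma = spike_coincidence(
            observed, predicted, duration=h_volt.duration)
    return fit
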