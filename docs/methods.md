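# Methods

## Scope and philosophy

`slicephys` pairs a generative model of four slice-electrophysiology
recording modalities with the analysis stages that measure them.  The
generators are not test fixtures: they define the study conditions.  Each
condition preset (control aCSF, CSF-tau, CSF-tau-depleted,
CSF-mock-depleted) stores published group means with their SEMs and group
sizes, and the package's validation logic is closed-loop — simulate at
the published group size, analyse, and require the measured group mean to
fall within two SEMs of the preset value.

## Neuron model

Cells are refractory exponential integrate-and-fire (rEIF) neurons,

    C dV/dt = (C/τ_m)(E_m − V) + (C·Δ_T/τ_m)·exp((V − V_T,eff)/Δ_T) + I(t) + ξ(t)

integrated by fixed-step Euler–Maruyama at the 20 kHz acquisition rate
(dt = 0.05 ms).  A numerical spike is registered when V reaches
V_T + 5Δ_T; V resets to E_m + 5 mV, stays clamped for a 2 ms absolute
refractory period, and the effective threshold V_T,eff jumps by 8 mV,
decaying exponentially with τ = 120 ms.  Threshold jumps accumulate over
spikes, so at a few hertz the model expresses mild spike-frequency
adaptation — deliberately so: with a fast (tens of ms) decay the
condition presets cannot reproduce the published control/CSF-tau firing
rate pair under a shared-gain drive, while a 120 ms decay (well within
the adaptation range reported for CA1 pyramidal cells) flattens the rate
separation to the published ~1.8-fold.

Since the numerical spike cut truncates the action potential ~15 mV above
threshold, the emitted voltage trace has a stereotyped AP waveform
(0.3 ms rise to +35 mV, ~1 ms repolarisation) pasted over the absolute
refractory window at each spike.  The pasted waveform never feeds back
into the dynamics; it exists so that downstream threshold detectors,
AP-amplitude and half-width measurements see realistic spikes.

Units are fixed package-wide: mV, pA, pF, MΩ, ms — under which
R_in = 1000·τ_m/C and ΔV = I·R/1000 hold exactly.

### Parameters and their derivation

* `C = 100 pF`, typical for CA1 pyramidal somata; `Δ_T = 3.0 mV`.  Δ_T
  is at the sharp-but-finite end of the range estimated for pyramidal
  cells.  It was chosen, together with the refractory decay, during the
  one-time calibration that makes the published control (2.3 Hz) and
  CSF-tau (4.2 Hz) rates coexist under a shared drive gain: a smaller Δ_T
  makes the fluctuation-driven escape rate too steep a function of the
  threshold distance, and no gain then satisfies both conditions.
* `V_T = E_m + Δ_T + (rheobase − 19 pA)·R_in/1000`.  The preset rheobase
  is what the ramp assay should recover.  A 0.33 pA/ms ramp reads above
  the EIF saddle-node rheobase by a lag term (ramp rate × τ_m ≈ 5 pA)
  plus a dynamic escape delay (≈ 14 pA for preset-range cells, measured
  against generator ground truth), hence the 19 pA correction.
* Intrinsic current noise ξ: white, 40 pA·√ms, giving ~1 mV of resting
  membrane-potential noise — enough that detection, fitting and
  prediction are tested against realistic jitter without drowning the
  naturalistic drive.
* Between-cell variability: each cell's E_m, R_in and rheobase are drawn
  as Gaussians with SD = published SEM × √(published n), which reproduces
  the published group SEMs at the published group sizes.  Rheobase draws
  are truncated below 25 pA (a lower value is a tonically firing cell no
  experimenter would hold), with the truncated-normal location solved so
  the truncated mean still equals the preset value.

## Naturalistic drive and gain calibration

The fluctuating current is the sum of two exactly-discretised
Ornstein–Uhlenbeck processes (x[k+1] = x[k]·e^(−dt/τ) + σ√(1−e^(−2dt/τ))·z)
with τ_fast = 3 ms and τ_slow = 10 ms, equal unit component SDs, zero
mean bias, multiplied by a single gain.  The gain is a fixed experimental
input shared by every recording and condition; it is calibrated once by
bisection so that the control preset's mean-parameter neuron fires at the
control target rate (2.3 Hz) averaged over six independent 40-s sweeps
(0.05 Hz tolerance).  Calibrating on the mean-parameter cell rather than
a random cell draw keeps a calibration subset's sampling luck from
leaking into every downstream rate measurement; the calibrated gain is
~75 (so each OU component has an SD of ~75 pA).

## Dynamic I–V analysis

* **Capacitance.**  Default estimator: regress dV/dt on (I_inj, V, 1)
  within ±2 mV of the median subthreshold voltage (post-spike windows
  excluded) and invert the current coefficient.  Controlling for V
  absorbs the leak current's local voltage dependence, and wideband
  intrinsic noise lands in the residual, so the estimate is unbiased to
  ~1 % on noisy cells.  The classical variance-minimising closed form
  C = Cov(I, dV/dt)/Var(dV/dt) is retained (`method="variance"`) and is
  oracle-checked against a brute-force grid; on clean data the two agree,
  but the classical form reads ~15 % low at 20 kHz when membrane current
  noise inflates Var(dV/dt).
* **Curve.**  I_ion = I_inj − C·dV/dt with centred differences at the
  native rate (optional smoothing is deliberately off by default — bin
  averaging already cancels derivative noise), samples from 1 ms before
  to 200 ms after each spike excluded, 1 mV bins, minimum 50 samples per
  bin.
* **EIF fit.**  Weighted (1/SEM²) nonlinear least squares of i_ion/C
  against −F(V), multi-started over Δ_T ∈ {0.5, 1, 2, 4} mV, best
  residual kept.  Zero-SEM bins receive the median weight.
* **Refractory fit.**  Dynamic I–V curves are rebuilt in
  time-since-spike slices (5–10, 10–20, 20–50, 50–100, 100–200 ms;
  under-occupied slices merge rightward, never dropped) and V_T is
  re-fitted per slice with the other parameters held.  Two measured
  biases shape this stage: a single wide 50–200 ms slice is dominated by
  samples that *survived* without spiking — a selection that reads as a
  spurious threshold elevation — so the long lags are sliced finely and
  slices whose upper edge exceeds 0.7 × the mean inter-spike interval
  are excluded; and because the threshold elevation accumulates over
  spikes, the decay is fitted with the multi-spike kernel
  ΔV_T(t) = A·Σ_j e^(−(t−t_j)/τ) (A linear given τ, τ by log-grid scan),
  including the baseline epoch's own residual kernel so the asymptotic
  threshold is corrected for what the baseline fit absorbed.  A
  single-exponential in time-since-last-spike is badly biased whenever
  ISIs are comparable to the decay constant.
* **Prediction.**  Deterministic integration of the fitted rEIF under
  the held-out stimulus; greedy one-to-one ±5 ms matching reports the
  matched-observed fraction, alongside the chance-corrected Γ factor.
  On noisy control-preset neurons the score is ~0.75–0.90 with predicted
  spike counts within a few percent of observed; the irreducible ceiling
  (true parameters, noise-free model vs noisy cell) is ~0.8 at the
  default intrinsic noise.

## mEPSC generation and detection

Generation: Poisson event times at the slice's mean interval; amplitudes
lognormal (CV 0.3); peak-normalised biexponential kernels (0.5 ms rise,
5 ms decay), negative-going at −60 mV holding; additive Gaussian baseline
noise of 2 pA RMS at 10 kHz.  No amplitude cut-off is applied at
generation — the >6 pA rule belongs to detection, and the ground-truth
table records every event.

Detection: candidates are negative threshold crossings (3.5 × the
median-absolute-deviation noise SD) of the 1–1000 Hz band-passed trace;
amplitudes and kinetics are measured on a zero-phase 2 kHz low-passed
copy — single-sample minima of the raw trace otherwise masquerade as
>6 pA events — with the event amplitude read as a ±0.3 ms average around
the trough (the near-unbiased trade-off between the noise-minimum bias of
a point read and the kernel's peak-flatness loss) against a local
pre-event median baseline.  The decay fit starts where the event has
fallen to 80 % of peak, past the rising component.  Acceptance requires
amplitude > 6 pA and rise faster than decay; rejected candidates stay in
the table with reasons.  At the preset signal-to-noise the detector runs
at ≥ 0.95 sensitivity with ~0 accepted false positives per trace, and
per-slice amplitude bias ≈ −0.1 pA against ground truth.

## Field potentials

Synthetic sweeps superpose a biphasic stimulus artefact, a narrow
fibre-volley trough 1.5 ms later, and an fEPSP whose first 2.5 ms are
exactly linear at the programmed slope before an 8 ms exponential
recovery.  The analysis measures the least-squares gradient over the 1 ms
window starting 0.5 ms after the volley trough — inside the linear
segment by construction, as in the recordings the convention imitates.
Paired pulses at ≤ 50 ms subtract the scaled single-pulse template before
measuring the second slope.  LTP series (sweeps every 30 s; 20 min
baseline; plateau approached with an 8-min time constant plus a brief
post-tetanic transient) are normalised to the baseline mean — exactly 1
by construction — and summarised over minutes 55–60 after induction.

## Theta oscillations

Generation is phenomenological: 1/f background noise plus a theta-band
sinusoid that grows with a 15 s envelope after the onset latency; no
network model stands behind it.  PSDs are Welch averages of
Hanning-windowed 2048-sample blocks at half overlap; `power` is a density
(mV²/Hz) normalised so band-integrated power equals segment variance, and
theta power integrates 4–7 Hz (the published analysis states mV² without
a normalisation convention; this Parseval convention is adopted).  Peak
oscillatory power maximises baseline-subtracted theta power over sliding
100–300 s windows, flooring negative bins at zero with a logged count.
Onset latency thresholds the 5-s-smoothed theta-band envelope at baseline
mean + 3 SD sustained for 10 s; traces that never cross are flagged "no
oscillation" and excluded from group latency statistics.  Band-pass
filtering at multi-kHz rates is performed at a decimated rate and
re-interpolated (the band sits two decades below the decimated Nyquist),
because direct IIR design at a 0.1 % relative bandwidth is numerically
hostile.

## Statistics

Kruskal–Wallis (tie-corrected) with Dunn's z comparisons, Holm-adjusted
(the published analysis names Dunn's test without a correction family;
unadjusted values are also emitted).  Wilcoxon signed-rank reports the
signed rank sum with the exact null distribution for n ≤ 25.  Two-sample
KS uses the exact sup-difference statistic with the asymptotic p.  The
input–output two-way ANOVA (condition × stimulus strength) reports the
condition main effect with Šidák-adjusted per-strength pairwise
follow-ups.  All tests calibrate to type-I error within [0.04, 0.06] at
α = 0.05 on simulated nulls.

## What the generators do and do not emulate

They emulate: acquisition rates (20 kHz whole-cell, 10 kHz field),
protocol structure, between-cell/slice variability at published SEMs,
intrinsic membrane noise, baseline noise, and the summary statistics of
each condition.  They do not emulate: channel-level biophysics,
electrode/bridge artefacts, slow drift, seal degradation, synaptic
conductance (the drive is a current), GABAergic microcircuits, or any
network mechanism of theta generation.  Passing closed-loop tests
therefore demonstrates that the analysis stages are unbiased and robust
at realistic signal-to-noise — not that they are immune to the artefact
structure of real rigs.

## Known limitations

* The published CSF-tau-depleted triple (E_m −69 mV, R_in 126 MΩ,
  rheobase 74 pA) makes that condition *more* excitable than control in
  any EIF-family model (threshold distance 10.3 vs 13.2 mV), yet its
  published firing rate is lower (2.1 vs 2.3 Hz).  Under the shared-gain
  drive the depleted condition therefore simulates at ~3.5–4 Hz; every
  other depleted-condition quantity round-trips.
* The published per-slice mean mEPSC intervals (17.6 s control, 1.9 s
  CSF-tau) imply a 9.3-fold frequency change, which cannot be reconciled
  with the separately published "7.5-fold" figure under
  frequency = events/time.  The presets carry the printed intervals, so
  the pipeline's frequency ratio reads ~9.
* Group-level sampling is faithful to published SEMs, so closed-loop
  recovery at published n has the same ±2 SEM sampling scatter a real
  replication would; roughly one master seed in ten lands a group mean
  marginally outside a two-SEM band by draw luck alone.
* Slice-level refractory estimation loses identifiability in cells firing
  above ~6 Hz (all lags survivorship-biased); the fit then falls back to
  fewer slices and wider uncertainty.
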