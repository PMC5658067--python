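# Methods

`swbold` re-implements, as a tested pipeline over synthetic ground truth, an
analysis chain relating optically recorded slow oscillation-associated
calcium waves to whole-brain BOLD fMRI: slow-wave event detection in
fiber-photometry traces, model-free (FIR) hemodynamic-response extraction,
event-related GLM mapping with leave-n-out hemodynamic response functions,
and correlation-based maps with specificity controls. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic test bed does and does not show about real data.

## The synthetic recordings

Because no paired in-vivo datasets are deposited, every stage is exercised
on a generator (`swbold.simulate`) whose defaults are the published study
conditions.

**Calcium traces.** Slow-wave transients are planted as a linear rise to
peak over `2*rise_time` (so the onset-to-half-maximum interval equals
`rise_time` by construction) followed by an exponential decay with constant
`tau = (duration - rise_time)/ln 2`, where `duration` is the full width at
half maximum. Events arrive as a renewal process: a hard refractory period
(default 3.0 s, comparable to the transient's suprathreshold extent, so
planted waveforms do not fuse) plus an exponential interval tuned to the
target rate. Defaults: 10.9 events/min; OGB-1 rise 72 ms / GCaMP6f rise
163 ms; half-max duration 1356 ms; peak amplitude 2.6 df/f. Per-wave
amplitudes, rise times and durations are log-normal with coefficients of
variation 0.2 / 0.3 / 0.3 — the published standard errors imply per-wave
spreads of this order, and that variability is part of what the detector
must tolerate. Waves superpose linearly on a sinusoidal baseline drift
(0.3 df/f, 240 s period) and white noise (sd 0.05 df/f) at 2 kHz.

With these kinetics the decay tails are long (`tau ~ 1.85 s`), so at the
in-scanner rate the trace rarely returns to a true zero baseline between
waves — a property the in-vivo recordings share ("the raw signal does not
decay to baseline" between closely spaced events). Several design choices
below exist to cope with exactly this.

**BOLD sessions.** A contiguous "cortical" slab (40% of the voxel grid)
carries the onset-impulse train convolved with a gamma-variate response
(unit-peak form, `y(t) = amp*((t-t0)/(a*b))^a * exp(a - (t-t0)/b)`), with
shape solved numerically so that time-to-peak = 6.5 s and half-maximum
duration = 6.8 s at onset latency 0.7 s, peak amplitude 0.17% signal
change. An isolated event therefore peaks at exactly the configured percent
change. Onset impulses rather than duration boxcars drive the convolution:
at TR = 1 s, event durations of 1-2 volumes would otherwise make the
planted single-event amplitude duration-dependent and `0.17%` ill-defined
(a boxcar model remains available). All voxels receive a common scanner
drift (0.5%, 300 s) and independent stationary AR(1) noise (rho = 0.3,
marginal sd 0.5%) around a written baseline of 100, so 1 unit = 1% signal.

The noise default corresponds to a temporal SNR of ~200 and yields mean
cortical t-values near 8 on a 20-min session — deliberately above the
in-vivo activation regime (mean T ~ 4) so that whole-compartment recovery
at family-wise thresholds is achievable; see "Limitations".

## Calcium preprocessing

2 kHz traces are downsampled to 1 kHz by pairwise averaging, baseline
corrected, and zero-phase low-pass filtered (4th-order Butterworth, 100 Hz,
applied forward-backward).

**Baseline estimation** works in shifted windows of 2500 samples (stride =
half a window). In each window the estimate is the median of the *floor
cohort*: samples within twice the sample-to-sample noise scale (MAD of
first differences) of the window's 10th percentile. Two gates protect the
estimate from the calcium signal itself: windows whose floor cohort covers
under 20% of the window (the window sits inside a transient) and windows
whose floor moves between the window halves by more than the noise scale (a
decaying tail, not a baseline) contribute no knot and are bridged by a
monotone (PCHIP) spline. Knots at the trace ends are extended from the last
accepted floor along a coarse long-window median trend so the spline never
extrapolates freely. The estimator is translation-equivariant, hence
idempotent up to interpolation error; when no window exposes a floor (e.g.
a noiseless, strictly sloped trace) it falls back to the long-window
median, which tracks drift exactly but cannot follow transients. Its
operating assumption is |baseline slope| x window << noise scale; df/f
conversion for raw-fluorescence input uses the same machinery for f0.

## Slow-wave detection

Detection runs on the preprocessed 1 kHz trace after an exponential moving
average (25 ms window; `y_t = a*x_t + (1-a)*y_{t-1}`, `a = 2/(N+1)`,
`y_0 = x_0`). Thresholds come from the amplitude histogram of the filtered
trace: the reference amplitude is its 95th percentile — the upper edge of
the histogram bulk. An extreme percentile (e.g. 99.9) is not usable as
"maximum" here: with multi-second decay tails the top permille of samples
sits far above the typical wave peak and a 70% threshold then misses a
third of genuine waves. The onset threshold is 70% of the reference and the
termination threshold 50% of the onset threshold; hysteresis segmentation
yields raw segments.

Post-processing applies three rules in order: (1) segments separated by
less than 100 ms merge into one wave; (2) waves shorter than 600 ms are
discarded (both boundaries strict, as stated); (3) waves whose peak fails
to reach the 90% point of the cumulative amplitude histogram of the whole
filtered trace are discarded. The intensity cutoff of rule (3) is capped at
the onset threshold: a wave that crossed 70% of the reference already
belongs to the signal population, so the rule acts as a floor on weak
activity admitted at permissive thresholds — its natural regime is the
threshold-calibration scan (`calibrate_threshold`), which sweeps candidate
fractions, maps each through binarization + FIR GLM to a suprathreshold
voxel count, and returns the fraction at the inflection (maximum discrete
second difference) of that curve.

Terminations, which the EMA localizes less sharply than onsets, are
optionally re-anchored to the noise level: each event ends at the last
sample above baseline + 2 sigma before the signal first stays below that
level for 50 ms, clamped to the next onset. Note that with OGB-1 kinetics
this tracks the indicator decay tail, so refined durations (~4-5 s) reflect
fluorescence visibility, not up-state duration — the reason the default GLM
regressor uses onset deltas (below).

**Per-wave quantification** follows the population-imaging conventions:
rise time = transient onset to half-maximum; duration = first to last value
above half maximum; amplitude = df/f from the pre-onset baseline (mean of
the 200 ms before onset) to the peak. The transient onset is recovered by a
line fit to the 20-80% rising flank extrapolated to the local baseline (the
detector's threshold crossing sits ~60% up the flank and is not the
physiological onset). The falling half-max crossing requires 25 ms of
persistence below the level so single noise dips on the slow decay do not
truncate the width. These definitions presuppose transients that return
toward baseline; recovery is unbiased (sub-SE) for waves separated by
>= ~10 s, while at the in-scanner rate the predecessor's tail biases
durations by a few tens of ms.

## Hemodynamic response extraction and quantification

The binarized slow-wave vector marks every volume overlapping a detected
event; FIR designs and impulse regressors are driven by the event onset
volumes directly (run starts of the duration-binarized vector under-count
onsets once refined durations make consecutive events' volumes touch).

The FIR basis has 40 one-TR bins spanning 20 s before to 20 s after onset;
per-voxel least squares (percent-of-mean scaling, intercept, AR(1)
prewhitening as below) yields 40 beta maps. An F test over all 40 bins
(p < 0.05) defines active voxels; the slice with the most active voxels
anchors the selection of the 10 highest-F voxels in it and in each
neighbor slice (30 voxels; an exclusion mask, e.g. for the sinus vein, is
honored; ties break by ascending index). The mean beta series of those
voxels, minus the mean of the 5 s pre-onset bins, is the session's
hemodynamic response. Estimation efficiency relies on jittered onsets —
strictly periodic events convolved with a response wider than their period
leave almost no regressor variance.

For analysis of a given session, the HRs of the *other* sessions are
averaged, truncated to 0-15 s (where the timecourses have returned to
baseline) and peak-normalized — the leave-n-out kernel that avoids
circularity. The canonical alternative is the standard double-gamma HRF
(peak 6 s, undershoot 16 s, ratio 1/6).

HRs are summarized by TTP, dSA, and HMD, preferably through a gamma-variate
fit (multi-start trust-region least squares over shape/onset grids; the
moving-average smoothing used for raw per-event timecourses defaults to off
for FIR estimates, which are already event averages). Discrete
quantification refines the peak with a three-point parabola and
interpolates the half-maximum crossings.

## Event-related GLM

BOLD preprocessing: discard the first five volumes, smooth with a 0.5 mm
FWHM Gaussian (converted to voxels via the header geometry), high-pass with
a discrete-cosine basis (cutoff 1/128 s, DC retained). The session records
its cutoff and all later model fitting passes regressors (and regress-out
covariates) through the same projection, and charges the removed dimensions
against the residual df — filtering data and model differently would leave
shared unmodeled low-frequency signal.

Regressors are the detected slow-wave onsets (deltas; duration boxcars
optional) convolved with the chosen HRF and mean-centered. Serial
correlation is handled by a single pooled AR(1) coefficient from the lag-1
autocorrelation of the OLS residuals, followed by Cochrane-Orcutt
prewhitening (first row scaled by sqrt(1-rho^2)) and a refit; whitened
residual lag-1 autocorrelation is < 0.05 on AR(1)-simulated data. F maps
are extra-sum-of-squares tests; t maps use one-sided contrasts with
family-wise error control by Bonferroni over in-mask voxels — conservative
and simple at desk scale (random-field theory is out of scope). ROI
comparisons check normality per sample (Lilliefors) and use a two-tailed t
test when both pass, otherwise the Wilcoxon rank-sum test.

## Controls and correlation maps

Time-mirroring maps each event (onset, d) to (T - onset - d, d), preserving
count, durations and interval statistics while destroying timing; swapping
transplants another session's events (clipped to length). Seed maps
correlate the seed-mean timecourse with every target voxel (threshold
r > 0.5; 26-connected clusters > 300 voxels counted). The calcium-informed
map first baseline-corrects each voxel with a 100 s window, computes
per-voxel event-locked mean responses (0-20 s, onset-anchored), correlates
them with the ROI-mean reference, keeps r > 0.8, removes clusters under 70
voxels, and derives a per-voxel time-to-peak map. Event-locked rather than
full-timecourse correlation is the primary interpretation (matching the
reference construction); full-timecourse seed correlation is separately
available. Lagged cross-correlation reports the Pearson coefficient over
the overlap at every integer-sample lag.

## Problem sizes

Default exercise scales, chosen to characterize estimator behavior well
within interactive runtimes: 30-40 min single sessions (2 kHz photometry;
1200-2405 volumes of 10x10x4 to 12x12x5 voxel grids) for rate and HR
recovery; pooled cohorts of three sessions for leave-n-out analyses;
~500-600 well-separated waves for wave-parameter recovery; 10^4 voxels for
null calibration; 20 seeded coupled sessions for the specificity controls.

## Limitations

- The generator has no vascular nonlinearity, motion, susceptibility
  artifacts, or spatially varying HRFs; passing recovery tests here shows
  the estimators are consistent under the stated model, not that the model
  captures every property of in-vivo recordings.
- Wave-parameter definitions assume near-baseline separation between
  transients; at the in-scanner rate the decay-tail overlap biases measured
  durations by a few tens of ms (well under the planted between-wave
  spread).
- The baseline estimator requires drift slow relative to its window and
  some identifiable quiescent floor; traces that never leave the decay
  tails have an intrinsically ambiguous baseline, and repeated correction
  then re-anchors to the running floor.
- Single-voxel correlation thresholds (r > 0.5 seed-based, r > 0.8
  calcium-informed) presuppose shared signal well above thermal noise; at
  the default CNR the full-timecourse seed threshold is unreachable by
  construction, and the analysis drivers demonstrate both regimes.
- At the coupling strength needed for whole-compartment recovery under
  Bonferroni FWE (mean cortical t >= ~5.5, about twice the in-vivo
  activation strength), a time-mirrored event train occasionally aligns
  with the true signal by chance (alignment correlation sd ~ 0.1) strongly
  enough to produce genuine suprathreshold voxels; this leakage is
  invariant to session length. The mirrored-control error rate is therefore
  slightly above nominal in a minority of seeds even though the chain's
  intrinsic family-wise error is nominal (verified on pure-null sessions).
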