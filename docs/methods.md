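# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `gammaloop`. It is the reference for *why* the pipeline is
built the way it is; the README covers *how* to run it.

## Scientific setting

Gamma oscillations (30–80 Hz) generated in the olfactory bulb (OB) are
transmitted to the piriform cortex (PirC) and broader limbic circuitry,
where their power correlates with affective state in rodent models.
Experiments in this area involve three computational components that this
package reimplements as a tested pipeline:

1. **Offline gamma-event detection** in local field potentials (LFPs):
   band-limited RMS power thresholded against an outlier-trimmed baseline.
2. **Multitaper spectral analysis**: power spectra, OB–PirC coherence, and
   the gamma-power-change ratio used to relate interventions to behaviour.
3. **Closed-loop phase-locked stimulation**: a real-time chain that detects
   OB gamma and feeds the filtered waveform back to PirC either in phase
   (constructive) or in anti-phase (destructive), simulated here sample by
   sample.

Because raw in-vivo recordings are not publicly deposited, every stage is
exercised against a synthetic LFP generator with exact ground truth. All
guarantees are therefore *property-based*: detector–oracle identity,
recovery of injected bursts, phase fidelity of the simulated stimulus, and
recovery of prescribed correlation structure.

## Synthetic data generator (`synth_data`)

The generator emulates a four-site implanted montage: OB (gamma source),
left and right PirC (targets), and one lateral-entorhinal/ventral-hippocampal
channel used as a reference. Construction is strictly additive —
background + bursts + artifacts — and fully deterministic given the seed
(per-channel sub-streams are spawned from a seed sequence, so adding
channels or components never perturbs the others).

**Background.** Independent per-channel 1/f^β noise, synthesized by
spectral shaping of white Gaussian noise (exact slope control on 1–100 Hz;
flat below 1 Hz to keep variance finite; DC removed), then normalized to
exactly `background_rms`. Default β = 1 (pink), RMS = 1 arbitrary unit —
only amplitude *ratios* matter downstream.

**Gamma bursts.** Poisson arrivals (default 0.2 s⁻¹); hann-enveloped
sinusoids with frequency drawn uniformly in 35–75 Hz (inset from the
30–80 Hz analysis band so that energy stays in band after filter
roll-off); peak amplitude = `burst_amplitude_snr` × the RMS of the
background inside 30–80 Hz (default SNR 5). Each burst is injected on OB
and reproduced on both PirC channels delayed by `ob_to_pirc_lag_s`
(default 5 ms), emulating coherent feed-forward gamma transmission.

Burst durations are uniform on **0.3–0.5 s**. This default is set against
the detector's structural resolution: the detection rule requires three
consecutive 50 ms supra-threshold windows, i.e. a ≥150 ms core, and a
hann-enveloped burst spends only about half its duration above its
half-maximum, so bursts must last ≈2 × 150 ms to present a detectable core
at moderate SNR. Shorter bursts are not "missed" by a deficient
implementation — they are undetectable under the stated rule, at any
implementation quality.

**Common-mode artifacts.** Hann-windowed white-noise transients (default
0.1 s, amplitude 20 × background RMS — EMG/movement artifacts are an order
of magnitude larger than LFP background) added *identically* to all
channels. They exist to exercise reference subtraction in the online path;
the offline detector deliberately has no artifact handling, so detection
benchmarks are run with the artifact rate set to zero (otherwise they would
measure the confound, not the detector).

**What the generator does not model:** respiration-coupled burst timing,
biophysical mitral-cell dynamics, behavioural-state switching,
channel-specific artifact gains, electrode drift, or line noise. Passing
recovery tests on this generator shows the algorithms implement their
definitions correctly at realistic SNR; it does not certify performance on
real recordings with structured noise.

## Offline gamma-event detection (`gamma_events`)

Pipeline: polyphase anti-aliased resampling to 1250 Hz → 8th-order
Butterworth band-pass 30–80 Hz applied forward-backward (zero phase lag;
SOS realization for numerical stability) → RMS in 50 ms windows → baseline
→ thresholding.

Windows *tile* the signal by default (step = window). The
"three consecutive windows" rule is most interpretable on a tiling, where
it imposes a clean ≥150 ms core; `step_s` is configurable for genuinely
sliding analyses. At 1250 Hz a 50 ms window quantizes to 62 samples
(49.6 ms); all reported times use the realized window.

**Baseline.** Mean and SD of the pooled window powers after discarding
windows above mean + 4 SD, *iterated to a fixed point* (the keep-set only
shrinks, so iteration terminates). A single trim pass is not enough: burst
windows lie far above the clean background, inflate the first-pass SD, and
enough of them survive one pass to raise the detection threshold by tens of
percent, visibly suppressing sensitivity. On series without heavy
contamination the iteration converges after one pass and equals the naive
trim. `outlier_k` is configurable.

**Detection.** Cores are maximal runs of ≥ `min_consecutive` (3) windows
strictly above mean + 3 SD; each core extends outward through contiguous
windows at or above mean + 2 SD; extended spans that touch are merged into
one event (boundaries "around" distinct peaks cannot overlap as distinct
events). Onset/offset are the outer edges of the extended span. Per-event
peak and mean RMS are both reported, since figure-level event-power
summaries can be defined either way. An `amplitude_floor` (default 0)
guards the degenerate near-constant-signal case where SD ≈ 0 would make
everything an event; detection with SD = 0 *and* floor = 0 raises rather
than returning nonsense.

The detector is verified two ways: exact equivalence with an independent
brute-force run-enumeration oracle on randomized series, and
sensitivity/precision ≥ 0.9 with median onset error ≤ 100 ms against
generator ground truth at SNR 5 (matching = any temporal overlap, after
merging overlapping truth bursts).

## Multitaper spectra and coherence (`spectral`)

Sliding 3 s windows with 50% overlap; each window demeaned (removes DC
leakage) and tapered with unit-energy DPSS tapers; one-sided densities
averaged over windows × tapers and normalized so the integral over
frequency equals the signal variance (Parseval, verified to 5% on tones).
Defaults: time-bandwidth 3, 5 tapers — the common convention where the
source analyses do not state taper parameters; both are configurable and
recorded in every `SpectralEstimate`.

Coherence is reported as **magnitude** (not squared), with cross-spectral
phase arg⟨XY*⟩ (positive = y lags x). It is undefined from a single
window–taper product and raises in that case. For independent signals the
magnitude estimator has a positive bias of order 1/√K (K = windows ×
tapers); the test suite uses 3/√K as a generous analytic bound.

`band_rms_series` (zero-phase band-pass then windowed RMS) provides gamma
power time courses; `power_change(pre, post) = (post − pre)/pre` is the
dimensionless intervention metric (scale-invariant, −1 = total
suppression, error on pre = 0).

`phase_lag` band-passes both signals, takes the per-sample analytic-signal
phase difference, and reports the circular mean and resultant length over
high-amplitude epochs — samples where the joint envelope (geometric mean of
the two Hilbert envelopes) exceeds its median. The inclusion rule is a
design choice (no rule is stated in the source analyses): phase is only
meaningful where both signals actually oscillate. Whether the original
analysis used cross-spectral or analytic-signal phase is unstated; the
analytic-signal route was chosen because it also serves the stimulus
phase-fidelity measurement.

## Closed-loop simulator (`closed_loop`)

The stream runs at 500 Hz per channel (so one sample = the 2 ms detection
resolution of the real rig; no sub-sample interpolation). Per sample:

1. **Reference subtraction**: OB minus the average of left PirC, right
   PirC, and LEC/vHip — cancels common-mode artifacts exactly, causally.
2. **Causal band-pass**: 4th-order Butterworth, 30–110 Hz, implemented as
   an SOS state machine whose one-sample `step` and batch `process` are
   bit-identical (verified). This filter *has* group delay — the
   offline/online contrast (zero-phase vs causal) is asserted in the tests.
3. **Adaptive threshold**: the rig's per-animal "fine-tuned adaptive
   threshold" procedure is unreported, so it is implemented operationally:
   exponentially forgotten mean m of |y| and mean absolute deviation d
   (forgetting time = `threshold_window_s`), threshold = m + k·d. During
   the first window the statistics accumulate as exact cumulative averages
   (unbiased the moment warm-up ends) and the threshold is +∞ (no
   triggers). The per-animal tuning step is reproduced by
   `calibrate_threshold_k`, which bisects k to hit a requested trigger rate
   on a baseline segment; at the stock k = 3 the threshold sits ≈2.3 σ and
   triggers freely on background, so burst-selective operation uses a
   calibrated k (≈6 under default study conditions).
4. **Gating and playback**: a supra-threshold sample opens a gate and is
   the trigger timestamp. While gated, the stimulus is the filtered signal
   (negated for anti-phase) passed through a first-order RC high-pass
   (τ = 0.25 s, bilinear discretization — preserves the analytic time
   constant; gain > 0.999 and < 0.8° phase lead at 50 Hz), with RC state
   reset at gate open so the waveform is exactly zero outside gates. The
   threshold is frozen during gates (the stimulus must not inflate its own
   detection statistics). The gate closes after `release_hold_s` (25 ms ≈
   one gamma cycle — an early-release rule chosen here; only the 300 ms
   cap is externally prescribed) of continuous sub-threshold signal, or at
   300 ms, whichever comes first. An optional refractory period follows.

Polarity anti-symmetry is exact to the bit: negation commutes with every
linear stage in IEEE arithmetic, and triggers/gates depend only on |y|.

Stimulus amplitude stays in filtered-signal units; the mapping to injected
current (isolator gain, charge limits) is hardware-specific and out of
scope.

## Evaluation (`evaluate`)

**Detection scoring.** Truth bursts are merged where they overlap; matching
is greedy by maximal temporal overlap, one-to-one, with any overlap
counting as a match. Onset error is signed (detected − truth).

**Phase fidelity.** Analytic-signal phase difference between stimulus and
reference within gates, excluding 12 ms at each gate edge (Hilbert edge
effects from the zero samples outside gates); circular mean and resultant.

**Behavioural statistics.** Sucrose preference = 100 × sucrose/(sucrose +
water). Pearson r with two-sided p from the t distribution on n − 2 df
(via `scipy.stats.pearsonr`).

**Virtual experiment.** Each virtual subject contributes a pre/post pair
of synthetic recordings sharing one seed (a paired design: the same gamma
generator, with post-intervention burst amplitude scaled by a per-subject
suppression factor drawn from U(0.1, 0.9)); gamma power is the mean
squared 30–80 Hz RMS on a PirC channel, and sucrose preference is an
affine function of the true suppression plus Gaussian noise (SD 5 points).
Cohort conditions (40 s, 0.6 bursts/s, artifact-free) keep measurement
noise small relative to the suppression effect. The driver demonstrates
recovery of a positive power-change/preference correlation; it makes no
claim of matching any in-vivo effect size.

## Numerical choices and degenerate inputs

- Filters are designed as second-order sections throughout; the 8th-order
  zero-phase band-pass is numerically stable at 1250 Hz where a
  transfer-function realization would not be.
- Resampling is polyphase with rational factors (never sample dropping);
  upsampling is refused.
- File I/O quantizes to little-endian int16 with explicit gain; overflow
  raises rather than clipping silently. Round trips are bit-exact for
  amplitudes on the gain grid.
- Times are seconds, 0-based from recording start, everywhere.
- Degenerate cases raise typed errors: zero pre-power in `power_change`,
  all-zero inputs to `phase_lag`, zero-SD baselines without a floor,
  empty reference sets, empty awake masks, zero total fluid intake.

## Problem sizes

Test and acceptance runs use 60 s recordings at 1250 Hz (detection
benchmark, 100 seeds), one 120 s recording for the closed-loop scenario,
100 × 60 s noise pairs at 250 Hz for coherence nulls, and 500 × n = 200
cohorts for the correlation statistics. These sizes give the Monte-Carlo
margins stated in the tests (e.g. binomial SE ≈ 1% on the 95% bands) while
keeping the default suite fast.

## Known limitations

- The adaptive-threshold statistic, update rate, and tuning protocol of
  the real rig are unreported; ours is one defensible operationalization,
  and absolute trigger rates should not be compared against the rig's.
- The offline detector analyses the single broadband 30–80 Hz RMS series;
  a per-subband variant (one reading of "for that particular frequency")
  is deliberately not implemented.
- Awake-period scoring is an input mask, not computed.
- No stimulation-artifact feedback into the recorded channels: the
  simulated loop records from a synthetic signal that the stimulus cannot
  perturb, unlike real tissue.
- Detection performance quoted here is conditional on the generator's
  burst model (hann envelope, stationary pink background); structured
  in-vivo noise will lower it.
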