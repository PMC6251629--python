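# Methods

This note documents the models, estimators, parameter defaults, and
numerical choices behind `lfpkit`, and what the synthetic-data validation
does and does not establish about real recordings.

## Behavioral state model

Gamma oscillations and sharp-wave ripples occur in complementary
behavioral states, so every LFP metric is conditioned on locomotion.
Speed is estimated from 30 Hz tracking by smoothing x/y with a Gaussian
kernel of 0.5 s full width (σ = 0.125 s) and taking central finite
differences (one-sided at the boundaries).  A Gaussian rather than a
boxcar is used because, at typical tracking jitter (σ ≈ 0.2 cm), the
boxcar-smoothed derivative leaves a mean spurious speed of ~0.5 cm/s —
exactly at the rest threshold — while the Gaussian of the same width
leaves ~0.35 cm/s, keeping a stationary animal unambiguously below
threshold.

States: **run** where speed ≥ 7 cm/s, **rest** where speed < 0.5 cm/s;
intermediate speeds belong to neither state.  Maximal threshold intervals
at least 1 s long become bouts; a speed exactly at 7 cm/s counts as
running.  Each rest bout is truncated to its first 20 s — truncation
rather than exclusion keeps the data of long immobility periods (whose
tail may drift into sleep) without discarding their quiet-rest onset; the
alternative reading (dropping bouts longer than 20 s outright) would
discard most usable rest time.  The analysis window (by default the
30–60 min post-treatment interval) clips all bouts; an empty state yields
flagged-missing metrics, never zeros.

## Signal conditioning

Each state's concatenated samples are z-scored with that subset's own
mean/SD *before* filtering.  This makes power comparable across sessions
recorded days apart (electrode impedance and gain drift), at the cost of
absolute units — all spectra are in arbitrary units — and of coupling the
reported band-power ratio to total signal variance (see "Expected biases"
below).  Statistics are pooled across bouts of a state, not per bout, so
slow amplitude differences between bouts survive normalization.

Band filters are 4th-order Butterworth responses applied as |H(f)|² in
the frequency domain on reflect-padded signals (pad length three periods
of the band's low edge).  This is the exact forward–backward (filtfilt)
magnitude response with strictly zero phase; unlike time-domain filtfilt
it has no residual edge-transient asymmetry, so filtering commutes with
time reversal to machine precision and narrowband probes stay
peak-aligned (< 1° phase error at band center).  Canonical bands:
theta 5–10 Hz, low-gamma 30–60 Hz, high-gamma 65–100 Hz, ripple
100–300 Hz, and a narrower 30–55 Hz low-gamma band used only for
phase-amplitude coupling.  Line noise is removed by zero-phase IIR
notches at 60 and 180 Hz with Q = 30 (bandwidth 2 Hz at 60 Hz; a tone
10 Hz away is attenuated < 1 dB).

Envelope and phase come from the Hilbert analytic signal; the first and
last 100 ms of every filtered bout are flagged edge-invalid and excluded
by all consumers.

## Multitaper spectra

PSDs use K = 5 DPSS tapers with time–bandwidth NW = (K+1)/2 = 3
(the standard K = 2NW − 1 family), giving a spectral concentration
half-bandwidth W = NW/T = 1.5 Hz on the default 2-s window.  Windows
overlap 50% within a bout and never span bout seams; bouts of 1–2 s are
analyzed whole with tapers re-fit to their length and interpolated onto
the 0.5 Hz grid by zero-padding.  Averages over tapers and windows are
duration-weighted.  The estimator is calibrated as a density: the
spectrum integrates to the signal variance (Parseval), and a sinusoid of
amplitude A integrates to A²/2 over its band.  Spectra are smoothed with
a centered moving average of 1 Hz (odd bin count, reflective edges,
area-preserving) before the peak in each band is read off; ties resolve
to the lowest frequency.  The headline scalar is the *peak* smoothed band
power; band means are recoverable from the returned spectrum.

## Theta–gamma coupling

The modulation index bins the low-gamma (30–55 Hz) envelope by theta
phase into N = 18 bins of 20°, normalizes the mean-envelope-per-bin to a
distribution P, and reports MI = (log N − H(P))/log N with natural-log
entropy — 0 for phase-independent amplitude, 1 when all amplitude sits in
one bin.  Phase 0 is the positive peak of the theta-filtered trace.
A closed-form check: for an envelope proportional to 1 + cos(φ − π/2),
integrating the profile over the 18 bins gives MI = 0.1045798 with
preferred phase π/2 exactly; the estimator reproduces this on dense
uniform phases.

Significance uses circular time-shift surrogates: the envelope is rolled
by a uniform random offset of at least one theta cycle (estimated from
the mean unwrapped phase increment), MI is recomputed 200 times, and the
95th percentile is the per-session floor.  Time-shift surrogates preserve
both marginals and all within-signal autocorrelation, but they are blind
to coupling when the slow oscillation has a perfectly constant frequency
(a shift is then just a phase offset, which MI ignores); they are valid
precisely because real — and simulated — theta drifts in frequency.

## Coherence and phase lag

Coherence uses the same multitaper windows: auto- and cross-spectra are
averaged over tapers and windows first, then |S_xy|/√(S_xx S_yy) is
formed (at least two windows are required; fewer makes magnitude
coherence identically 1).  The summary scalar is the mean over 30–60 Hz.
With ~60 windows × 5 tapers the independent-noise bias floor is ≈ 0.05–0.1,
comfortably below physiological in-band values.

High coherence alone cannot distinguish lagged inter-areal coordination
from volume conduction; the phase-lag analysis disambiguates.  Both
channels are band-filtered, Hilbert phases are differenced and wrapped,
and the samples are decimated to one per period of the band's *low* edge
(33 ms at 30 Hz) — the band's decorrelation time — before circular
statistics, because neighboring samples are strongly serially dependent
and would otherwise inflate the v-test.  The v-test for concentration at
a known direction μ uses V = Σ cos(θᵢ − μ), u = V√(2/n), with one-tailed
normal p; tests are run against both 0 and 2π (numerically identical
targets, reported separately for parity with the field's convention of
quoting both).  A 5-ms delay in a 45 Hz shared component maps to a mean
phase difference of 2π·45·0.005 ≈ 1.41 rad, which the estimator recovers
within 0.1 rad.

## Ripple detection

On the z-scored rest signal, per bout: 60/180 Hz notch → zero-phase FIR
band-pass 100–300 Hz of order 69 (71 taps, Hamming design) → Hilbert
envelope → centered 50-ms moving average.  The detection threshold,
envelope mean + 3 SD, is computed once over *all* analyzed rest samples
(pooled, not per bout) — short bouts would otherwise yield unstable
thresholds — and at least 10 s of rest is required.  Supra-threshold
excursions longer than 30 ms become candidates; candidates whose onset
falls within 200 ms of the previous accepted event's *offset* are
excluded (the offset-to-onset reading of the exclusion rule; onset-to-
onset differs only for long events), and candidates overlapping the
100-ms bout-edge margins are dropped with a log entry.  Event amplitude
is the peak smoothed-envelope height in SD units above the mean, making
amplitudes comparable across sessions; event rate is count over analyzed
rest seconds.  Detection count is monotonically non-increasing in the
threshold, and accepted outputs always satisfy the spacing rule.

## Unit classification

Putative pyramidal cells: peak-to-valley spike width > 300 µs, baseline
rate < 5 Hz, and an autocorrelogram (1-ms bins to ±50 ms, refractory bins
below 1.5 ms excluded) whose global peak lies at ≤ 10 ms (bursting).
Putative interneurons: width ≤ 300 µs and rate ≥ 5 Hz.  Anything else —
including units with < 50 baseline spikes — is unclassified.  The
classification is deterministic and invariant to waveform scaling.

## The session simulator

The simulator emulates the statistical structure the pipeline assumes,
with exact ground truth:

* **Locomotion** — alternating run/rest bouts with exponential dwell
  (means 8 s run, 10 s rest; switch rates 0.125 and 0.1 s⁻¹), a 2-s
  minimum dwell so bouts are resolvable under 0.5-s velocity smoothing,
  run speed 10 cm/s with slowly wandering heading (smoothly steered away
  from the arena walls rather than reflected, so the smoothed speed never
  dips through the run threshold mid-bout), rest jitter 0.1 cm/s.
* **Hippocampal LFP** (1 kHz) — 1/f-amplitude background (SD 1, flat
  below 1 Hz); theta at 7 Hz with slow frequency drift (SD 0.4 Hz below
  0.2 Hz) and state-gated amplitude (1.0 run / 0.3 rest); low-gamma at
  42 Hz with envelope A(t) = a·g·(1 − κ/2 + (κ/2)cos(θ(t) − φ₀)),
  defaults a = 0.3, κ = 0.5, φ₀ = π/2; high-gamma at 80 Hz (0.15);
  60/180 Hz line noise (0.1); rest-only ripple bursts.  The theta drift
  matters: without it the gamma envelope would be strictly periodic and
  shift surrogates could never decohere it from theta phase.
* **Ripples** — Poisson centers (default 0.3 Hz) inside rest bouts with a
  0.15-s margin and a dead time of 200 ms + duration (thinning removes
  ≈ rate × 0.26 of draws), each a Gaussian-windowed 150 Hz burst with
  σ_t = duration/4 (60 ms default) and peak amplitude 6 × the rest-state
  ripple-band background SD.  The σ_t = duration/4 choice makes a 6-SD
  burst survive the detector's 50-ms smoothing with a supra-threshold
  width comfortably above 30 ms (smoothed peak ≈ 0.75 of raw; crossing
  width ≈ 50 ms at a ≈ 1.9 SD effective threshold).
* **Prefrontal channel** — the low-gamma component delayed by 5 ms plus
  independent 1/f background and shared line noise.
* **Condition pairs** — vehicle and treatment share the locomotion seed
  (within-animal design) and draw noise independently; only the gamma
  gain g and the ripple rate differ.  Ground truth includes the exact
  oscillator theta phase, so coupling recovery can be scored without
  re-estimation.

Determinism: all randomness flows from one `SeedSequence`; identical
seeds give bit-identical signals, and identical configs + seeds give
byte-identical result JSON.

### What the synthetic validation does not show

The generator's oscillations are narrowband tones with analytic
envelopes, its background is stationary 1/f noise, and its ripples are
stereotyped bursts.  Real recordings add non-stationary artifacts
(movement, chewing, electrical transients), asymmetric theta waveforms
(which bias Hilbert phase), ripple-frequency variability, and epileptiform
events that a 3-SD envelope detector can confuse with ripples.  Passing
tests therefore establish estimator correctness and calibration, not
robustness to those contaminants; no artifact-rejection stage is included
because none is part of the modeled workflow.

### Expected biases under z-scoring

Because each state is normalized by its total SD, adding band-limited
power changes the denominator: a gamma amplitude gain g is recovered as a
power ratio g²/(1 + (g² − 1)·f), where f is the gamma share of total
variance (~3% at defaults), i.e. ≈ 2.17 rather than 2.25 at g = 1.5.
This is a property of the normalization, not an estimator error, and it
applies equally to real data analyzed this way.

## Problem sizes and defaults in the reproduction script

`scripts/acceptance.py` uses 1800-s sessions (one 30-min analysis window)
for condition pairs, chosen so each arm holds on the order of 200–300
ripple events and the rate-ratio estimate carries only a few percent of
Poisson error; shorter checks (120–130 s) suffice for spectral
calibration and detector operating points.  All sub-seeds derive from the
single `--seed` argument.

## Known limitations

* EDF/NWB import is out of scope; the native formats are float32 + JSON
  sidecar, CSV, and JSON.
* The phase-lag stage estimates phase via the analytic signal of the
  band-filtered traces rather than wavelet convolution; for narrow bands
  the two agree closely, but cycle-by-cycle phase estimates near envelope
  zeros are noisy in both.
* Group-level inferential statistics are deliberately absent; the
  comparison layer stops at per-pair effect sizes.
* The spectral smoothing kernel (1 Hz boxcar) and windowing scheme are
  package defaults; peak band powers depend mildly on them.
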