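# Methods

`optopace` implements the quantitative analysis used in intravital cardiac
optogenetics experiments: classifying heartbeats as laser-driven or
autonomous from the ECG, measuring how pacing deforms the ECG waveform,
tracking vessel diameter responses to opto-stimulation in brightfield
video, reconstructing motion-frozen frames from line-scanned fluorescence
microscopy of the beating heart, and quantifying pacing-locked Ca²⁺
transients. Because such recordings are rarely deposited, the package ships
synthetic-data generators whose ground truth is analytic; every analysis
stage is validated against them.

## ECG analysis

**Preprocessing.** The raw ECG is resampled to a uniform grid (linear
interpolation), lowpass filtered, optionally inverted, shifted to median 0
and scaled to maximum absolute amplitude 1. The filter is a 4th-order
Butterworth with a 100 Hz passband applied forward–backward
(`sosfiltfilt`), so it is zero-phase: interval measurements are not biased
by filter delay. The filter family and order are implementation choices;
only the passband is a protocol constant.

**Peak detection.** R peaks are local maxima above a height threshold
(default 0.4 normalized units) separated by at least 50 ms; both defaults
are exposed in configuration because mouse ECG amplitudes and heart rates
vary. P waves are the maximum in a window from 100 ms to 10 ms before each
R peak; the 10 ms guard keeps the QRS upstroke out of the window. A P wave
is reported missing when the window's intensity range is below 0.1
normalized units (no discernible deflection) or the window leaves the
trace. Manual curation is supported as a file round-trip: detected peak
times export to a one-column CSV, can be edited, and re-import.

**Beat classification.** A beat is *unstimulated* if its R peak precedes
the first laser pulse; *stimulated* if, under ventricular pacing, the R
peak falls 10–38 ms (inclusive) after the nearest preceding pulse rising
edge, or, under sinoatrial-node pacing, the P peak falls 38–52 ms
(inclusive) after the nearest preceding falling edge; all other post-onset
beats are *excluded*. Each pulse can capture at most one beat (the
earliest); later beats matching the same pulse are excluded. Window
comparisons carry a 1 ns tolerance so beats constructed exactly on a
boundary are classified inclusively regardless of float rounding.

**Intervals.** R-wave duration is the span between the zero crossings
flanking the R peak, each located by linear interpolation between the
bracketing samples; the PR interval runs from the P peak to the first zero
crossing of the QRS complex — the last negative-to-positive crossing before
the R peak. Both searches are bounded (default 60 ms) and report missing
when no crossing exists. These definitions require the median-zero
normalization above, which is why `measure_intervals` expects a
preprocessed trace.

**Statistics.** Group comparisons use a two-sample Mann–Whitney U computed
from midranks. For tie-free samples with n ≤ 20 total, the p-value comes
from the exact permutation distribution of U (dynamic programme over the
standard two-index recurrence); otherwise from the normal approximation
with tie correction and a 0.5 continuity correction. At 5 vs 5 the lattice
step of the discrete U distribution limits the approximation to roughly
±0.02 of the exact two-sided p; the exact branch is used automatically at
those sizes.

## Vessel videometry

**Stabilization.** Each frame is translated by the integer shift (default
search ±20 px) that maximizes Pearson correlation with the first frame,
computed over the complement of an optional exclusion rectangle — the area
lit by the stimulation laser, which would otherwise anchor registration to
the beam instead of the tissue. All masked correlation sums over candidate
shifts are obtained exactly from three FFT cross-correlations, so the
result is identical to exhaustive search but fast. Shifts use wrap-around
(circular) semantics; ties resolve toward the smallest shift so identical
frames register at (0, 0). Sub-pixel registration is deliberately not
attempted: wall positions are already sub-pixel via the profile fit.

**Profiles.** Intensity is sampled by bilinear interpolation along a
user-specified chord across the vessel at half-pixel steps, and at each
position averaged over a perpendicular band of total width 28.05 µm
(sample count = band width / pixel size rounded to the nearest odd
integer; 51 samples at 0.55 µm/px). Band averaging across the vessel axis
suppresses speckle without blurring the cross-vessel edge profile.

**Wall detection.** The two most *prominent* local maxima of the profile
are taken as the sidewalls — prominence rather than raw height resists
bright lumen glare — and each is refined by a least-squares quadratic fit
over ±2 profile samples (5 points), giving sub-sample position and
intensity. The 5-point window was chosen over the minimal 3-point one
because, at half-pixel profile steps, the 3-point second difference is
dominated by noise; on noiseless Gaussian ridges both windows agree with a
dense-grid argmax to well under 0.1 µm. Frames where two walls cannot be
found carry missing values; more than 50% failures abort the series.

**Response metrics.** The width series is smoothed with a centered running
average (default 5 frames, missing values skipped). MIN is the minimum
smoothed width in the first 10 s after laser activation, MAX the maximum
during activation, and the response is `((MAX − MIN)/MIN) × 100` with
`net_change = MAX − MIN`. For constriction experiments the roles swap
(baseline = early maximum, extreme = minimum during activation) via a
`direction` flag, since the formula as printed describes dilation. Group
comparisons use Welch two-sample t-tests with step-down Šidák (Holm–Šidák)
adjustment: sort p ascending, `adj_i = max_{j≤i} [1 − (1 − p_j)^(m−j+1)]`,
clipped to 1.

## Gated reconstruction and pacing coupling

Cardiac phase of an image line acquired at time t is
`(t − R_prev)/(R_next − R_prev)` for the bracketing R peaks; lines outside
the R-peak span are unassignable. Phase 0 sits at the R peak and bins are
half-open `[k/n, (k+1)/n)` with n = 10 by default (10% increments of the
cycle). Lines within a configurable fraction (default 0.3) of the
respiratory cycle, centered on the detected inspiration peak, are
rejected before binning. Each accepted line contributes to exactly one bin
at its row index; bin images are per-pixel means over contributing lines,
with empty bin-rows marked missing rather than zero. The original
reconstruction this emulates is described only as indexing lines by cycle
position; no sub-bin interpolation or volume fusion is attempted here.

Fluorescence traces are detrended with a running median (default 1 s),
and transient candidates are upward crossings of baseline + 0.2 × range
that stay above threshold for at least 20 ms — the sustained-duration
requirement is what keeps white noise from producing spurious events on
transient-free traces. Each event's onset is walked back to the foot of the
rise (last sample at/below 5% of range, then down the strict local
descent), which recovers the true onset to one sample on noiseless data.
Pulses are matched greedily in time order to the first unused onset within
200 ms of their rising edge; the coupling fraction is matched/total.

## Synthetic data

The generators produce the statistical structure the analyses assume, with
ground truth that is analytic rather than re-measured:

- **ECG**: each beat is a P (Gaussian, σ = 6 ms), QRS (Ricker wavelet) and
  T (Gaussian, σ = 15 ms, +60 ms) complex. The Ricker R-wave with
  σ = r_duration/2 has zero crossings exactly at peak ± r_duration/2 and
  negative side lobes playing the role of Q and S, so the zero-crossing
  duration definition is exact by construction; the P peak is placed so
  the commanded PR interval (P peak to QRS onset crossing) is exact.
  Autonomous beats tick at the heart rate until stimulation onset; from
  then on each laser pulse drives one beat at the commanded latency after
  its rising (ventricular) or falling (nodal) edge. Gaussian timing jitter
  (default SD 1 ms) applies to beat times and, independently, to each
  beat's R duration and PR interval; additive white Gaussian noise
  (default SD 0.02 of R amplitude) covers the trace. An optional dropout
  probability models loss of capture at high pacing rates (default 0).
- **Vessel video**: a uniform background plus a fixed smooth random
  texture (so registration has structure to lock onto) plus two vertical
  Gaussian ridges (σ = 2 µm) whose separation follows a commanded
  timecourse; per-frame integer-pixel jitter is applied by circular shift
  and recorded. Commanded step dilations ramp over ~2 s starting 0.5 s
  after laser onset — an instantaneous step exactly at laser onset would
  leave no pre-dilation width inside the MIN search window and make the
  percent-change formula degenerate.
- **Line scans**: lines acquired row-by-row at a constant line rate over a
  static spatial pattern, multiplied by `1 + depth·sin(2π·phase)` with
  phase measured from simulated R peaks at exact multiples of the cardiac
  period; companion ECG and sinusoidal respiration traces are emitted.
- **Fluorescence**: one transient `(1 − e^(−t/rise))·e^(−t/decay)` scaled
  by an amplitude begins a fixed latency after each pulse rising edge;
  overlaps sum; the baseline is constant.

Everything is drawn from one seeded NumPy generator per call: identical
spec and seed give bit-identical output.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: ECG morphology variation between animals
and electrode placements, baseline wander and movement artifacts beyond
white noise, arrhythmias other than clean capture/non-capture, vessel wall
asymmetry and curvature, out-of-plane motion in microscopy, photobleaching
and shot noise. Detection thresholds that are comfortable on this
synthetic data (R-peak height 0.4, P prominence 0.1) will need adjustment
on noisy in vivo recordings — which is why they are all configuration
parameters, with the values used echoed into each run's provenance record.

## Problem sizes and numerical choices

Test and verification workloads are sized to exercise the statistics
while staying quick: paced ECG runs use 115 autonomous + 273 driven beats
at 1 kHz (≈78 s of signal), matching the beat counts reported for the
experiment they emulate; interval-recovery checks use 200 beats; vessel
runs use 100–150 frames of 96×192 px; reconstruction checks use tens of
thousands of lines. Zero crossings and TTL edges are linearly
interpolated between samples; classification windows are closed intervals
with 1 ns slack; quadratic peak fits fall back to the sample position when
the local curvature is not concave; degenerate inputs (flat traces, empty
samples, all-dark frames) raise typed errors rather than returning
numbers.

## Known limitations

- Beat classification assumes one driven beat per pulse; competing
  autonomous beats during stimulation (fusion beats) are simply excluded.
- Registration is integer-pixel and translational only; rotation or
  non-rigid tissue deformation is out of scope.
- The respiratory gate uses a fixed fraction of the median cycle around
  the inspiration peak; it does not adapt to irregular ventilation.
- The Mann–Whitney exact branch requires tie-free data; heavily quantized
  measurements at small n fall back to the corrected normal approximation.
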