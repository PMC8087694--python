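# Methods

This note documents the models and procedures implemented in `chronoecg`,
the assumptions behind the synthetic-data generator, and the numerical
choices made where a procedure was genuinely open.

## Recording model and units

All analysis operates on fixed 10,000-sample *sweeps*: 10 s of mouse
telemetry at 1 kHz, or ~78 s / ~39 s of human ECG at 128 / 256 Hz.
Mouse recordings arrive as pre-cut sweeps on a 5-min cadence alongside
per-bin locomotor-activity counts and body temperature; human recordings
are continuous (EDF) and are segmented into contiguous sweeps, dropping a
trailing partial window.  Conventions throughout: samples in mV, sampling
rate in Hz, timestamps in seconds from the recording start, intervals in
ms, circadian times in hours; sample indices are 0-based with half-open
windows.  Zeitgeber time (ZT, hours after lights-on) is derived from the
schedule's lights-on hour, so both ZT and clock time are available from
one stored time base.

EDF files are read through `mne`; because no EDF writer is available in
the supported environment, a minimal 16-bit single-channel EDF writer
(1-s data records, physical/digital scaling from the data range) is
included for round-trip testing and data exchange.

## Beat detection and quality control

R waves are detected per sweep as local maxima of the baseline-referenced
rectified signal whose amplitude lies inside an operator-set window
`[lower, upper]`, separated by a refractory period (mouse 50 ms, human
300 ms — physiological upper bounds on heart rate, with the human value
wide enough that the T wave of the same beat cannot register as a
separate candidate).  Candidates are accepted greedily by decreasing
amplitude; ties break to the earlier sample.  Detection uses the
rectified signal so that inverted ectopic complexes remain visible to the
arrhythmia classifier.

The default amplitude window is derived per sweep from the 99.9th
percentile of the rectified signal (essentially the R-peak level):
`lower = 0.25 × ref`, `upper = 2.5 × ref`.  The lower fraction must stay
below one third of the relative R amplitude or QC rule 1 below can never
pass; 0.25 leaves headroom for amplitude drift while excluding P and
(with the refractory) T waves.  All three settings are exposed.

Template filtering builds the sweep's mean beat waveform over a fixed
window centred on R (half-width 40 ms mouse, 250 ms human) and scores
each beat by `1 − Pearson r` against it; beats with mismatch above
θ = 0.2 are removed.  The correlation metric is scale-free and therefore
robust to slow amplitude drift; θ is exposed.  Beats whose window is
truncated by the sweep edge are excluded and counted as rejected.

A sweep is excluded from analysis when any of three rules trips:

1. mean baseline-referenced |R| amplitude of retained beats < 3 × lower
   window limit;
2. baseline variation > 1/3 × lower limit, where baseline variation is
   the robust spread (median absolute deviation × 1.4826) of the samples
   outside all beat windows;
3. template-rejection fraction > 20% of detected events.

Boundary behaviour is strict in the exclusion direction (2.9× fails,
3.1× passes; 19% passes, 25% fails).

## Fiducial delineation (species dialects)

Per beat, on a lightly smoothed trace (centred moving average, width 3
samples):

* **P peak**: maximum between the previous beat's T offset and the
  current R minus a QRS guard (12 ms mouse, 80 ms human).
* **Isoelectric level**: median of the baseline segment between the
  previous T offset and a guard before the P peak; if shorter than 5
  samples the estimate falls back to the whole pre-QRS window, and
  landmarks that depend on it are flagged when no estimate exists.
* **P offset** — mouse: the first positive deflection right of the P
  peak; human: the first crossing of the isoelectric line.
* **Q onset** — mouse: the first positive deflection left of the R peak,
  which on smooth morphology is the QRS trough (located on the raw trace;
  smoothing skews the asymmetric Q+R overlap by a sample); human: the
  departure of the Q wave from baseline, found by continuing left from
  the trough until the descent stops.
* **T peak**: extremum between R (plus a guard) and ~75% of the local RR
  — a maximum in humans, a minimum in mice (inverted T).
* **T offset** — mouse: first return to the isoelectric level after the
  T trough; human: first positive deflection after crossing the
  isoelectric level.

"Deflection" is operationalised as a *net-change* test: the first index
at which the trace, smoothed with a heavier moving average (width 7
samples mouse, 3 human), stops falling over a span of 3 (mouse) / 2
(human) samples, corrected for the smoothing delay so that on a clean
compact-support wave the returned index is exactly the wave's support
edge.  A single-sample sign test is noise-fragile: at 1 kHz with noise at
5% of the R amplitude the smoothed derivative of the P-wave limb is
comparable to the noise of the first difference, and a first-sign-change
rule stops several milliseconds early or late.  The net-change test keeps
clean-trace behaviour exact to one sample while holding the median error
under noise to ~1–2 ms (measured against generator truth in the test
suite).  "Crossing" is the first sample at or beyond the isoelectric
level; sub-sample interpolation is not applied, since all downstream
quantities are reported at sample resolution.

Intervals: RR = ΔR to the next beat in the sweep; PR segment =
Q onset − P offset (a PR *segment*; P onset is never located, so the PR
interval is not computed); QT = T offset − Q onset, with no rate
correction applied anywhere.  Note the species dialects imply slightly
different Q-onset anchors (QRS trough in the mouse vs Q-wave departure in
the human); each species' ground truth uses its own convention, so QT is
self-consistent within species and not comparable across them in
absolute terms.  An invalid landmark removes only the affected interval
for that beat; landmark-ordering violations (P < Poff ≤ Qon < R < Tpk ≤
Toff) invalidate the offending landmark.  Per-sweep parameters are the
medians over valid beats, HR = 60000 / median RR; QC-failed sweeps are
flagged excluded and never enter binning.

## Geometric HRV

Relative RR intervals, r_i = 2(RR_i − RR_{i−1})/(RR_i + RR_{i−1}), are
exactly invariant under RR → c·RR.  The summary statistic is 100 × the
median Euclidean distance of the consecutive-pair cloud (r_i, r_{i+1})
from its component-wise median.  The median-distance-from-median
aggregation is this package's concrete choice of robust spread; it is
isolated behind `geometric_hrv` so an alternative aggregation can be
swapped without touching callers.  The measure is 0 for a constant
train, moves < 5% under a single 400-ms outlier among 500 beats, and
responds monotonically to beat-to-beat jitter.

## Rhythmometry

Parameter series are z-scored per subject across the full session
(sample, n−1, SD; only QC-passing sweeps contribute) and averaged into
5-min bins.  A subject is excluded from waveform analyses when fewer than
70% of bins are nonempty.

**Cosinor.**  `Cosinor(values, times_h).fit()` performs OLS on the
harmonic regressors cos ωt, sin ωt (ω = 2π/24) and reports mesor,
amplitude, acrophase (delta-method standard errors), the zero-amplitude
F-test (2 numerator df against the intercept-only model) and the residual
variance; a permutation alternative (`p_permutation`) shuffles the
response.  Preconditions: ≥ 8 observations covering more than half the
period, where phase coverage is measured circularly (period minus the
largest phase gap).  At A/σ = 1 with n = 288 bins the delta-method
acrophase SE is (σ/A)·√(2/n)/ω ≈ 0.32 h, so roughly 88% of fits land
within 0.5 h of truth; the acceptance suite asserts the median error
≤ 0.5 h and the test suite the ≥ 80% coverage this implies.

**Watson–Williams.**  Group acrophases are compared as angles (hours ×
2π/24) with the standard F statistic, corrected by 1 + 3/(8κ̂) where κ̂
is the maximum-likelihood von Mises concentration from the pooled mean
resultant length; results are flagged unreliable below r̄ = 0.45.  A unit
test cross-checks the F-based p-value against a permutation oracle on the
same angles.

**Cross-correlogram phase delays.**  For two binned series the Pearson
correlation is computed over pairwise-complete bins at every lag within
±12 h (5-min steps); pairing a(t) with b(t+τ) makes a positive fitted
mean a delay of b.  A four-parameter Gaussian (height, mean, SD, offset)
is fitted to the correlogram, initialised at its argmax; a failed fit
falls back to the argmax lag, flagged.  Cohort inference is a one-sample
t-test of the per-subject fitted means against zero; subjects whose
correlogram has no positive peak are excluded and counted.

**Dependency curves.**  ΔX between consecutive nonempty bins (gaps skip
the pair); ΔRR is grouped into bins of width 0.25 SD (human) / 0.5 SD
(mouse) and the concurrent Δparameter averaged per bin.  The summary
slope is the regression of the raw difference pairs.  With a cohort of
10 synthetic animals the sampling SE of a true-zero slope is ~0.01–0.02,
so a strict 95% CI occasionally excludes zero for an uncoupled parameter;
the acceptance check therefore bounds the magnitude of the cohort-mean
PR slope (≤ 0.1, the same band granted the QT slope) rather than testing
a null that is true by construction.

**Profiles, detrending, heatmaps.**  Group profiles are smoothed with
LOWESS (span 0.3) with an SEM band from subject-level spread.  Slow
drift is removed by subtracting a centred moving average over 24 h; for
an even window span the endpoints carry half weights, so a whole-period
window annihilates 24-h periodic components exactly, and half-window
edges are returned absent.  RR heatmaps bin intervals into 15-min ×
1.5-ms cells folded onto the 24-h day, convert each time column to a
probability, smooth with a 2-D Gaussian kernel (SD = 5 bins, truncation
3 SD — "5 SD window" is read as kernel SD in bins) using circular padding
on the time axis and reflection on the RR axis, and renormalise the
columns.  Circularity makes the smoothed map exactly equivariant under
whole-column rotations of the day.

## Activity coupling

"Inactive" means an activity count of zero in a 5-min telemetry bin; a
"bout" is a maximal run of nonzero bins.  The at-rest circadian profile
is a 24-h constrained sine fitted to sweeps whose current and preceding
30 min of bins are all zero (the current bin is included in the criterion
because the acute effect acts within the bin).  Responses aligned to
activity cessation require the full 45-min following window to be
strictly inactive in every bin; values are deviations from the at-rest
curve at the matching phase.  Transient bouts are single-bin bouts with
> 5 min of inactivity before and > 20 min after, normalised to the
preceding rest bin; overlapping events drop the later one.  The siesta
contrast compares per-day parameter means in a 2-h siesta window against
the immediately preceding 2 h; by default the window is the 2-h span
minimising mean activity within ZT 18–24.

## Arrhythmia calling

QRS width is the extent of the contiguous region around R where the
signed deflection stays above half the R amplitude.  A beat is labeled a
ventricular premature complex (VPC) when its width exceeds 1.5 × the
template's QRS width **and** its signed R amplitude deviates from the
template's by more than 50% of the template amplitude.  The second
criterion operationalises "QRS inversion": it captures fully inverted
complexes as well as the alternate axis of bidirectional runs, while a
merely widened beat with normal amplitude and polarity is not a VPC.
Prematurity (preceding RR < 0.8 × the local median) is computed and
flagged but not required.  Maximal runs of ≥ 4 consecutive VPCs are
episodes: bidirectional VT (BVT) when the signed amplitudes alternate in
sign at every step, VT otherwise; episode duration is recorded.  A
subject showing VT on every trial of a repeated provocation is classified
susceptible.  Incidence tables are tested with the Pearson chi-square
(no continuity correction, df = 1), odds ratio alongside.

## Synthetic generator

The generator defines the study conditions used by the tests and the
acceptance script.

**Intervals.**  Per-sweep RR (ms) = M + A·cos(2π(ZT − φ)/24) +
g·activity + ε.  Mouse defaults: M = 100 ms, A = 7 ms, φ = ZT6 (RR
longest mid rest phase), activity gain g = −0.25 ms per count (movement
shortens RR), sweep-level noise SD 2 ms, beat-level jitter SD 1.5 ms.
Human defaults: M = 900 ms, A = 60 ms, φ = 22 h, jitter 25 ms.  QT and
the PR segment carry their own cosinor terms (PR: M = 15 ms, A = 1.5 ms,
acrophase 1.5 h after RR's, matching the delayed AV-nodal rhythm the
analyses are designed to detect) plus acute deviations coupled to RR *on
the standardized scale*: dev = sd·(c·z_RR + √(1−c²)·η) with c the
dimensionless coupling (QT 0.8, PR 0).  Defining c on the z-scale makes
it the exact regression slope that the z-scored dependency analysis
estimates, for any noise level; a raw-ms coupling would be divided out by
the per-parameter z-scoring and always recover ~1.  QT's own cosinor
amplitude defaults to 0: its daily rhythm is inherited entirely through
the RR coupling, which is the physiological reading.  Per-beat QT is
clamped so the T wave ends before the next beat's P wave (clamps are
counted); non-positive interval draws are resampled, and more than 1%
resampling aborts generation as unphysiological.  An optional exponential
decay of the activity effect (`activity_tau_min`) models slow relaxation
after bouts.

**Behaviour.**  Activity counts per 5-min bin follow a two-state
(moving/quiescent) Markov chain with phase-dependent transition rates:
long movement bouts with brief naps in the dark (active) phase, sparse
short bouts amid long immobility in the light phase and the siesta
window.  Quiescent bins are exactly zero — this matters because every
rest-based analysis conditions on zero-count runs.  Poisson rates: 25
counts/bin while moving at night, 8 during rest-phase bouts.  After a
light/dark shift the behavioural phase ramps toward the new schedule at a
configurable rate (default 1.5 h/day) and body temperature (24-h cosine,
peak ZT18, amplitude 0.8 °C, noise 0.08 °C) phase-locks to the
re-entraining component.

**Waveforms.**  Each wave (P, Q, R, S, T) is a raised-cosine (Hann) bump
with compact support.  Unlike a Gaussian, a Hann bump returns *exactly*
to the isoelectric line at its support edge, which makes the
offset/crossing delineation rules well-posed at single-sample precision
on clean traces — the property the oracle tests rely on.  Mouse defaults
(mV / half-width ms): P 0.15/6, Q −0.2/3 centred 4 ms before R, R 1.0/4,
T −0.3/10 (inverted); human: P 0.15/50, Q −0.15/20, R 1.2/25, S −0.2/15,
T 0.35/80 (upright).  The Q bump overlaps the R upstroke so the QRS is
one complex; the Q-trough offset is located numerically once per profile.
Landmarks are snapped to the sample grid before bump placement, so
annotated interval differences reproduce the true intervals exactly at
the rendering rate.  White noise and a slow sinusoidal baseline wander
are added last.  The reference noise condition for the oracle suites is
noise SD = 5% of the R amplitude with 0.03 mV wander.  Optional
per-sweep artifacts (a large stationary noise burst, probability 2% in
the acceptance condition) and missing sweeps emulate telemetry dropouts;
artifact sweeps are expected to fail QC regardless of time of day.

**Arrhythmia.**  Injected runs shorten RR by 0.6 (tachycardia), widen
the QRS bumps by 2 and render no P or T; VT runs keep polarity −1, BVT
runs alternate −1.0 / +0.35 (alternating sign, grossly deviating from
the template in both phases).  Runs of ≥ 4 beats receive an episode
annotation with kind and duration; shorter runs leave labeled VPCs only.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real PQRST morphology variation between and
within subjects (notched P waves, biphasic T waves, the human T-offset
morphology dependence that made QT unmeasurable for some individuals),
electrode motion artifacts with beat-like shapes, respiratory sinus
arrhythmia and other structured HRV, ectopy other than the stylised
VT/BVT runs, circadian modulation of HRV itself (beat jitter is
homoscedastic in ms, so relative variability is mildly higher at short
RR), and EEG/PSG context channels.  Oracle-recovery results bound
algorithmic error under the stated noise model, not delineation accuracy
on clinical recordings.

## Problem sizes

The test suite and `scripts/acceptance.py` use: a 5-day mouse recording
(1440 sweeps, ~144,000 beats) at 1 kHz for the fiducial and QC suites; a
10-animal cohort of 5-day sweep-level simulations for the dependency
slopes; 1000 white-noise simulations (96 bins each) for the cosinor
type-I calibration and 200 (288 bins) for acrophase recovery; 12
synthetic subjects for phase-delay power; ~30 sweeps for arrhythmia
sensitivity plus an arrhythmia-free recording for the false-positive
contract.  These sizes reproduce the telemetry study's scale while
keeping a full run to a few minutes on one CPU.

## Known limitations

* The human delineation operates at 128 Hz, where one sample is 7.8 ms;
  interval errors of 1–2 samples (8–16 ms) are the quantization floor,
  not algorithmic bias.
* The human T-offset rule implements only the stated
  crossing-then-deflection branch; low-confidence T offsets are flagged
  rather than re-derived from alternative morphologies.
* The Watson–Williams test assumes comparable concentration across
  groups; the implementation flags low-resultant data but does not switch
  to a nonparametric alternative automatically.
* `siesta_contrast` returns per-day paired means; cohort-level inference
  is left to standard statistics packages.
* The EDF writer covers the single-channel, integer-rate case needed for
  round trips; it is not a general EDF+ exporter.
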