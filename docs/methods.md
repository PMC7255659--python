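# Methods

`epicollar` implements and evaluates a seizure-detection pipeline for a
collar-mounted, 3-axis accelerometer worn by dogs with idiopathic
epilepsy, together with a synthetic-data generator that stands in for
the field recordings (which were never deposited).  This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic experiments do and do not show.

## The detection pipeline

**Device model.** The simulated device samples specific force at
100 Hz on three axes with 8-bit resolution over ±8 g (quantization step
0.0625 g).  The sample rate and bit depth are device facts; the ±8 g
range is a typical MEMS full scale chosen here, exposed as
`SimulationConfig.adc_range_g`.

**Orientation normalization** (`orientation.orient_to_dog_frame`).
A collar rotates freely about the neck, so sensor axes are arbitrary.
The one usable physical constraint is gravity: averaged over seconds,
the sensed specific force points along the dog's ventral axis.  Per
4-second block the gravity direction is estimated by zero-phase
2nd-order Butterworth low-pass filtering (cutoff 0.3 Hz, standard for
actigraphy gravity separation) and mapped onto `(0, 0, −1)` by the
minimal rotation.  Rotations are interpolated between block centres by
normalized quaternion interpolation evaluated at 0.5-s sub-blocks;
because realistic collar drift moves adjacent block rotations by far
less than a degree, this is indistinguishable from per-sample spherical
interpolation and much cheaper on week-long traces.  Every applied
matrix is exactly orthogonal, so per-sample norms are preserved to
floating-point precision (a tested invariant).

The residual degree of freedom — rotation about gravity — is
unobservable from a resting accelerometer.  Since the collar constrains
the nuisance rotation to the cranial (neck) axis, gravity re-alignment
alone removes it; this is what the rotation-robustness experiment
verifies end to end.  An optional heuristic (`resolve_yaw=True`) aligns
the dominant horizontal dynamic-energy axis with the cranial axis for
other mounting geometries; it is off by default because it is unstable
on quiet blocks and unnecessary for collar geometry.

Blocks whose mean specific-force norm falls below 0.3 g (free fall,
zeroed non-collection samples) are flagged degenerate and inherit the
previous block's rotation, with a warning.

**Features** (`features`).  Per 4-second window (non-overlapping by
default; the stride is configurable but never exceeds the window) and
per oriented axis:

* quantiles at 5, 10, 25, 50, 75, 90, 95% (linear-interpolation
  convention), computed on the raw window — they carry posture and
  sustained tonic offsets;
* band-averaged log power spectral density: Welch estimate (Hann,
  `nperseg = min(len, 256)`, 50% overlap, mean detrending), natural log
  with an additive floor ε = 10⁻¹² g²/Hz, averaged over B = 12 equal
  bands partitioning (0, 50] Hz.  An alternative `per_bin` mode keeps
  the log-PSD of every non-DC Welch bin;
* normalized spectral entropy: Shannon entropy of the PSD over non-DC
  bins as a probability mass, divided by log(#bins), so it lies in
  [0, 1]; a zero-power window is defined as 1.0 (maximally
  uninformative) rather than an error.

The layout (per axis: 7 quantiles, B spectral values, entropy; axes
cranial, lateral, ventral) is versioned, and a trained model refuses
feature matrices whose layout version differs.

**Classifier** (`detector.SeizureDetector`).  A random forest
(200 trees, unlimited depth, balanced class weights, fixed recorded
seed) maps each window's feature vector to a seizure probability.
Windows overlapping a non-collection interval are never scored: they
carry NaN, not 0.  Training labels mark a window positive when it
overlaps a generalized seizure by at least half the window.  Because
seizure windows are a tiny minority of a months-long recording,
training optionally subsamples each record's negative windows
(deterministically; 30 000 per record in the study pipeline) while
keeping every positive.

**Post-processing.**  The probability series is smoothed by a centred
5-point median filter (edges reflected; NaNs excluded from each
neighbourhood, an all-NaN neighbourhood stays NaN), which suppresses
isolated single-window spikes by construction.  Maximal runs of
filtered values strictly above the threshold (default 0.5) become
detection events; runs separated by at most one sub-threshold window
(8 s at the default stride) are merged, absorbing brief clonic pauses.
"Above" is read as strict inequality; merging consecutive
supra-threshold windows into one event is an interpretation choice —
per-window counting would inflate both TP multiplicity (harmless, a
seizure counts once) and FP counts.

**Threshold individualization.**  After phase 1, each dog's threshold
is adjusted by codifying the study's manual rule: a dog whose phase-1
false-detection rate exceeds `fp_many_per_day` (0.2/day) has its
threshold raised to `margin` (0.95) × the minimum peak filtered
probability over its phase-1 true positives, never below the 0.5
default; a dog with many misses (more than 3, or over half its
evaluable seizures) and an acceptable false-positive rate has it
lowered to 0.95 × the maximum peak over its missed seizures, floored at
`t_min` = 0.05; otherwise it is unchanged.  All policy constants are
configuration, since the original adjustments were manual judgements.

**Evaluation** (`evaluation`).  A seizure overlapping any
non-collection interval is excluded before scoring.  A kept seizure is
a true positive iff at least one detection overlaps it or lies within
60 s (the matching tolerance is a choice; diary and device clocks were
never aligned more precisely than minutes).  However many detections
land on one seizure, it counts once; every detection matching no
seizure is one false positive.  Sensitivity is TP / evaluable with a
Wald 95% interval (p ± 1.96·√(p(1−p)/n), clipped to [0, 100], one
decimal) — Wald, because it reproduces the printed field-study
intervals exactly; Wilson is available.  The false-detection-rate
denominator subtracts one day per whole 24-hour unit within each
contiguous gap (⌊gap/24 h⌋; a `total` rule dividing summed gap time by
24 h is available).  Cohort results report both pooled sensitivity
(summed counts) and the mean of per-dog sensitivities (dogs with no
evaluable seizures excluded) — with heterogeneous per-dog seizure
counts these genuinely differ, and both are meaningful.  The pooled
binomial interval ignores within-dog clustering of seizures; it is the
field study's own convention and should be read with that caveat.

**QoL scoring.**  Fifteen items on a 1–5 bipolar scale; items whose
favourable end is 1 are reverse-coded (v → 6 − v) so high is always
good, then summed to a 15–75 composite.  The real questionnaire's
reverse-coding key is not public; the package fixes a declared
synthetic set (items 1, 4, 6, 9, 12, zero-based).  Paired composites
are compared with a paired t test (identical sheets give t = 0, p = 1;
a zero-variance nonzero shift is flagged degenerate rather than
assigned a fabricated statistic), and changes are correlated with
Pearson's r.

## The synthetic-data generator

The generator emulates the study's data-generating process:
two ~3-month phases per dog (duration configurable; the reference
experiments use shorter phases, below), seizure times as a homogeneous
Poisson process, charging gaps on a fixed schedule recorded as a wear
mask (samples zeroed, never silently missing), everyday activity bouts
(walking, play, shaking, scratching — the last three rhythmic at
3–6 Hz, the classic false-alarm generators), slow collar roll as an
angular random walk about the neck axis (0.3 rad/√h by default) with a
uniformly random initial angle, gravity, Gaussian sensor noise
(0.02 g), and 8-bit quantization.  All randomness derives from SHA-256
substreams of one root seed, per dog and per phase, so any dog-phase
regenerates bit-identically in isolation.

**The seizure waveform is a phenomenological stand-in.**  No
quantitative kinematic description of canine generalized tonic-clonic
movement exists for this device, so the waveform is built from the
clinical phenomenology: a tonic segment (5–20 s; sustained 0.5–1.5 g
offset on the cranial axis plus broadband tremor) followed by a clonic
segment (decaying sinusoid at 1–4 Hz, initial amplitude 1.5–3 g,
decaying to ~30%, randomly oriented in the cranial–lateral plane),
total duration 30–120 s.  Every parameter is config-exposed and should
be treated as a modelling assumption, not a measurement.

Consequently, passing synthetic tests shows that the pipeline is
*correct* (each stage does what it claims, verified against independent
oracles) and that it is *capable* (when seizure and activity
distributions separate, it approaches perfect accuracy), but it cannot
certify field sensitivity on real dogs, where the study itself measured
only ~19–22%: real seizure kinematics, real activity confounds, and
diary noise are outside the generator.

## Reference experiments (`experiments.py`)

Problem sizes are the package's own desk-scale choices.

* **Separable cohort**: 5 dogs, two 7-day phases each, seizures at
  1/day with high-amplitude clonus (2.5–3.5 g) against 0.5 g
  activities, charging gaps every 3 days.  The full two-phase pipeline
  (train on 2 dogs, phase-1 at 0.5, individualize, phase-2) should
  recover essentially all seizures with ≈0 false detections/day,
  mirroring the best-monitored field dogs.
* **Rotation robustness**: per-window detection agreement between a
  2.4-h trace and the same trace under a fixed 1.2-rad collar roll;
  the orientation stage should make this ≥95%.
* **Generalization gap**: 7 dogs, 0.25-day phase-1 each, heterogeneous
  phenotypes — two training dogs share a strong slow phenotype, five
  held-out dogs have weak tonic components and clonic amplitudes
  overlapping everyday activity.  Training on the 2 dogs is compared
  with leave-one-dog-out training over the cohort on held-out pooled
  sensitivity; the 2-dog pool generalizes strictly worse, reenacting
  the direction of the field study's central limitation.

## Numerical choices and degenerate inputs

* Samples are float32 throughout the heavy path; feature extraction and
  statistics run in the input precision (differences to a float64
  reference are orders below the 0.0625 g ADC step).
* Quantization is mid-tread and idempotent; values clip at ±full scale.
* Empty traces, single-class training sets, zero-variance correlation
  inputs, zero evaluable seizures, and non-positive corrected phase
  lengths raise errors rather than returning silent defaults.
* Collar-roll transcendentals are computed on a 1-s grid and expanded
  piecewise-linearly (drift ≈10⁻³ rad/s makes the error negligible
  against sensor noise).
* Intervals are half-open `[start, end)` with UTC timestamps
  everywhere; a seizure beginning exactly when a gap ends is kept.

## Known limitations

* The simulator does not model focal-seizure kinematics, EEG ground
  truth, battery depletion, diary mis-timing, or owner compliance
  variation; wear gaps are deterministic.
* The yaw heuristic is untested on non-collar geometries.
* Pooled confidence intervals ignore seizure clustering within dog.
* The mixed-effects covariate models of the original analysis are out
  of scope; the package provides the simple phase comparison, paired
  t test, and Pearson correlation instead.
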