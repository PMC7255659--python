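# epicollar

Seizure detection from a collar-mounted accelerometer for dogs with
idiopathic epilepsy — simulation, detection, and field-study-style
evaluation in one package.

Most epileptic dogs keep having seizures despite treatment, and owners
worry most about seizures that happen while the dog is alone.  A
collar-mounted 3-axis accelerometer (100 Hz, 8-bit) can in principle
detect the violent rhythmic movement of a generalized tonic-clonic
seizure.  `epicollar` implements that detection chain and the
evaluation arithmetic used to judge it in the field, plus a synthetic
cohort generator so the whole pipeline is testable without any
recordings:

1. **Orientation**: sensor-frame acceleration is rotated into the dog's
   anatomical frame using the collar's physical constraint — the
   low-passed gravity vector is mapped onto the ventral axis per
   4-second block (zero-phase Butterworth, 0.3 Hz cutoff), removing the
   collar-roll nuisance rotation.
2. **Features**: per 4-s window and axis, the 5/10/25/50/75/90/95%
   quantiles, the band-averaged log power spectral density (Welch, 12
   bands to 50 Hz), and the normalized spectral entropy
   H = −Σ pᵢ log pᵢ / log N of the PSD.
3. **Detection**: a random forest (200 trees, balanced class weights)
   emits a per-window seizure probability p̂ᵗ; the series is smoothed
   with a 5-point median filter and maximal runs with filtered value
   > 0.5 become detection events.
4. **Individualization**: after phase 1, false-alarm-prone dogs get the
   threshold raised to just below their weakest true positive, and
   miss-prone dogs get it lowered toward their strongest missed
   seizure.
5. **Evaluation**: seizures during non-collection are excluded;
   sensitivity = TP/evaluable with a Wald 95% CI
   (p̂ ± 1.96·√(p̂(1−p̂)/n)); false detections per day use a denominator
   that drops one day per whole 24-h non-collection period.  Quality-
   of-life sheets (15 items, 1–5, reverse-coded items standardized) are
   summed to a 15–75 composite and compared with a paired t test.

The package is organised statsmodels-style: `SeizureDetector.fit()`
returns a `SeizureDetectorResults` (predict/detect/summary), and
`TwoPhaseStudy(...).fit()` returns a `StudyResults` carrying per-dog
and pooled tables, thresholds, QoL statistics, a `summary()` and a
performance plot.

## Worked example

```python
from epicollar import SimulationConfig, TwoPhaseStudy

cfg = SimulationConfig(
    seed=3,
    duration_days=0.2,            # two ~5-hour phases (demo scale)
    seizure_rate_per_day=30.0,    # frequent seizures so the demo has events
    clonic_amp_g=(2.5, 3.5),      # vigorous, well-separated clonus
    gap_schedule=(0.0, 0.0),
)
study = TwoPhaseStudy(config=cfg, n_dogs=3, train_dogs=2)
res = study.fit()
print(res.summary())
```

prints

```
Two-phase collar-accelerometer study
============================================================
Phase 1 (threshold: predefined 0.5)
  pooled sensitivity : 100.0% (95% CI [100.0%, 100.0%]) on 14/14 evaluable seizures
  mean per-dog sens. : 100.0%
  false detections   : 0 over 0.6 corrected days (mean 0.000/day)
Phase 2 (threshold: individualized)
  pooled sensitivity : 100.0% (95% CI [100.0%, 100.0%]) on 21/21 evaluable seizures
  mean per-dog sens. : 100.0%
  false detections   : 0 over 0.6 corrected days (mean 0.000/day)
Individualized thresholds:
  dog-00: 0.5000
  dog-01: 0.5000
  dog-02: 0.5000
QoL composite: 45.33 -> 54.67 (paired t = 14.00, p = 0.0051, n = 3)
```

Read: in each phase, every simulated generalized seizure was detected
(pooled sensitivity = ΣTP/Σevaluable, with its Wald interval), no false
detections occurred on the gap-corrected days, no dog met the
"numerous false positives / many misses" criteria so all thresholds
stayed at the 0.5 default, and the owners' QoL composite (15–75 scale)
rose significantly between study initiation and completion.  With
high-amplitude, well-separated seizure signatures the pipeline is
near-perfect; field accuracy on real dogs is limited by seizure
kinematics and training data, not by this machinery.

The same pipeline is scriptable from the shell:

```bash
epicollar run-study --config cfg.yaml --seed 3 --out results/
epicollar report --study-dir results/
```

(`simulate`, `train`, `detect`, `individualize`, `evaluate` expose the
individual stages; artifacts are deterministic given config + seed and
carry the config hash.)

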