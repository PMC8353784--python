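# falldetect

Online fall detection from smartphone inertial sensors, for digital-health
researchers building or evaluating fall-alert systems. The package implements
a deployable two-stage detector, its full training and calibration procedure,
a streaming event pipeline with alerting and contextual event records,
deployment evaluation metrics, and a seeded synthetic IMU generator so the
whole pipeline runs end-to-end without any protected data.

## The detector

The phone's tri-axial accelerometer (g, gravity-inclusive) and gyroscope
(rad/s) are segmented into non-overlapping 5 s windows, quality-gated
(≥ 200 samples, no gap > 200 ms) and linearly interpolated to 250 samples at
20 ms (50 Hz). Detection is two-stage:

1. **Screen** — a window is a fall candidate only if its peak acceleration
   magnitude ‖a‖ = √(ax² + ay² + az²) strictly exceeds 2 g.
2. **Classifier** — 40 windowed features (20 per sensor: magnitude moments,
   IQR, extrema, their first-difference counterparts and per-axis extrema/IQR)
   feed an elastic-net penalized logistic regression

       min (1/n) Σᵢ −[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)] + λ(α‖w‖₁ + (1−α)/2 ‖w‖₂²)

   with α = 0.6, λ = 0.015, fit by cyclic coordinate descent. The posterior
   p = σ(b + w·x) raises an **alert** above the calibrated threshold — the
   5th percentile of training-fall posteriors (0.908 in the original
   deployment), targeting 95 % training sensitivity — and marks a
   **potential fall** above 0.5.

Evaluation follows deployment conventions: greedy one-to-one alert/fall
matching, sensitivity/specificity/precision/accuracy/F1, and the false-alarm
interval in days of use per false positive. See `docs/methods.md` for the
full model description and design choices.

## Worked example

Train on synthetic windows from six participants, calibrate the alert
threshold, then stream-detect two held-out participants with planted falls,
stumbles and phone drops:

```python
import numpy as np
from falldetect.synthetic_imu import SyntheticConfig, gen_study, gen_training_windows
from falldetect.elasticnet_classifier import (
    fit, calibrate_threshold, training_set_from_windows, loso_cv)
from falldetect.detection_engine import stream_detect
from falldetect.evaluation_metrics import (
    ConfusionCounts, match_events, performance, render_report_md)

train_cfg = SyntheticConfig(n_participants=6, seed=11)
windows, groups = gen_training_windows(2000, 2000, train_cfg, seed=11)
train = training_set_from_windows(windows, groups)
model = fit(train)                      # alpha=0.6, lam=0.015
model.threshold = calibrate_threshold(model, train.X[train.y == 1])
print(f"threshold = {model.threshold:.3f}, "
      f"nonzero weights = {np.count_nonzero(model.weights)}/40")
folds, mean_auroc = loso_cv(train)
print(f"LOSO mean AUROC = {mean_auroc:.4f}")

study_cfg = SyntheticConfig(n_participants=2, days=1, hours_per_day=1.0,
                            falls_per_participant=50,
                            stumbles_per_participant=6,
                            drops_per_participant=5, seed=99)
study = gen_study(study_cfg)
tp = fp = fn = total = failed = 0
for pid, rec in study.recordings.items():
    events = stream_detect(rec, model)
    alerts = [e.t_start for e in events if e.status == "alert"]
    truth = [ev.t_label for ev in study.truth if ev.participant_id == pid]
    a, b, c = match_events(alerts, truth)
    tp, fp, fn = tp + a, fp + b, fn + c
    total += len(events); failed += sum(e.processing_failure for e in events)
counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=total - failed - tp - fp,
                         total_windows=total, recording_days=2 / 24.0,
                         n_failed=failed)
print(render_report_md(performance(counts), counts))
```

Output:

```
threshold = 0.650, nonzero weights = 18/40
LOSO mean AUROC = 0.9986
| Metric | Value |
|---|---|
| Sample size (5 s windows) | 1441 |
| True positives | 93 |
| False positives | 0 |
| False negatives | 7 |
| Sensitivity | 93.0 % |
| Precision | 100.0 % |
| F1-score | 0.964 |
...
```

The elastic net keeps 18 of 40 features; leave-one-participant-out AUROC is
near-perfect on synthetic data; 93 of the 100 planted falls are recovered
with no false alarms in the two hours streamed. (Synthetic classes are more
separable than real ones — `docs/methods.md` discusses what this does and
does not show.)

The same workflow is available from the shell:

```sh
falldetect simulate --config sim.yaml --out data/ --seed 5
falldetect train    --features features.csv --calibrate --out model.json
falldetect detect   --recording data/P00.csv --model model.json --out events.jsonl
falldetect evaluate --events events.jsonl --truth data/falls.csv --days 90 \
                    --out report.json
```

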