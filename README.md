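# apnea-st

Sleep-apnea detection from single-lead ECG, minute by minute.

Sleep apnea (SA) — repeated cessation or reduction of breathing during
sleep — leaves a signature in the ECG: apnea episodes modulate heart rate
cyclically and alter R-wave amplitude.  This package implements an
end-to-end pipeline that exploits exactly that signature, for researchers
working with per-minute-annotated ECG corpora (PhysioNet Apnea-ECG, UCDDB)
or their own recordings:

1. **Preprocessing** — Hamilton-style R-peak detection, RR-interval and
   R-amplitude extraction, median-filter artifact correction, and cubic
   resampling of each labeled minute ±2 context minutes onto two aligned
   900-point channels.
2. **Model** — a spatio-temporal classifier: a stem 1-D convolution,
   stacked blocks of convolution → max-pooling → dropout → bidirectional
   GRU, dot-product attention `a = softmax(F Bᵀ) B` over the last block's
   forward/backward stacks, and dense layers ending in a 2-way softmax.
   Layers run on a small NumPy reverse-mode autodiff engine shipped in the
   package; every layer equation also has an independent loop-level
   reference implementation used as a test oracle.
3. **Training** — mini-batch Adam on binary cross-entropy with per-epoch
   best-on-validation checkpointing, seeded end to end; minority
   oversampling and checkpoint fine-tuning for cross-dataset transfer.
4. **Diagnosis** — per-recording apnea-hypopnea index AHI = 60·N/T from the
   N predicted SA minutes out of T evaluated minutes, the clinical call
   SA iff AHI > 5, and cohort-level MAE / Pearson r against annotation-derived
   AHI.
5. **Synthetic test bed** — a generator of WFDB-format ECG with known beat
   times and planted cyclic apnea episodes, so the whole pipeline is
   testable without downloads.

See `docs/methods.md` for the model equations, parameter defaults and
design choices.

## Worked example

```python
import numpy as np
from apnea_st import (SimConfig, generate_beats, synthesize_ecg,
                      detect_r_peaks, extract_beat_series, clean_rr,
                      build_windows, evaluate_recording)

# 15 minutes of synthetic ECG with one 4-minute apnea episode
cfg = SimConfig(duration_s=900.0, apnea_intervals=((120.0, 360.0),), seed=31)
truth = generate_beats(cfg)
ecg = synthesize_ecg(truth, cfg)

peaks = detect_r_peaks(ecg)
series = clean_rr(extract_beat_series(ecg, peaks))
windows = build_windows(series, truth.minute_labels)
print(f"{len(peaks)} beats detected, {len(windows)} five-minute windows")
print("center minutes:", [w.center_minute for w in windows])
print("labels:        ", [w.label for w in windows])

result = evaluate_recording(np.array([w.label for w in windows]))
print(f"AHI = {result.ahi_pred:.2f} events/h -> diagnosis: {result.diagnosis}")
```

prints

```
1068 beats detected, 11 five-minute windows
center minutes: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12]
labels:         [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
AHI = 21.82 events/h -> diagnosis: SA
```

The detector finds every rendered beat; minutes 0–1 and 13–14 are dropped
for lacking the full ±2-minute context; the apnea episode spanning
120–360 s labels center minutes 2–5 as SA (a minute counts as SA when
events occupy strictly more than 5 s of it).  Feeding these 11 windows to a
trained model replaces the ground-truth labels with predictions, and the
same AHI arithmetic yields the recording-level diagnosis.

Each window is a `(900, 2)` array — RR intervals and R-peak amplitudes
resampled to an effective 3 Hz — which is exactly the model input:

```python
from apnea_st import ModelSpec, build_model, model_forward
from apnea_st.preprocessing import WindowSet, fit_normalization, apply_normalization

ws = WindowSet.from_windows(windows)
ws = apply_normalization(ws, *fit_normalization(ws))
model = build_model(ModelSpec().tiny(), seed=0)   # untrained at this point
print(model_forward(model, ws.X).shape)           # (11, 2) probability pairs
```

## Command line

```sh
apnea-st simulate --n 8 --out data/sim --seed 7     # synthetic WFDB cohort
apnea-st preprocess --in data/sim --out data/windows
apnea-st build --blocks 3                           # print the layer table
apnea-st train --data data/windows --out ckpt --epochs 40 --runs 10
apnea-st evaluate --weights ckpt.run0.npz --data data/windows --per-recording
```

`train --runs 10` repeats training over consecutive seeds and reports the
mean ± SD validation accuracy; `preprocess` accepts any directory of WFDB
records with per-minute A/N annotation files, so the same commands drive
the full PhysioNet benchmark once the data are downloaded.

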