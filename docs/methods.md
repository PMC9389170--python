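# Methods

## Problem and model

The package classifies one-minute segments of single-lead ECG as sleep-apnea
(SA) or normal, and aggregates the per-minute calls into a per-recording
diagnosis.  The physiological basis is that apnea episodes modulate heart
rate cyclically (the bradycardia–tachycardia pattern) and change R-wave
morphology, so the RR-interval series and the R-peak amplitude series carry
the discriminative information.

The classifier is a spatio-temporal network.  Its input is a pair of aligned
900-point channels — RR intervals (s) and R-peak amplitudes (mV) — covering
the labeled minute plus two context minutes on each side (5 min total).  The
stack is:

1. a stem 1-D convolution (128 filters, kernel 3, ReLU, same padding);
2. `n_blocks` spatio-temporal blocks, each: convolution (128 × 3, ReLU) →
   max-pooling (size 3, stride 3) → dropout(0.2) → bidirectional GRU
   (128 units per direction, full sequences); between blocks the forward and
   backward stacks F and B are concatenated along channels and followed by
   dropout(0.2);
3. dot-product attention `a = softmax(F Bᵀ) B` on the final BiGRU's
   forward/backward stacks;
4. flatten → dense(64, ReLU) → dropout(0.2) → dense(64, ReLU) →
   dense(2, softmax).

With the default three blocks the sequence length contracts
900 → 300 → 100 → 33, so attention mixes 33 high-level time steps.  The
default model has 1,111,042 trainable parameters.

The GRU cell follows the literal gate convention

    r = σ(W_r x + U_r h₋),  z = σ(W_z x + U_z h₋),
    h̃ = tanh(W_x x + r ⊙ U_x h₋),  h = z ⊙ h₋ + (1−z) ⊙ h̃,

in which the update gate multiplies the **previous** state.  The mirrored
convention used by some frameworks is equivalent under z ↔ 1−z; here the
trainable layer and the reference oracle both use the literal form, so they
are directly comparable.  GRU and convolution layers carry no bias terms
(matching the defining equations); dense layers have zero-initialized
biases.  The attention softmax normalizes over key positions (the last axis
of F Bᵀ); the defining expression does not fix the axis, and this choice
makes each output row a convex combination of backward states.

All layers run on a small reverse-mode automatic-differentiation engine
written on NumPy (`apnea_st.autodiff`), in float64.  Independent loop-level
implementations of each layer equation (`apnea_st.reference`) serve as test
oracles; the assembled network is checked end-to-end against their
composition and against finite-difference gradients.

## Preprocessing

- **R-peak detection** is a Hamilton-family detector: 8–16 Hz third-order
  Butterworth band-pass (zero-phase), absolute first difference, 80 ms
  moving-average integration, candidate local maxima accepted against an
  adaptive threshold `noise + 0.3125·(signal − noise)` where the signal and
  noise levels are exponential running averages (coefficient 1/8) of
  accepted and rejected candidate heights, a 200 ms refractory period
  (within which a larger candidate replaces the previous acceptance — the
  detection function ripples on the QRS ramp), and refinement of each
  detection to the raw-signal maximum within ±50 ms.  All constants are
  function parameters.
- **Artifact cleaning**: RR values outside [0.4, 2.0] s or deviating more
  than 20% from a 5-point running median are replaced by that running
  median; the amplitude of the beat ending a flagged interval is replaced by
  the amplitude series' own running median (symmetric treatment; can be
  disabled).  The running median uses edge-replicated padding.  These four
  numbers are standard heart-rate-variability artifact bounds and are
  exposed as arguments.
- **Windowing**: minute m (0-based, half-open [60m, 60(m+1)) s) is windowed
  with ±2 context minutes; edge minutes without full context are dropped,
  not padded.  Both series are cubically interpolated (SciPy `CubicSpline`,
  not-a-knot) onto 900 uniform points over the 300 s span — grid points at
  t0 + k·(300/900), k = 0…899, i.e. an exact 3 Hz effective rate with a
  half-open span consistent with the minute convention.  RR knots sit at the
  time of the beat that ends each interval.  Evaluation points outside the
  in-window knot range take the nearest knot value.  Windows with fewer than
  4 in-window knots are rejected ("sparse beats") and dropped.
- **Normalization**: per-channel z-score with mean/SD fitted on the training
  windows and stored with the checkpoint, so inference is self-contained.

## Minute labeling from respiratory events

A minute is labeled SA when qualifying respiratory events occupy strictly
more than 5 s of it.  Occupancy is the measure of the **union** of events
(overlapping events do not double-count), computed exactly from the interval
arithmetic.  The set of qualifying event types is configurable; the default
counts all apnea and hypopnea variants.  Four UCDDB subjects without apnea
events (ucddb008/011/013/018) are excluded via a configuration list, not
reader logic.

## Training

Mini-batch Adam on binary cross-entropy of the SA-class probability
(clipped to [1e−7, 1−1e−7]).  Defaults: 40 epochs, learning rate 0.001,
batch 128, β₁ = 0.9, β₂ = 0.999, ε = 1e−7.  The Adam step uses the
rearranged bias-corrected form θ ← θ − α·√(1−β₂ᵗ)/(1−β₁ᵗ)·m/(√v + ε).
After every epoch the validation accuracy is computed and the weights are
checkpointed when it strictly improves (ties keep the earlier checkpoint);
accuracy is the checkpoint criterion because it is the headline per-segment
metric.  Shuffling, dropout masks and initialization all flow from a single
seed, so a fixed seed fixes the entire trajectory bitwise.

Class imbalance is handled by seeded oversampling of the minority class to
parity (duplication with replacement), and transfer to a second dataset by
fine-tuning: training continued from a checkpoint with identical mechanics.
The validation split is performed at the recording level by default to
avoid leakage between overlapping ±2-minute context windows of neighboring
segments; a segment-level split remains available for the second-dataset
workflow where recordings are few.

## Evaluation

Per segment: confusion counts with SA positive (decision = argmax of the
softmax pair, equivalently SA probability ≥ 0.5), accuracy, recall,
specificity, precision, F1 (undefined ratios reported as NaN, never
0-by-convention), and ROC AUC (threshold varied only for the curve).  Per
recording: AHI = 60·N/T over the T minutes that survived preprocessing,
with the clinical call SA iff AHI > 5 (strict).  Because predictions exist
only for surviving minutes, the annotation-derived reference AHI used in
cohort comparisons is computed over the same minutes, keeping the
comparison like for like.  Cohort agreement: mean absolute AHI error and
the Pearson correlation coefficient (undefined under zero variance; NaN
with a warning).

## Synthetic test bed

The generator plants the one structure the features can detect: inside
configured apnea intervals the RR mean is modulated by
`1 + 0.25·sin(2πt/40 s)` and the R amplitude by `1 + 0.30·sin(2πt/40 s)`;
outside, RR ~ Normal(0.85 s, 0.02 s) and amplitude 1 mV (±0.01 mV jitter).
Beats are rendered as a Ricker wavelet (~100 ms wide, σ = 20 ms, unit peak
exactly on the beat's sample) so the detector's refinement step has an
unambiguous target; optional white noise can be added.  Episode/gap
alternation targets a configured SA-minute prevalence (default 0.3),
accounting for the ~1 extra labeled minute each episode gains from the
>5 s rule at its boundaries.  Per-record seeds derive from one master seed
through a `SeedSequence` spawn, so every record and the manifest are
independently reproducible.

What the generator does **not** emulate: realistic QRS/P/T morphology,
respiration or SpO₂, arrhythmias, electrode artifacts, baseline wander, or
inter-subject variability.  Passing the synthetic end-to-end check
demonstrates that the pipeline is wired correctly and can learn the planted
RR/amplitude modulation; it does not certify clinical performance on real
polysomnography.

## Reference experiment (problem sizes)

The download-free experiment used by `scripts/acceptance.py` and the
end-to-end test: 8 records of 60 min at 100 Hz with prevalence 0.3 and no
added noise; records 0–5 train (20% of their windows held out for
validation), 6–7 test; the small configuration (1 block, 8 filters, 8 GRU
units, 16 dense units, ~40k parameters) trained 5 epochs with batch 32 and
learning rate 0.005.  The cohort AHI comparison uses all 8 recordings so
the correlation rests on more than two points.  These sizes were chosen so
a scientist can re-run the whole experiment in well under a minute on one
CPU core while leaving ample headroom between typical results
(accuracy ≈ 0.94–1.0 across seeds) and the ≥ 0.85 end-to-end bar.

## Known limitations

- The trainable network is CPU-bound NumPy; the full 3-block model is
  practical for inference and short training runs but not for the 40-epoch,
  17k-segment benchmark protocol, which is expected to run on the CLI over
  hours rather than in the test suite.
- The WFDB support covers format 16 with a shared .dat file; the per-minute
  apnea annotation stream is a plain-text A/N file rather than the binary
  annotation format.
- EDF reading goes through MNE and assumes millivolt-dimension ECG
  channels.
- `clean_rr` is a single pass; idempotency holds for isolated artifacts
  (verified over seeded random series) but is not guaranteed for dense
  artifact bursts.
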