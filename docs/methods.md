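# Methods

## The model and its assumptions

`grusynth` casts waveform learning as next-sample classification over a
discrete amplitude alphabet, the way character-level language models
treat text. The assumptions this rests on:

- a single channel carries the morphology of interest; no covariates;
- amplitude resolution can be reduced to `S_D` classes (64 by default,
  32 in the reduced experiments) without destroying the shapes to be
  learned — quantization is a deliberate, lossy complexity reduction;
- morphology is (quasi-)stationary over the recording: one set of
  parameters describes the whole signal;
- everything the model needs about the past can be carried in the hidden
  states of three GRU layers, reset to zero at every window boundary.

The pipeline is: smooth → quantize → label shift (`y_n = x_{n+1}`, final
label 0) → window (2/3 overlap) → embed → 3×GRU → affine regression →
softmax → cross-entropy/BPTT/RMSprop. Synthesis runs the same network
autoregressively, drawing each next step from the predicted distribution
(no temperature, no greedy decoding) and feeding it back.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `S_D` | amplitude classes | 64 (32 reduced) | balances amplitude fidelity against output-alphabet size |
| `H_D` | GRU hidden size | 256 ECG / 512 RESP, EMG (64 reduced) | wide-band signals need more state capacity |
| `W` | window length, samples | 512 (1024 RESP; 128 reduced) | should cover ≥ one cycle of the signal |
| hop | window stride | `W/3` (rounded if `W % 3 ≠ 0`, with a warning) | 2/3 overlap triples effective data |
| `ma_window` | moving-average length | 0.2 s | baseline estimate; subtracted when detrending |
| `hann_window` | Hanning length | 0.04 s | removes noise above ~25 Hz at 250 Hz without erasing the QRS |
| `η, γ, ε` | RMSprop constants | 1e-3, 0.9, 1e-8 | conventional values; γ in the 0.9–0.95 range |
| grad clip | global norm ceiling | 5.0 (off with `--no-clip`) | BPTT over hundreds of steps can explode early in training |
| `batch_windows` | windows per update | 32 (16 in the experiments) | smaller batches give more updates per pass, which matters more than batch smoothness here |

The reduced experiment protocols (`grusynth.experiments`) use
`learning_rate = 2e-3`: with only ~64 hidden units and ~350 windows the
loss surface is benign and the larger step roughly halves the number of
epochs needed. Library defaults stay at the conservative 1e-3.

## Numerical choices

- Quantization normalizes by the full amplitude range `(max − min)` so
  the alphabet is exactly spanned; rounding is half-away-from-zero,
  stated so results are bit-reproducible (ties at step midpoints are the
  only values affected).
- The smoothing kernels are normalized to unit sum and applied with
  nearest-edge padding, so length is preserved and a constant input maps
  to itself (when not detrending).
- Softmax subtracts the row maximum before exponentiation.
- Cross-entropy floors probabilities at 1e-12 inside the log (logged when
  it triggers); the gradient uses the exact softmax+cross-entropy form
  `o − onehot(y)`, unaffected by the floor.
- GRU gates carry no bias terms; layer-1 input projections are
  `(H_D × S_D)`, deeper layers `(H_D × H_D)` — forced by composition.
- Hidden state starts at zero for every training window and at the start
  of synthesis.
- All arithmetic is float64; gradients are exact derivatives of the
  forward pass, and the finite-difference verification uses the
  norm-based per-array relative error, evaluated at a generic-scale
  random parameter point — at the tiny uniform init some gate-path
  derivatives (~1e-11) sit below what float64 central differences can
  resolve against a loss of order 1, so an element-wise comparison there
  measures round-off, not correctness.
- Ties in the error-matrix "lowest" flags go to the lowest model index.
- The evaluation predictor is the argmax of the output distribution
  (`mode="sample"` is available); errors are in step² units.

## What the synthetic fixtures emulate — and what they don't

`gen_resp` produces a quasi-sinusoid with per-cycle period jitter (5%),
slow amplitude drift and additive noise; `gen_emg` multiplies 20–110 Hz
band-limited noise by a periodic raised-cosine burst envelope over a 5%
resting tone; `gen_ecg` sums five Gaussian waves (P, Q, R, S, T) at fixed
phase fractions of a jittered beat cycle over a constant baseline. Three
parameter sets ("subjects") per kind vary rates and amplitudes (ECG
subjects beat at 60/70/80 bpm — a realistic resting range that also
gives the evaluation distinct sources).

They do **not** reproduce: real inter-beat correlation structure
(respiratory sinus arrhythmia), electrode/motion artifacts, baseline
wander, pathological morphologies, or realistic EMG spectral shapes.
Passing tests therefore demonstrate that the *pipeline* can learn and
discriminate morphologies of these classes, not that it is validated on
clinical recordings.

Because the fixtures carry no baseline wander, the experiment protocols
detrend only the fast signals (ECG, EMG); for RESP (~0.25 Hz) the
moving-average subtraction would remove essentially the whole signal and
leave only noise, so RESP is low-passed without detrending. On real
recordings with drift, detrending RESP with a correspondingly longer
moving-average window would be the appropriate configuration.

## Experiment protocols and problem sizes

- **Gradient verification**: `S_D=8, H_D=4, W=16`, batch 2 — every
  parameter perturbed ±1e-5; agreement is ~1e-6, two orders below the
  1e-5 bar.
- **Overfit/rhythm**: ECG subject 3 (80 bpm), 60 s at 250 Hz, `W=128,
  S_D=32, H_D=64`, all 346 windows, batches of 16, 120 epochs at 2e-3.
  Subject 3 is used because at 80 bpm one full beat (~187 samples) keeps
  every inter-wave gap within the 128-sample training horizon. The
  synthesized rhythm is measured as the dominant autocorrelation peak in
  the 0.3–2.5 s beat range over 4096 generated samples (256 burn-in),
  identically for training and generated sequences.
- **Source discrimination**: 30 s of RESP/EMG/ECG (subject 1 each),
  same reduced dimensions, 40 epochs; training windows drawn from the
  first third of each signal, the error matrix computed on 128-sample
  windows tiling the final two thirds. These sizes keep a full
  five-seed replication to a few minutes while leaving the diagonal
  property clearly resolved (off-diagonal errors are 5–100× larger).

## Open design points, resolved

- The quantization denominator is the amplitude *range*, the only
  reading that spans the step alphabet when `min ≠ 0`.
- The loss is plain categorical cross-entropy with one-hot targets.
- The regression node is the per-sample affine map `ô_n = b_o + Vᵀ h_n⁽³⁾`.
- An "epoch" is one full shuffled pass over all training windows;
  updates happen per mini-batch.
- Generation can start from a single uniformly random step (default) or
  from a real warm-up window run through the model without sampling;
  both modes are provided.
- Window lengths not divisible by 3 use a rounded hop and warn, rather
  than erroring — the canonical `W` values (512, 1024, 128) are all
  indivisible by 3, so a hard error would make 2/3 overlap unusable.

## Known limitations

- Preprocessing is sensitive to large-amplitude outliers: a single spike
  stretches the quantization range and compresses everything else.
- Quantization is lossy by design; `S_D` bounds amplitude fidelity.
- The network is a finite state machine: very long-range structure
  (longer than what hidden state can count through) is not captured, and
  window-boundary state resets bias the model toward within-window
  dependencies.
- Training is CPU-bound Python/NumPy; it is sized for the reduced
  protocols, not for hours-long recordings at full dimensions.
- Synthesis quality degrades under exposure bias: sampled steps can
  drift off the training manifold, and with undertrained models the
  generated rhythm is slower and more irregular than the source.
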