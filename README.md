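# grusynth

Learning and synthesis of biosignal morphology with stacked GRU networks.

`grusynth` treats a single-channel physiological time series — respiration
(RESP), electromyogram (EMG) or electrocardiogram (ECG) — as a sequence of
quantized amplitude classes and fits a recurrent next-sample classifier to
it. New signals are then generated autoregressively: each next amplitude
step is *sampled* from the model's output distribution and fed back as the
next input, so the generated trace is a fresh stochastic realization of
the learned morphology, not a replay. Because a model fitted to one signal
explains that signal's future better than any other model does, the
cross-model prediction-error matrix also identifies a signal's type (and,
for sufficiently individual signals, its source).

## Model

A signal sampled at rate `f` (250 Hz throughout the examples) is smoothed
(moving average + Hanning low-pass, optionally baseline-detrended),
quantized to `S_D` integer steps

    x_n = round( (s_n − min s) / (max s − min s) · (S_D − 1) ),  x_n ∈ {0,…,S_D−1}

paired with next-sample labels `y_n = x_{n+1}` (final label 0), and cut
into windows of length `W` with 2/3 overlap. Each step index selects a
column of a learnable square embedding matrix `E (S_D×S_D)`; the embedded
vector passes through three GRU layers with hidden size `H_D`:

    r = σ(W_r x + U_r h_{n−1})          reset gate
    z = σ(W_z x + U_z h_{n−1})          update gate
    h̃ = tanh(W_h x + U_h (r ∘ h_{n−1}))
    h_n = z ∘ h_{n−1} + (1 − z) ∘ h̃     (z → 1 keeps the old state)

followed by an affine regression node `ô = b_o + Vᵀ h⁽³⁾` and a softmax
giving the probability of every possible next step. Training minimizes
the categorical cross-entropy `−mean log o[y]` by backpropagation through
time, with RMSprop updates

    E(g²)_t = γ E(g²)_{t−1} + (1−γ) g_t²,   θ_{t+1} = θ_t − η g_t / √(E(g²)_t + ε).

All of this is implemented from scratch in NumPy (exact gradients,
verified against finite differences), with scikit-learn-style estimators
on top.

## Worked example

No recordings are needed: the package ships seeded generators for
RESP-like, EMG-like and ECG-like signals (three "subjects" each).

```python
import numpy as np
from grusynth import GruSignalModel, SignalQuantizer, SignalSmoother, dominant_period
from grusynth.fixtures import generate

raw = generate("ecg", subject=3, duration=60.0, rate=250.0, seed=1)  # 80 bpm
smoothed = SignalSmoother(rate=250.0, detrend=True).fit(raw).transform(raw)
quantizer = SignalQuantizer(n_steps=32).fit(smoothed)

model = GruSignalModel(n_steps=32, hidden_dim=64, window=128, epochs=120,
                       batch_windows=16, learning_rate=2e-3,
                       max_train_windows=None, random_state=1)
model.fit(quantizer.to_quantized(smoothed))
print(f"loss: {model.history_.losses[0]:.3f} -> {model.history_.losses[-1]:.3f}")

syn = model.sample(n_samples=4096, burn_in=256, random_state=1)
print("train period %.3f s" % dominant_period(quantizer.transform(smoothed).astype(float), 250.0, 0.3, 2.5))
print("synth period %.3f s" % dominant_period(syn.steps.astype(float), 250.0, 0.3, 2.5))
```

prints

```
loss: 2.626 -> 0.205
train period 0.748 s
synth period 0.748 s
```

i.e. the fitted model drives the next-step cross-entropy from near
chance (`ln 32 ≈ 3.47` at initialization; 2.63 averaged over the first
epoch) down to 0.21, and the freely generated signal beats at
the same 0.75 s period (80 bpm) as the subject it was trained on — the
model has acquired the "notion of frequency" of the training data, not
just its local shapes.

The same workflow is available from a shell:

```bash
grusynth simulate --kind ecg --subject 3 --duration 60 --seed 1 --out ecg.csv
grusynth preprocess --signal ecg.csv --sd 32 --window 128 --out data.npz
grusynth train --dataset data.npz --hd 64 --epochs 120 --seed 1 --out model.npz
grusynth synthesize --model model.npz --n 4096 --seed 1 --out synth.csv
grusynth evaluate --models model.npz --signals ecg.csv --window 128 --out matrix.tsv
```

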