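"""End-to-end experiment protocols on the synthetic fixtures.

These functions wire the generators, preprocessing, training, synthesis
and evaluation together into the three study protocols the package is
validated with: overfitting one subject's signal and checking the
synthesized rhythm, cross-training three signal types and checking that
each signal is best explained by its own model, and verifying the BPTT
gradients against finite differences.  Problem sizes default to reduced
dimensions (W=128, S_D=32, H_D=64, tens of seconds of signal) so a full
protocol runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from . import fixtures, preprocess, synthesis, training
from .evaluation import (
    SplitSpec,
    dominant_period,
    error_matrix,
    split_dataset,
)
from .network import init_params
from .preprocess import QuantizedSignal

__all__ = [
    "fixture_quantized",
    "overfit_experiment",
    "discrimination_experiment",
    "gradient_check",
    "count_models",
]

# Fixture smoothing: the synthetic signals carry no baseline wander, and
# subtracting a 0.2 s moving average from a ~0.25 Hz respiratory
# quasi-sinusoid would remove essentially the whole signal, so detrending
# is reserved for the fast signals (ECG, EMG).
FIXTURE_DETREND = {"resp": False, "emg": True, "ecg": True}


def fixture_quantized(
    kind: str,
    subject: int,
    duration: float,
    n_steps: int,
    seed: int,
    rate: float = fixtures.DEFAULT_RATE,
) -> QuantizedSignal:
    """Generate, smooth and quantize one synthetic fixture signal."""
    raw = fixtures.generate(kind, subject=subject, duration=duration,
                            rate=rate, seed=seed)
    return preprocess.preprocess_signal(
        raw, rate=rate, n_steps=n_steps, detrend=FIXTURE_DETREND[kind])


def overfit_experiment(
    seed: int,
    duration: float = 60.0,
    window: int = 128,
    n_steps: int = 32,
    hidden_dim: int = 64,
    epochs: int = 120,
    batch_windows: int = 16,
    learning_rate: float = 2e-3,
    max_train_windows: int | None = None,
    subject: int = 3,
    synth_samples: int = 4096,
    rate: float = fixtures.DEFAULT_RATE,
) -> dict:
    """Overfit one subject's ECG-like signal and synthesize from the model.

    Returns the epoch-1 and final cross-entropy, their ratio, and the
    dominant autocorrelation periods of the training and synthesized
    signals (with the relative period error).  A model that has learned
    the morphology should at least halve the loss and generate output
    whose rhythm matches the training heart rate.
    """
    q = fixture_quantized("ecg", subject, duration, n_steps, seed, rate)
    labels = preprocess.make_labels(q.steps)
    ws = preprocess.segment(q.steps, labels, window)
    if max_train_windows is not None and ws.n_windows > max_train_windows:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(ws.n_windows, max_train_windows, replace=False))
        ws = preprocess.WindowSet(X=ws.X[keep], Y=ws.Y[keep],
                                  window=ws.window, hop=ws.hop)
    cfg = training.TrainConfig(
        n_steps=n_steps, hidden_dim=hidden_dim, epochs=epochs,
        batch_windows=batch_windows, eta=learning_rate, seed=seed)
    params, history = training.train(ws, cfg)

    syn = synthesis.synthesize(
        params,
        synthesis.SynthesisConfig(n_samples=synth_samples, burn_in=256, seed=seed),
        s_min=q.s_min, s_max=q.s_max,
    )
    # search the physiologic beat range; both periods measured identically
    period_lo, period_hi = 0.3, 2.5
    train_period = dominant_period(q.steps.astype(float), rate,
                                   period_lo, period_hi)
    synth_period = dominant_period(syn.steps.astype(float), rate,
                                   period_lo, period_hi)
    return {
        "loss_first": history.losses[0],
        "loss_final": history.losses[-1],
        "loss_ratio": history.losses[-1] / history.losses[0],
        "train_period_s": train_period,
        "synth_period_s": synth_period,
        "period_rel_error": abs(synth_period - train_period) / train_period,
        "params": params,
        "history": history,
        "quantized": q,
        "synthesized": syn,
    }


def discrimination_experiment(
    seed: int,
    duration: float = 30.0,
    window: int = 128,
    n_steps: int = 32,
    hidden_dim: int = 64,
    epochs: int = 40,
    batch_windows: int = 16,
    learning_rate: float = 2e-3,
    n_train_windows: int = 128,
    subject: int = 1,
    rate: float = fixtures.DEFAULT_RATE,
):
    """Train one model per signal type and cross-evaluate all pairs.

    Each model trains on random windows from the first third of its
    signal; the models x signals error matrix is computed on windows tiled
    over the held-out final two thirds.  Returns the
    :class:`~grusynth.evaluation.ErrorMatrix` (rows and columns ordered
    RESP, EMG, ECG).
    """
    kinds = ["resp", "emg", "ecg"]
    models, tests = [], []
    for i, kind in enumerate(kinds):
        q = fixture_quantized(kind, subject, duration, n_steps, seed + i, rate)
        spec = SplitSpec(window=window, n_train_windows=n_train_windows,
                         test_window=window, seed=seed)
        train_ws, test_ws = split_dataset(q, spec)
        cfg = training.TrainConfig(
            n_steps=n_steps, hidden_dim=hidden_dim, epochs=epochs,
            batch_windows=batch_windows, eta=learning_rate, seed=seed + i)
        params, _ = training.train(train_ws, cfg)
        models.append(params)
        tests.append(test_ws)
    return error_matrix(models, tests, model_names=kinds, signal_names=kinds)


def gradient_check(
    n_steps: int = 8,
    hidden_dim: int = 4,
    window: int = 16,
    batch: int = 2,
    seed: int = 0,
    fd_step: float = 1e-5,
    params=None,
) -> float:
    """Max relative error between BPTT and central finite differences.

    Perturbs every parameter entry by ±``fd_step``, assembles the numeric
    gradient of every parameter array, and returns the worst per-array
    relative error ``||g_bptt - g_fd|| / (||g_bptt|| + ||g_fd||)`` (the
    norm-based metric standard for gradient checking; element-wise ratios
    are dominated by floating-point noise wherever a derivative is
    incidentally near zero).
    """
    rng = np.random.default_rng(seed)
    if params is None:
        # generic-scale random point: at the tiny uniform init the gate-path
        # gradients (~1e-11) fall below float64 finite-difference resolution,
        # so the comparison is made where both sides are resolvable
        params = init_params(n_steps, hidden_dim, seed)
        for arr in params.to_dict().values():
            arr += rng.normal(0.0, 0.3, size=arr.shape)
    X = rng.integers(0, n_steps, size=(batch, window))
    Y = rng.integers(0, n_steps, size=(batch, window))

    grads, _ = training.bptt_gradients(params, X, Y)

    from .network import forward_batch

    def loss_at(p):
        probs, _ = forward_batch(X, p)
        return training.cross_entropy(probs, Y)

    arrays = params.to_dict()
    worst = 0.0
    for name, theta in arrays.items():
        flat = theta.ravel()
        g = grads[name].ravel()
        numeric = np.empty_like(g)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + fd_step
            lp = loss_at(params)
            flat[i] = orig - fd_step
            lm = loss_at(params)
            flat[i] = orig
            numeric[i] = (lp - lm) / (2 * fd_step)
        denom = np.linalg.norm(g) + np.linalg.norm(numeric)
        rel = np.linalg.norm(g - numeric) / max(1e-12, denom)
        worst = max(worst, rel)
    return worst


def count_models(roster: dict[str, int]) -> int:
    """Total models under the one-model-per-subject-per-signal scheme.

    ``roster`` maps signal kind to the number of subjects recorded for
    it; every (subject, signal) pair gets its own model.
    """
    if any(n < 0 for n in roster.values()):
        raise ValueError("subject counts must be non-negative")
    return int(sum(roster.values()))
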