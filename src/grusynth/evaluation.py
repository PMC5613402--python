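"""Cross-model evaluation: train/test split, per-window squared prediction
error, and the models x signals error matrix.

The protocol trains each model on random windows drawn from the first
third of its signal and measures, on windows tiled over the remaining two
thirds of *every* signal, the mean squared difference between the model's
deterministic next-step prediction (argmax of the output distribution)
and the true next step.  A model should explain the signal that trained
it best, so per-signal minima of the mean error are expected on the
diagonal of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import ModelParams, forward_batch
from .preprocess import QuantizedSignal, WindowSet, make_labels

__all__ = [
    "SplitSpec",
    "ErrorMatrix",
    "split_dataset",
    "window_mse",
    "batch_window_mse",
    "error_matrix",
    "dominant_period",
]


@dataclass
class SplitSpec:
    """Train/test split settings.

    Train windows (length ``window``) are sampled uniformly without
    replacement from the hop-grid of windows fully inside the first
    ``train_fraction`` of the signal; test windows (length
    ``test_window``) tile the remainder without overlap.  The regions are
    disjoint, so no test sample is ever seen in training.
    """

    window: int
    train_fraction: float = 1.0 / 3.0
    n_train_windows: int = 128
    test_window: int = 512
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_train_windows < 1 or self.window < 3 or self.test_window < 1:
            raise ValueError("invalid split dimensions")


@dataclass
class ErrorMatrix:
    """Mean and standard deviation of per-window squared prediction error.

    Rows are models, columns are signals.  ``lowest_flags[m, s]`` marks the
    row with the smallest mean in column ``s`` (ties broken toward the
    lowest model index).
    """

    mean: np.ndarray
    std: np.ndarray
    lowest_flags: np.ndarray
    model_names: list[str]
    signal_names: list[str]

    @property
    def diagonal_is_lowest(self) -> bool:
        """True when every signal is best explained by its own model."""
        n = min(self.mean.shape)
        return bool(np.all(self.lowest_flags[np.arange(n), np.arange(n)]))


def split_dataset(
    x: QuantizedSignal, spec: SplitSpec
) -> tuple[WindowSet, WindowSet]:
    """Split a quantized signal into training and test window sets."""
    steps = x.steps
    labels = make_labels(steps)
    n = steps.size
    boundary = int(np.floor(spec.train_fraction * n))
    if boundary < spec.window:
        raise ValueError("signal too short for one training window")
    if n - boundary < spec.test_window:
        raise ValueError("signal too short for one test window")

    hop = max(1, int(round(spec.window / 3)))
    starts = np.arange(0, boundary - spec.window + 1, hop)
    rng = np.random.default_rng(spec.seed)
    if starts.size <= spec.n_train_windows:
        if starts.size < spec.n_train_windows:
            warnings.warn(
                f"only {starts.size} train windows available "
                f"(requested {spec.n_train_windows}); using all",
                stacklevel=2,
            )
        chosen = np.sort(starts)
    else:
        chosen = np.sort(rng.choice(starts, size=spec.n_train_windows,
                                    replace=False))
    idx = chosen[:, None] + np.arange(spec.window)[None, :]
    train = WindowSet(X=steps[idx], Y=labels[idx], window=spec.window, hop=hop)

    test_starts = np.arange(boundary, n - spec.test_window + 1, spec.test_window)
    tidx = test_starts[:, None] + np.arange(spec.test_window)[None, :]
    test = WindowSet(X=steps[tidx], Y=labels[tidx],
                     window=spec.test_window, hop=spec.test_window)
    return train, test


def window_mse(
    params: ModelParams,
    X: np.ndarray,
    Y: np.ndarray,
    mode: str = "argmax",
    rng: np.random.Generator | None = None,
) -> float:
    """Mean squared next-step prediction error over one window.

    The point prediction is the mode of the output distribution
    (``mode="argmax"``); ``mode="sample"`` instead draws the prediction
    stochastically, matching the generator's behaviour.
    """
    X = np.asarray(X, dtype=np.int64)
    Y = np.asarray(Y, dtype=np.int64)
    return float(batch_window_mse(params, X[None, :], Y[None, :], mode, rng)[0])


def batch_window_mse(
    params: ModelParams,
    X: np.ndarray,
    Y: np.ndarray,
    mode: str = "argmax",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-window mean squared prediction error for a stack of windows."""
    X = np.asarray(X, dtype=np.int64)
    Y = np.asarray(Y, dtype=np.int64)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must be equal-shape (D, W)")
    if X.max() >= params.n_steps or Y.max() >= params.n_steps:
        raise ValueError("window steps outside the model's alphabet")
    probs, _ = forward_batch(X, params)
    if mode == "argmax":
        y_hat = probs.argmax(axis=-1)
    elif mode == "sample":
        if rng is None:
            rng = np.random.default_rng()
        u = rng.random(size=probs.shape[:2])
        cdf = probs.cumsum(axis=-1)
        y_hat = (u[..., None] > cdf).sum(axis=-1)
    else:
        raise ValueError("mode must be 'argmax' or 'sample'")
    diff = (y_hat - Y).astype(np.float64)
    return (diff * diff).mean(axis=1)


def error_matrix(
    models: list[ModelParams],
    signals: list[WindowSet],
    model_names: list[str] | None = None,
    signal_names: list[str] | None = None,
    mode: str = "argmax",
) -> ErrorMatrix:
    """Models x signals matrix of mean/std per-window prediction error."""
    if not models or not signals:
        raise ValueError("need at least one model and one signal")
    n_steps = models[0].n_steps
    if any(m.n_steps != n_steps for m in models):
        raise ValueError("all models must share the same step alphabet")
    mean = np.empty((len(models), len(signals)))
    std = np.empty_like(mean)
    for i, model in enumerate(models):
        for j, ws in enumerate(signals):
            errs = batch_window_mse(model, ws.X, ws.Y, mode=mode)
            mean[i, j] = errs.mean()
            std[i, j] = errs.std()
    flags = np.zeros(mean.shape, dtype=bool)
    flags[np.argmin(mean, axis=0), np.arange(mean.shape[1])] = True  # argmin
    # takes the first (lowest model index) on ties
    return ErrorMatrix(
        mean=mean, std=std, lowest_flags=flags,
        model_names=model_names or [f"model{i}" for i in range(len(models))],
        signal_names=signal_names or [f"signal{j}" for j in range(len(signals))],
    )


def dominant_period(
    signal: np.ndarray,
    rate: float,
    min_period: float | None = None,
    max_period: float | None = None,
) -> float:
    """Dominant period in seconds, from the autocorrelation peak.

    The (mean-removed, biased) autocorrelation is searched for its global
    maximum at lags within ``[min_period, max_period]`` seconds.  When
    ``min_period`` is not given the search starts past the first
    zero-crossing of the autocorrelation (so the trivial near-zero-lag
    peak is excluded); ``max_period`` defaults to half the signal length.
    """
    x = np.asarray(signal, dtype=np.float64)
    x = x - x.mean()
    n = x.size
    if n < 8:
        raise ValueError("signal too short for period estimation")
    ac = np.correlate(x, x, mode="full")[n - 1:]
    if min_period is not None:
        lo = max(2, int(round(min_period * rate)))
    else:
        neg = np.nonzero(ac < 0)[0]
        lo = int(neg[0]) if neg.size else 2
    hi = min(n - 1, int(round((max_period or (n / 2) / rate) * rate)))
    if hi <= lo:
        raise ValueError("period search range is empty")
    lag = lo + int(np.argmax(ac[lo:hi + 1]))
    return lag / rate
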