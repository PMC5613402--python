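"""scikit-learn style estimators wrapping the pipeline.

``SignalSmoother`` and ``SignalQuantizer`` are transformers over 1-D
signals; ``GruSignalModel`` is the next-step classifier / generator.  All
three follow the scikit-learn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores) so they compose with
``sklearn.pipeline.Pipeline`` and the model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import preprocess, synthesis, training
from .network import forward_batch
from .evaluation import batch_window_mse
from .preprocess import QuantizedSignal

__all__ = ["SignalSmoother", "SignalQuantizer", "GruSignalModel"]


def _as_1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).squeeze()
    if x.ndim != 1:
        raise ValueError("expected a single-channel 1-D signal")
    return x


class SignalSmoother(TransformerMixin, BaseEstimator):
    """Moving-average + Hanning smoothing of a raw signal.

    Parameters
    ----------
    rate : sampling rate in Hz; used for the default window lengths
        (0.2 s moving average, 0.04 s Hanning).
    ma_window, hann_window : explicit lengths in samples (override rate).
    detrend : subtract the moving average (baseline removal) instead of
        low-passing it.
    """

    def __init__(self, rate: float = 250.0, ma_window: int | None = None,
                 hann_window: int | None = None, detrend: bool = True):
        self.rate = rate
        self.ma_window = ma_window
        self.hann_window = hann_window
        self.detrend = detrend

    def fit(self, X, y=None):
        ma, hann = preprocess.default_smooth_windows(self.rate)
        self.ma_window_ = self.ma_window if self.ma_window is not None else ma
        self.hann_window_ = self.hann_window if self.hann_window is not None else hann
        return self

    def transform(self, X):
        check_is_fitted(self)
        return preprocess.smooth(_as_1d(X), self.ma_window_,
                                 self.hann_window_, detrend=self.detrend)


class SignalQuantizer(TransformerMixin, BaseEstimator):
    """Affine amplitude quantizer onto ``{0 .. n_steps-1}``.

    ``fit`` records the amplitude range (``s_min_``, ``s_max_``);
    ``transform`` maps amplitudes to integer steps and
    ``inverse_transform`` maps steps back to amplitudes.
    """

    def __init__(self, n_steps: int = 64):
        self.n_steps = n_steps

    def fit(self, X, y=None):
        x = _as_1d(X)
        q = preprocess.quantize(x, self.n_steps)
        self.s_min_ = q.s_min
        self.s_max_ = q.s_max
        return self

    def transform(self, X):
        check_is_fitted(self)
        x = _as_1d(X)
        scaled = (x - self.s_min_) / (self.s_max_ - self.s_min_) * (self.n_steps - 1)
        steps = np.floor(scaled + 0.5).astype(np.int64)
        return np.clip(steps, 0, self.n_steps - 1)

    def inverse_transform(self, X):
        check_is_fitted(self)
        steps = np.asarray(X)
        return self.s_min_ + steps / (self.n_steps - 1) * (self.s_max_ - self.s_min_)

    def to_quantized(self, X) -> QuantizedSignal:
        """Transform and package with the learned amplitude range."""
        return QuantizedSignal(steps=self.transform(X), s_min=self.s_min_,
                               s_max=self.s_max_, n_steps=self.n_steps)


class GruSignalModel(BaseEstimator):
    """Next-step classifier over quantized signals, with a generator.

    ``fit`` takes a 1-D integer step sequence (or a
    :class:`~grusynth.preprocess.QuantizedSignal`), windows it with 2/3
    overlap, optionally subsamples ``max_train_windows`` random windows,
    and trains the embedding + 3-layer GRU + softmax model by BPTT with
    RMSprop.  ``predict`` returns argmax next-step predictions for windows,
    ``sample`` generates a new sequence autoregressively.

    Parameters mirror the training configuration: ``n_steps`` (S_D),
    ``hidden_dim`` (H_D), ``window`` (W), RMSprop constants, and
    ``random_state`` for full reproducibility.
    """

    def __init__(self, n_steps: int = 64, hidden_dim: int = 256,
                 window: int = 512, epochs: int = 100, batch_windows: int = 32,
                 learning_rate: float = 1e-3, decay: float = 0.9,
                 epsilon: float = 1e-8, grad_clip: float | None = 5.0,
                 max_train_windows: int | None = 128,
                 checkpoint_epochs: tuple = (), random_state: int = 0):
        self.n_steps = n_steps
        self.hidden_dim = hidden_dim
        self.window = window
        self.epochs = epochs
        self.batch_windows = batch_windows
        self.learning_rate = learning_rate
        self.decay = decay
        self.epsilon = epsilon
        self.grad_clip = grad_clip
        self.max_train_windows = max_train_windows
        self.checkpoint_epochs = checkpoint_epochs
        self.random_state = random_state

    def _config(self) -> training.TrainConfig:
        return training.TrainConfig(
            n_steps=self.n_steps, hidden_dim=self.hidden_dim,
            epochs=self.epochs, batch_windows=self.batch_windows,
            eta=self.learning_rate, gamma=self.decay, epsilon=self.epsilon,
            grad_clip=self.grad_clip,
            checkpoint_epochs=tuple(self.checkpoint_epochs),
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        if isinstance(X, QuantizedSignal):
            self.s_min_, self.s_max_ = X.s_min, X.s_max
            steps = X.steps
            if X.n_steps != self.n_steps:
                raise ValueError("QuantizedSignal alphabet != n_steps")
        else:
            self.s_min_ = self.s_max_ = None
            steps = np.asarray(X, dtype=np.int64).squeeze()
            if steps.ndim != 1:
                raise ValueError("expected a 1-D step sequence")
        labels = preprocess.make_labels(steps)
        ws = preprocess.segment(steps, labels, self.window)
        if self.max_train_windows is not None and ws.n_windows > self.max_train_windows:
            rng = np.random.default_rng(self.random_state)
            keep = np.sort(rng.choice(ws.n_windows, self.max_train_windows,
                                      replace=False))
            ws = preprocess.WindowSet(X=ws.X[keep], Y=ws.Y[keep],
                                      window=ws.window, hop=ws.hop)
        self.params_, self.history_ = training.train(ws, self._config())
        self.n_windows_ = ws.n_windows
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-sample next-step distributions for windows ``(D, W)``."""
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, dtype=np.int64))
        probs, _ = forward_batch(X, self.params_)
        return probs

    def predict(self, X) -> np.ndarray:
        """Argmax next-step prediction for each sample of each window."""
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y) -> float:
        """Negative mean per-window squared prediction error (higher=better)."""
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, dtype=np.int64))
        y = np.atleast_2d(np.asarray(y, dtype=np.int64))
        return -float(batch_window_mse(self.params_, X, y).mean())

    def sample(self, n_samples: int, burn_in: int = 0,
               random_state: int | None = None,
               init_mode: str = "random_step",
               warmup: np.ndarray | None = None) -> synthesis.SynthesizedSignal:
        """Generate a new signal from the fitted model."""
        check_is_fitted(self, "params_")
        cfg = synthesis.SynthesisConfig(
            n_samples=n_samples, burn_in=burn_in,
            seed=self.random_state if random_state is None else random_state,
            init_mode=init_mode,
        )
        return synthesis.synthesize(self.params_, cfg, warmup=warmup,
                                    s_min=self.s_min_, s_max=self.s_max_)
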