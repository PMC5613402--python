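"""Signal preprocessing: smoothing, amplitude quantization and windowing.

A raw biosignal is smoothed (moving average + Hanning low-pass, optionally
detrended by subtracting the moving average), quantized to an integer step
alphabet ``{0 .. n_steps-1}``, paired with next-sample labels, and cut into
overlapping training windows.  The quantized sequence is the supervised
dataset a :class:`~grusynth.network.ModelParams` network consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d, uniform_filter1d

__all__ = [
    "QuantizedSignal",
    "WindowSet",
    "smooth",
    "quantize",
    "dequantize",
    "make_labels",
    "segment",
    "default_smooth_windows",
]


@dataclass(frozen=True)
class QuantizedSignal:
    """Integer step sequence with the amplitude range it was mapped from.

    ``steps[n]`` is the quantization class ``k`` of sample ``n``; ``s_min``
    and ``s_max`` are kept so the sequence can be mapped back to amplitude
    units (:func:`dequantize`).
    """

    steps: np.ndarray
    s_min: float
    s_max: float
    n_steps: int

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=np.int64)
        object.__setattr__(self, "steps", steps)
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.s_max > self.s_min:
            raise ValueError("s_max must exceed s_min")
        if steps.size and (steps.min() < 0 or steps.max() > self.n_steps - 1):
            raise ValueError("steps outside {0..n_steps-1}")

    def __len__(self) -> int:
        return int(self.steps.size)


@dataclass(frozen=True)
class WindowSet:
    """Paired input/label window matrices produced by overlapped segmentation.

    ``X`` and ``Y`` have shape ``(D, W)``; row ``d`` starts at sample
    ``d * hop`` of the underlying sequence and ``Y[d, n]`` is the step that
    follows ``X[d, n]`` in that sequence.
    """

    X: np.ndarray
    Y: np.ndarray
    window: int
    hop: int

    def __post_init__(self):
        X = np.asarray(self.X, dtype=np.int64)
        Y = np.asarray(self.Y, dtype=np.int64)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if X.shape != Y.shape:
            raise ValueError("X and Y must have identical shape")
        if X.ndim != 2 or X.shape[1] != self.window:
            raise ValueError("X must be (n_windows, window)")

    @property
    def n_windows(self) -> int:
        return int(self.X.shape[0])

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.hop / self.window


def default_smooth_windows(rate: float) -> tuple[int, int]:
    """Default smoothing window lengths for a given sampling rate.

    Moving average of 0.2 s (baseline estimate / detrend reference) and a
    0.04 s Hanning window (high-frequency noise removal); both short enough
    to leave a 250 Hz ECG QRS complex recognisable.
    """
    return max(1, round(rate / 5)), max(1, round(rate / 25))


def smooth(
    raw: np.ndarray,
    ma_window: int,
    hann_window: int,
    detrend: bool = True,
) -> np.ndarray:
    """Smooth a raw signal with a moving average and a Hanning low-pass.

    Parameters
    ----------
    raw : array of amplitudes.
    ma_window : moving-average length in samples.
    hann_window : Hanning window length in samples.
    detrend : if True (default), the moving average is *subtracted* (the
        moving average acts as a running baseline estimate, so subtracting
        it removes drift); if False the moving average output itself is
        low-passed.

    The output always has the same length as the input.  The Hanning kernel
    is normalized to unit sum so a constant input maps to that constant
    (when ``detrend`` is off).
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 1 or raw.size < 1:
        raise ValueError("raw must be a non-empty 1-D array")
    if ma_window < 1 or hann_window < 1:
        raise ValueError("window lengths must be >= 1")
    if ma_window > raw.size or hann_window > raw.size:
        raise ValueError("smoothing window longer than signal")

    ma = uniform_filter1d(raw, size=ma_window, mode="nearest")
    base = raw - ma if detrend else ma

    if hann_window == 1:
        return base
    kern = np.hanning(hann_window)
    if kern.sum() == 0:  # np.hanning(2) is all zeros
        kern = np.ones(hann_window)
    kern = kern / kern.sum()
    return convolve1d(base, kern, mode="nearest")


def quantize(s: np.ndarray, n_steps: int) -> QuantizedSignal:
    """Map amplitudes onto the integer step alphabet ``{0 .. n_steps-1}``.

    ``k_n = round((s_n - min s) / (max s - min s) * (n_steps - 1))`` —
    normalised by the full amplitude range so the extreme amplitudes land
    exactly on steps 0 and ``n_steps - 1``.  Rounding is half away from
    zero so results are bit-reproducible.
    """
    s = np.asarray(s, dtype=np.float64)
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if s.size < 1:
        raise ValueError("empty signal")
    s_min, s_max = float(s.min()), float(s.max())
    if s_max == s_min:
        raise ValueError("degenerate signal: constant amplitude cannot be quantized")
    scaled = (s - s_min) / (s_max - s_min) * (n_steps - 1)
    steps = np.floor(scaled + 0.5).astype(np.int64)  # half away from zero (scaled >= 0)
    return QuantizedSignal(steps=steps, s_min=s_min, s_max=s_max, n_steps=n_steps)


def dequantize(x: QuantizedSignal) -> np.ndarray:
    """Inverse affine map of :func:`quantize` (without rounding).

    Step 0 maps to ``s_min`` and step ``n_steps - 1`` to ``s_max``;
    ``quantize(dequantize(x)) == x`` because step centres are fixed points.
    """
    return x.s_min + x.steps / (x.n_steps - 1) * (x.s_max - x.s_min)


def make_labels(x: np.ndarray) -> np.ndarray:
    """Next-sample labels: ``y_n = x_{n+1}``, with a 0 pad at the end."""
    x = np.asarray(x, dtype=np.int64)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("x must be a non-empty 1-D sequence")
    y = np.empty_like(x)
    y[:-1] = x[1:]
    y[-1] = 0
    return y


def segment(x: np.ndarray, y: np.ndarray, window: int) -> WindowSet:
    """Cut paired sequences into windows with 2/3 overlap (hop = W/3).

    Window starts are multiples of the hop; trailing samples that do not
    fill a full window are discarded.  When ``window`` is not divisible by
    3 the hop is rounded (a 2/3 overlap cannot be exact) and a warning is
    emitted.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if window < 3:
        raise ValueError("window must be >= 3")
    if x.size < window:
        raise ValueError("sequence shorter than one window")
    if window % 3 == 0:
        hop = window // 3
    else:
        hop = int(round(window / 3))
        warnings.warn(
            f"window={window} not divisible by 3; using hop={hop} "
            "(overlap slightly off 2/3)",
            stacklevel=2,
        )
    n_win = (x.size - window) // hop + 1
    starts = np.arange(n_win) * hop
    idx = starts[:, None] + np.arange(window)[None, :]
    return WindowSet(X=x[idx], Y=y[idx], window=window, hop=hop)


def preprocess_signal(
    raw: np.ndarray,
    rate: float,
    n_steps: int,
    ma_window: int | None = None,
    hann_window: int | None = None,
    detrend: bool = True,
) -> QuantizedSignal:
    """Smooth then quantize a raw signal with rate-derived default windows."""
    ma_def, hann_def = default_smooth_windows(rate)
    s = smooth(
        raw,
        ma_window if ma_window is not None else ma_def,
        hann_window if hann_window is not None else hann_def,
        detrend=detrend,
    )
    return quantize(s, n_steps)
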