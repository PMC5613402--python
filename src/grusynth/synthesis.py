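"""Autoregressive signal synthesis by stochastic re-feeding.

Starting from a random step (or a warm-up window), the model's next-step
probability vector is sampled and the drawn step is fed back as the next
input, indefinitely.  Because each step is drawn from the full predicted
distribution, the generated signal is a semi-random realization of the
learned morphology rather than a deterministic replay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GruState, ModelParams, forward_window

__all__ = ["SynthesisConfig", "SynthesizedSignal", "sample_step", "synthesize"]


@dataclass
class SynthesisConfig:
    """Generation settings.

    ``init_mode`` is ``"random_step"`` (first input drawn uniformly from
    the step alphabet) or ``"seed_window"`` (a real window is run through
    the model without sampling to warm up the hidden state).  ``burn_in``
    samples are generated and discarded before the kept sequence starts.
    """

    n_samples: int
    burn_in: int = 0
    seed: int = 0
    init_mode: str = "random_step"

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.init_mode not in ("random_step", "seed_window"):
            raise ValueError("init_mode must be 'random_step' or 'seed_window'")


@dataclass
class SynthesizedSignal:
    """Generated step sequence with its per-sample probability trace.

    ``prob_trace[n]`` is the distribution the n-th kept step was drawn
    from (the band one would plot behind the trace); ``amplitude`` is the
    dequantized sequence when an amplitude range is known, else None.
    """

    steps: np.ndarray
    prob_trace: np.ndarray
    amplitude: np.ndarray | None = None


def sample_step(o: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one step index from probability vector ``o``.

    Consumes exactly one uniform draw from ``rng`` (inverse-CDF sampling),
    so generation is reproducible draw-for-draw.
    """
    o = np.asarray(o, dtype=np.float64)
    if o.ndim != 1:
        raise ValueError("o must be a 1-D probability vector")
    if np.any(o < -1e-12):
        raise ValueError("probability vector has negative entries")
    total = o.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"probability vector sums to {total}, not 1")
    cdf = np.cumsum(o)
    cdf[-1] = 1.0  # guard against rounding in the final bin
    u = rng.random()
    return int(np.searchsorted(cdf, u, side="right"))


def synthesize(
    params: ModelParams,
    config: SynthesisConfig,
    warmup: np.ndarray | None = None,
    s_min: float | None = None,
    s_max: float | None = None,
) -> SynthesizedSignal:
    """Generate a signal by sampling and re-feeding the model.

    Hidden state starts at zero.  With ``init_mode="seed_window"`` the
    ``warmup`` steps are run through the model deterministically (no
    sampling) and generation starts from the last warm-up sample;
    otherwise the first input is a uniformly random step.  The same seed
    yields the identical sequence.
    """
    rng = np.random.default_rng(config.seed)
    state = GruState.zeros(params.hidden_dim)

    if config.init_mode == "seed_window":
        if warmup is None or len(warmup) < 1:
            raise ValueError("seed_window mode requires a warm-up window")
        warmup = np.asarray(warmup, dtype=np.int64)
        _, state = forward_window(warmup[:-1], params, state) if len(warmup) > 1 \
            else (None, state)
        x = int(warmup[-1])
    else:
        x = int(rng.integers(params.n_steps))

    total = config.n_samples + config.burn_in
    steps = np.empty(total, dtype=np.int64)
    trace = np.empty((total, params.n_steps))
    for n in range(total):
        probs, state = forward_window(np.array([x]), params, state)
        o = probs[0]
        k = sample_step(o, rng)
        steps[n] = k
        trace[n] = o
        x = k

    kept = steps[config.burn_in:]
    kept_trace = trace[config.burn_in:]
    amplitude = None
    if s_min is not None and s_max is not None:
        amplitude = s_min + kept / (params.n_steps - 1) * (s_max - s_min)
    return SynthesizedSignal(steps=kept, prob_trace=kept_trace, amplitude=amplitude)
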