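"""The sequential next-step model: embedding, three stacked GRU layers,
an affine regression node and a softmax.

Each quantized sample index ``x_n`` selects a column of the embedding
matrix ``E``; the embedded vector passes through three GRU layers whose
hidden states are threaded across the samples of a window; the top hidden
state is mapped by ``o_hat = b_o + V.T @ h3`` and normalised by a softmax
into a probability vector over the ``S_D`` possible next steps.

Gate equations per layer (no gate biases)::

    r = sigmoid(W_r x + U_r h_prev)
    z = sigmoid(W_z x + U_z h_prev)
    h~ = tanh(W_h x + U_h (r * h_prev))
    h  = z * h_prev + (1 - z) * h~

Note the update-gate convention: ``z -> 1`` *keeps* the old state.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GruLayerParams",
    "ModelParams",
    "GruState",
    "init_params",
    "embed",
    "gru_step",
    "regression",
    "softmax",
    "forward_window",
    "forward_batch",
]

N_LAYERS = 3
INIT_SCALE = 0.08  # uniform init half-width for all weight matrices


def _sigmoid(a: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |a|
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass
class GruLayerParams:
    """Weight matrices of one GRU layer.

    ``W_*`` project the layer input (shape ``(H_D, input_dim)``), ``U_*``
    the recurrent state (shape ``(H_D, H_D)``).
    """

    W_r: np.ndarray
    U_r: np.ndarray
    W_z: np.ndarray
    U_z: np.ndarray
    W_h: np.ndarray
    U_h: np.ndarray

    @property
    def hidden_dim(self) -> int:
        return self.W_r.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_r.shape[1]

    def validate(self) -> None:
        h, d = self.W_r.shape
        for name in ("W_r", "W_z", "W_h"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} shape mismatch")
        for name in ("U_r", "U_z", "U_h"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must be square (H_D, H_D)")
        for name in ("W_r", "U_r", "W_z", "U_z", "W_h", "U_h"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class ModelParams:
    """All learnable parameters of the model.

    ``E`` is the square ``(S_D, S_D)`` embedding matrix, ``layers`` the
    three GRU layers (layer 1 input dim ``S_D``, deeper layers ``H_D``),
    ``V`` the ``(H_D, S_D)`` regression weights and ``b_o`` the output bias.
    """

    E: np.ndarray
    layers: list[GruLayerParams]
    V: np.ndarray
    b_o: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.E.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.V.shape[0]

    def validate(self) -> None:
        s = self.E.shape[0]
        if self.E.shape != (s, s):
            raise ValueError("E must be square (S_D, S_D)")
        if len(self.layers) != N_LAYERS:
            raise ValueError(f"expected {N_LAYERS} GRU layers")
        h = self.layers[0].hidden_dim
        expected_in = [s, h, h]
        for i, (layer, d) in enumerate(zip(self.layers, expected_in)):
            layer.validate()
            if layer.input_dim != d or layer.hidden_dim != h:
                raise ValueError(f"layer {i} has inconsistent dimensions")
        if self.V.shape != (h, s):
            raise ValueError("V must be (H_D, S_D)")
        if self.b_o.shape != (s,):
            raise ValueError("b_o must be (S_D,)")

    # --- flat named-array view (used by the optimizer and checkpoints) ---
    def to_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {"E": self.E}
        for i, layer in enumerate(self.layers):
            for name in ("W_r", "U_r", "W_z", "U_z", "W_h", "U_h"):
                out[f"gru{i}.{name}"] = getattr(layer, name)
        out["V"] = self.V
        out["b_o"] = self.b_o
        return out

    @classmethod
    def from_dict(cls, arrays: dict[str, np.ndarray]) -> "ModelParams":
        layers = []
        i = 0
        while f"gru{i}.W_r" in arrays:
            layers.append(
                GruLayerParams(
                    **{n: np.asarray(arrays[f"gru{i}.{n}"], dtype=np.float64)
                       for n in ("W_r", "U_r", "W_z", "U_z", "W_h", "U_h")}
                )
            )
            i += 1
        params = cls(
            E=np.asarray(arrays["E"], dtype=np.float64),
            layers=layers,
            V=np.asarray(arrays["V"], dtype=np.float64),
            b_o=np.asarray(arrays["b_o"], dtype=np.float64),
        )
        params.validate()
        return params

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)


@dataclass
class GruState:
    """Per-layer hidden vectors carried across samples within a window."""

    h: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def zeros(cls, hidden_dim: int, batch: int | None = None) -> "GruState":
        shape = (hidden_dim,) if batch is None else (batch, hidden_dim)
        return cls(h=[np.zeros(shape) for _ in range(N_LAYERS)])


def init_params(n_steps: int, hidden_dim: int, seed: int) -> ModelParams:
    """Random initial parameters: i.i.d. uniform on [-0.08, 0.08], zero bias.

    The same seed yields bit-identical parameters.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if hidden_dim < 1:
        raise ValueError("hidden_dim must be >= 1")
    rng = np.random.default_rng(seed)

    def u(*shape):
        return rng.uniform(-INIT_SCALE, INIT_SCALE, size=shape)

    E = u(n_steps, n_steps)
    layers = []
    for in_dim in (n_steps, hidden_dim, hidden_dim):
        layers.append(
            GruLayerParams(
                W_r=u(hidden_dim, in_dim), U_r=u(hidden_dim, hidden_dim),
                W_z=u(hidden_dim, in_dim), U_z=u(hidden_dim, hidden_dim),
                W_h=u(hidden_dim, in_dim), U_h=u(hidden_dim, hidden_dim),
            )
        )
    V = u(hidden_dim, n_steps)
    b_o = np.zeros(n_steps)
    return ModelParams(E=E, layers=layers, V=V, b_o=b_o)


def embed(x_n: int, E: np.ndarray) -> np.ndarray:
    """Look up the embedding of step index ``x_n``: column ``x_n`` of ``E``."""
    x_n = int(x_n)
    if not 0 <= x_n < E.shape[1]:
        raise ValueError(f"step index {x_n} outside 0..{E.shape[1] - 1}")
    return E[:, x_n].copy()


def gru_step(
    x_in: np.ndarray, h_prev: np.ndarray, layer: GruLayerParams
) -> np.ndarray:
    """One GRU update for a single sample (1-D) or a batch (2-D, rows)."""
    x_in = np.asarray(x_in, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if x_in.shape[-1] != layer.input_dim or h_prev.shape[-1] != layer.hidden_dim:
        raise ValueError("input/state dimensions do not match layer")
    r = _sigmoid(x_in @ layer.W_r.T + h_prev @ layer.U_r.T)
    z = _sigmoid(x_in @ layer.W_z.T + h_prev @ layer.U_z.T)
    h_cand = np.tanh(x_in @ layer.W_h.T + (r * h_prev) @ layer.U_h.T)
    return z * h_prev + (1.0 - z) * h_cand


def regression(h3: np.ndarray, V: np.ndarray, b_o: np.ndarray) -> np.ndarray:
    """Affine output map ``o_hat = b_o + V.T @ h3`` (batched over rows)."""
    h3 = np.asarray(h3, dtype=np.float64)
    if h3.shape[-1] != V.shape[0] or b_o.shape[0] != V.shape[1]:
        raise ValueError("regression shapes inconsistent")
    return b_o + h3 @ V


def softmax(o_hat: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    o_hat = np.asarray(o_hat, dtype=np.float64)
    if not np.all(np.isfinite(o_hat)):
        raise ValueError("softmax input must be finite")
    shifted = o_hat - o_hat.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def forward_window(
    x_window: np.ndarray, params: ModelParams, state: GruState | None = None
) -> tuple[np.ndarray, GruState]:
    """Run one window of step indices through the model.

    Returns the ``(W, S_D)`` matrix of next-step probability vectors and
    the final hidden state (which may be threaded into a following call).
    """
    x_window = np.asarray(x_window, dtype=np.int64)
    probs, states = forward_batch(x_window[None, :], params, None if state is None
                                  else GruState(h=[h[None, :] for h in state.h]))
    return probs[0], GruState(h=[h[0] for h in states.h])


def forward_batch(
    X: np.ndarray,
    params: ModelParams,
    state: GruState | None = None,
    return_cache: bool = False,
):
    """Vectorised forward pass over a batch of windows.

    ``X`` is ``(D, W)`` step indices.  Returns ``(probs, final_state)`` with
    ``probs`` of shape ``(D, W, S_D)``; with ``return_cache=True`` also
    returns the per-timestep intermediates needed for backpropagation
    through time.
    """
    X = np.asarray(X, dtype=np.int64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_windows, window)")
    if X.size and (X.min() < 0 or X.max() >= params.n_steps):
        raise ValueError("step indices outside the model alphabet")
    D, W = X.shape
    H = params.hidden_dim
    S = params.n_steps

    if state is None:
        h = [np.zeros((D, H)) for _ in range(N_LAYERS)]
    else:
        h = [np.asarray(hi, dtype=np.float64).copy() for hi in state.h]

    probs = np.empty((D, W, S))
    cache = {
        "X": X,
        "xhat": np.empty((W, D, S)),
        "inputs": [None, np.empty((W, D, H)), np.empty((W, D, H))],
        "r": [np.empty((W, D, H)) for _ in range(N_LAYERS)],
        "z": [np.empty((W, D, H)) for _ in range(N_LAYERS)],
        "hc": [np.empty((W, D, H)) for _ in range(N_LAYERS)],
        "h_prev": [np.empty((W, D, H)) for _ in range(N_LAYERS)],
        "h_top": np.empty((W, D, H)),
        "probs": probs,
    } if return_cache else None

    E_T = params.E.T  # row x_n is the embedding of step x_n
    for n in range(W):
        x_in = E_T[X[:, n]]  # (D, S)
        if cache is not None:
            cache["xhat"][n] = x_in
        for l, layer in enumerate(params.layers):
            h_prev = h[l]
            r = _sigmoid(x_in @ layer.W_r.T + h_prev @ layer.U_r.T)
            z = _sigmoid(x_in @ layer.W_z.T + h_prev @ layer.U_z.T)
            hc = np.tanh(x_in @ layer.W_h.T + (r * h_prev) @ layer.U_h.T)
            h_new = z * h_prev + (1.0 - z) * hc
            if cache is not None:
                if l > 0:
                    cache["inputs"][l][n] = x_in
                cache["r"][l][n] = r
                cache["z"][l][n] = z
                cache["hc"][l][n] = hc
                cache["h_prev"][l][n] = h_prev
            h[l] = h_new
            x_in = h_new
        if cache is not None:
            cache["h_top"][n] = h[-1]
        probs[:, n, :] = softmax(regression(h[-1], params.V, params.b_o))

    final_state = GruState(h=h)
    if return_cache:
        return probs, final_state, cache
    return probs, final_state
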