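"""Model fitting: cross-entropy loss, backpropagation through time and
RMSprop updates.

The loss is the categorical cross-entropy between the model's next-step
probability vectors and the one-hot encoded labels, averaged over every
sample of every window in a mini-batch.  Gradients are exact derivatives of
the forward computation, obtained by backpropagation through the unrolled
recurrence; RMSprop divides each update by the root of a decayed running
average of squared gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import ModelParams, forward_batch, init_params
from .preprocess import WindowSet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "RmspropState",
    "TrainingDivergedError",
    "cross_entropy",
    "bptt_gradients",
    "rmsprop_update",
    "grad_global_norm",
    "clip_gradients",
    "train",
]

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # floor inside log; keeps the loss finite


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: "TrainHistory"):
        super().__init__(message)
        self.history = history


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``batch_windows`` is the number of windows per parameter update; one
    epoch is a full shuffled pass over all windows.  ``grad_clip`` is a
    global-norm ceiling applied to the gradient before the update
    (``None`` disables clipping).  ``checkpoint_epochs`` lists epochs at
    which a deep copy of the parameters is kept (epoch 0 = initialization),
    so the model's learning history can be replayed by synthesizing from
    each snapshot.
    """

    n_steps: int
    hidden_dim: int
    epochs: int
    batch_windows: int = 32
    eta: float = 1e-3
    gamma: float = 0.9
    epsilon: float = 1e-8
    grad_clip: float | None = 5.0
    checkpoint_epochs: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_windows < 1:
            raise ValueError("batch_windows must be >= 1")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        self.checkpoint_epochs = tuple(sorted(self.checkpoint_epochs))


@dataclass
class TrainHistory:
    """Per-epoch mean loss / gradient norm and parameter snapshots."""

    losses: list[float] = field(default_factory=list)
    grad_norms: list[float] = field(default_factory=list)
    checkpoints: dict[int, ModelParams] = field(default_factory=dict)


@dataclass
class RmspropState:
    """Running average of squared gradients plus the optimizer constants."""

    avg_sq_grad: dict[str, np.ndarray]
    eta: float = 1e-3
    gamma: float = 0.9
    epsilon: float = 1e-8

    @classmethod
    def zeros_like(cls, params: ModelParams, eta: float = 1e-3,
                   gamma: float = 0.9, epsilon: float = 1e-8) -> "RmspropState":
        return cls(
            avg_sq_grad={k: np.zeros_like(v) for k, v in params.to_dict().items()},
            eta=eta, gamma=gamma, epsilon=epsilon,
        )


def cross_entropy(outputs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log probability assigned to the true next steps.

    ``outputs`` is ``(N, S_D)`` probability rows (or ``(D, W, S_D)``),
    ``labels`` the matching integer steps.  Probabilities below 1e-12 are
    floored so the loss stays finite; the event is logged.
    """
    outputs = np.asarray(outputs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    flat_o = outputs.reshape(-1, outputs.shape[-1])
    flat_y = labels.reshape(-1)
    if flat_o.shape[0] != flat_y.shape[0]:
        raise ValueError("outputs and labels length mismatch")
    if flat_y.size and (flat_y.min() < 0 or flat_y.max() >= flat_o.shape[1]):
        raise ValueError("labels outside the step alphabet")
    p = flat_o[np.arange(flat_y.size), flat_y]
    if np.any(p < PROB_FLOOR):
        logger.warning("clamped %d probabilities below %.0e in cross-entropy",
                       int(np.sum(p < PROB_FLOOR)), PROB_FLOOR)
        p = np.maximum(p, PROB_FLOOR)
    return float(-np.mean(np.log(p)))


def bptt_gradients(
    params: ModelParams, X_batch: np.ndarray, Y_batch: np.ndarray
) -> tuple[dict[str, np.ndarray], float]:
    """Exact loss gradients for a batch of windows, by BPTT.

    Returns ``(grads, loss)`` where ``grads`` maps each parameter array
    name (as in :meth:`ModelParams.to_dict`) to the derivative of the
    batch-mean cross-entropy, averaged over windows and samples.
    """
    X = np.asarray(X_batch, dtype=np.int64)
    Y = np.asarray(Y_batch, dtype=np.int64)
    if X.ndim != 2 or X.shape != Y.shape:
        raise ValueError("X_batch and Y_batch must be equal-shape (D, W)")
    if X.shape[0] < 1:
        raise ValueError("batch must be nonempty")
    D, W = X.shape
    S = params.n_steps

    probs, _, cache = forward_batch(X, params, return_cache=True)
    loss = cross_entropy(probs, Y)

    grads = {k: np.zeros_like(v) for k, v in params.to_dict().items()}
    dE_T = np.zeros_like(params.E.T)  # row k = grad of embedding of step k
    V = params.V
    layers = params.layers
    scale = 1.0 / (D * W)

    dh = [np.zeros((D, params.hidden_dim)) for _ in range(len(layers))]
    eye = np.eye(S)
    for n in range(W - 1, -1, -1):
        dout = (probs[:, n, :] - eye[Y[:, n]]) * scale  # softmax+CE combined
        grads["b_o"] += dout.sum(axis=0)
        grads["V"] += cache["h_top"][n].T @ dout
        dh[-1] += dout @ V.T
        dx = None
        for l in range(len(layers) - 1, -1, -1):
            layer = layers[l]
            r = cache["r"][l][n]
            z = cache["z"][l][n]
            hc = cache["hc"][l][n]
            hp = cache["h_prev"][l][n]
            x_in = cache["xhat"][n] if l == 0 else cache["inputs"][l][n]
            d = dh[l]

            da_z = d * (hp - hc) * z * (1.0 - z)
            da_h = d * (1.0 - z) * (1.0 - hc * hc)
            drh = da_h @ layer.U_h
            da_r = drh * hp * r * (1.0 - r)

            pre = f"gru{l}."
            grads[pre + "W_h"] += da_h.T @ x_in
            grads[pre + "U_h"] += da_h.T @ (r * hp)
            grads[pre + "W_r"] += da_r.T @ x_in
            grads[pre + "U_r"] += da_r.T @ hp
            grads[pre + "W_z"] += da_z.T @ x_in
            grads[pre + "U_z"] += da_z.T @ hp

            dh[l] = d * z + drh * r + da_r @ layer.U_r + da_z @ layer.U_z
            dx = da_r @ layer.W_r + da_z @ layer.W_z + da_h @ layer.W_h
            if l > 0:
                dh[l - 1] += dx
        np.add.at(dE_T, X[:, n], dx)
    grads["E"] = dE_T.T

    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in parameter '{name}'")
    return grads, loss


def grad_global_norm(grads: dict[str, np.ndarray]) -> float:
    """Euclidean norm of the concatenation of all gradient arrays."""
    return float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))


def clip_gradients(
    grads: dict[str, np.ndarray], max_norm: float
) -> tuple[dict[str, np.ndarray], float]:
    """Scale all gradients so their global norm is at most ``max_norm``."""
    norm = grad_global_norm(grads)
    if norm > max_norm > 0:
        factor = max_norm / norm
        grads = {k: g * factor for k, g in grads.items()}
    return grads, norm


def rmsprop_update(
    params: ModelParams,
    grads: dict[str, np.ndarray],
    state: RmspropState,
) -> tuple[ModelParams, RmspropState]:
    """One RMSprop step, elementwise::

        E(g^2)_t = gamma * E(g^2)_{t-1} + (1 - gamma) * g_t^2
        theta    = theta - eta * g_t / sqrt(E(g^2)_t + epsilon)
    """
    arrays = params.to_dict()
    if set(arrays) != set(grads) or set(arrays) != set(state.avg_sq_grad):
        raise ValueError("params, grads and optimizer state are not congruent")
    new_arrays = {}
    for k, theta in arrays.items():
        g = grads[k]
        acc = state.avg_sq_grad[k]
        acc *= state.gamma
        acc += (1.0 - state.gamma) * g * g
        new_arrays[k] = theta - state.eta * g / np.sqrt(acc + state.epsilon)
    return ModelParams.from_dict(new_arrays), state


def train(
    dataset: WindowSet,
    config: TrainConfig,
    init: ModelParams | None = None,
) -> tuple[ModelParams, TrainHistory]:
    """Fit the model to a windowed dataset.

    Each epoch shuffles the windows (seeded) and performs one RMSprop
    update per mini-batch of ``config.batch_windows`` windows.  Hidden
    state starts at zero for every window.  Checkpoints are deep copies
    taken at the configured epochs; epoch 0 is the initialization.
    """
    X, Y = dataset.X, dataset.Y
    if X.shape[0] < 1:
        raise ValueError("dataset has no windows")
    if X.max() >= config.n_steps or Y.max() >= config.n_steps:
        raise ValueError("dataset steps exceed the configured alphabet")

    params = init.copy() if init is not None else init_params(
        config.n_steps, config.hidden_dim, config.seed)
    params.validate()
    opt = RmspropState.zeros_like(
        params, eta=config.eta, gamma=config.gamma, epsilon=config.epsilon)
    history = TrainHistory()
    if 0 in config.checkpoint_epochs:
        history.checkpoints[0] = params.copy()

    rng = np.random.default_rng(config.seed)
    n_win = X.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n_win)
        batch_losses, batch_norms = [], []
        for start in range(0, n_win, config.batch_windows):
            idx = order[start:start + config.batch_windows]
            grads, loss = bptt_gradients(params, X[idx], Y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became non-finite at epoch {epoch}", history)
            if config.grad_clip is not None:
                grads, norm = clip_gradients(grads, config.grad_clip)
            else:
                norm = grad_global_norm(grads)
            params, opt = rmsprop_update(params, grads, opt)
            batch_losses.append(loss)
            batch_norms.append(norm)
        history.losses.append(float(np.mean(batch_losses)))
        history.grad_norms.append(float(np.mean(batch_norms)))
        logger.info("epoch %d  loss %.5f  grad-norm %.3f",
                    epoch, history.losses[-1], history.grad_norms[-1])
        if epoch in config.checkpoint_epochs:
            history.checkpoints[epoch] = params.copy()
    return params, history
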