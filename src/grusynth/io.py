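"""Readers and writers: signal files, model checkpoints, window datasets.

Signals are interchanged as a single numeric column (plain text or CSV,
optional header); the sampling rate travels in configuration, never
inferred from the file.  Checkpoints and preprocessed datasets are NumPy
``.npz`` containers with a format-version tag and JSON metadata; loading a
checkpoint re-validates every shape invariant so a truncated or
incompatible file fails loudly.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path

import numpy as np

from .network import ModelParams
from .preprocess import WindowSet

__all__ = [
    "read_signal",
    "write_signal",
    "save_model",
    "load_model",
    "save_dataset",
    "load_dataset",
    "CorruptCheckpointError",
]

CHECKPOINT_VERSION = 1
DATASET_VERSION = 1


class CorruptCheckpointError(RuntimeError):
    """A checkpoint file is unreadable, truncated or violates invariants."""


def read_signal(path: str | Path) -> np.ndarray:
    """Read a one-amplitude-per-line signal file.

    A single non-numeric first line is treated as a header; a non-numeric
    value anywhere else raises a parse error naming the line.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip().rstrip(",")
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header row
                raise ValueError(
                    f"{path}: non-numeric value on line {lineno}: {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no numeric samples found")
    return np.asarray(values, dtype=np.float64)


def write_signal(samples: np.ndarray, path: str | Path,
                 header: str | None = None) -> None:
    """Write one amplitude per line (optionally with a header row)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(header + "\n")
        for v in np.asarray(samples).ravel():
            fh.write(f"{v:.10g}\n")


def save_model(params: ModelParams, metadata: dict, path: str | Path) -> None:
    """Save parameters plus metadata (S_D, H_D, seed, s_min/s_max, rate...)."""
    params.validate()
    arrays = {k.replace(".", "__"): v for k, v in params.to_dict().items()}
    meta = dict(metadata)
    meta.setdefault("n_steps", params.n_steps)
    meta.setdefault("hidden_dim", params.hidden_dim)
    np.savez(
        path,
        __version__=np.int64(CHECKPOINT_VERSION),
        __metadata__=json.dumps(meta),
        **arrays,
    )


def load_model(path: str | Path) -> tuple[ModelParams, dict]:
    """Load a checkpoint; returns (params, metadata).

    Raises :class:`CorruptCheckpointError` on version mismatch, missing
    arrays, or shape-invariant violations.
    """
    try:
        with np.load(path, allow_pickle=False) as data:
            if "__version__" not in data:
                raise CorruptCheckpointError(f"{path}: not a model checkpoint")
            version = int(data["__version__"])
            if version != CHECKPOINT_VERSION:
                raise CorruptCheckpointError(
                    f"{path}: checkpoint version {version} unsupported")
            meta = json.loads(str(data["__metadata__"]))
            arrays = {
                k.replace("__", "."): data[k]
                for k in data.files
                if k not in ("__version__", "__metadata__")
            }
    except (OSError, ValueError, KeyError, EOFError, zipfile.BadZipFile) as exc:
        raise CorruptCheckpointError(f"{path}: unreadable checkpoint ({exc})") from exc
    try:
        params = ModelParams.from_dict(arrays)
    except (ValueError, KeyError) as exc:
        raise CorruptCheckpointError(f"{path}: invalid parameters ({exc})") from exc
    return params, meta


def save_dataset(ws: WindowSet, meta: dict, path: str | Path) -> None:
    """Save a preprocessed window dataset (X, Y + quantization metadata)."""
    np.savez(
        path,
        __version__=np.int64(DATASET_VERSION),
        __metadata__=json.dumps({**meta, "window": ws.window, "hop": ws.hop}),
        X=ws.X,
        Y=ws.Y,
    )


def load_dataset(path: str | Path) -> tuple[WindowSet, dict]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__metadata__"]))
        ws = WindowSet(X=data["X"], Y=data["Y"],
                       window=int(meta["window"]), hop=int(meta["hop"]))
    return ws, meta
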