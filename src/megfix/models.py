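"""Compact CNN decoders for single-trial MEG classification.

Two variants share the same skeleton:

* a **spatial** layer projecting the ``n_channels``-dimensional sensor signal
  onto ``k`` latent source time courses (``S = W^T X``, no bias, so the learnt
  ``W`` is interpretable as a bank of spatial filters),
* a **temporal** layer of length-``l_filt`` convolutions ("same" padding) —
  LF applies one independent FIR filter per source (no cross-source mixing);
  VAR lets every output source be a filtered combination of all ``k`` inputs
  (a vector-autoregressive view of the latent dynamics),
* ReLU, non-overlapping max-pooling over ``pool`` adjacent samples, dropout,
  and a single fully-connected layer with softmax over the two classes.

Training minimizes binary cross-entropy with Adam (defaults: batch 100,
learning rate 3e-4), with dropout before the dense layer and an l1 penalty on
both convolutional layers' weights.  Validation ROC AUC is recorded after
every mini-batch update ("training iteration"); the weights at the best
validation point are restored at the end when a validation set is supplied.

Everything is plain NumPy: the networks are small (tens of thousands of
parameters), gradients are written out analytically, and runs are
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import DegenerateTrainingError, InvalidArchitectureError
from .preprocessing import EpochSet

__all__ = ["ModelConfig", "TrainedModel", "build_model", "train", "predict_proba", "save_model", "load_model"]

LF = "LF"
VAR = "VAR"


@dataclass(frozen=True)
class ModelConfig:
    k: int = 16  # latent sources
    l_filt: int = 14  # temporal filter length (samples)
    pool: int = 4  # max-pool width = stride
    dropout_rate: float = 0.5
    l1_penalty: float = 3e-4
    learning_rate: float = 3e-4
    batch_size: int = 100
    max_iterations: int = 1000
    seed: int = 0
    dtype: str = "float32"  # training precision; float64 available for checks

    def __post_init__(self) -> None:
        if self.k < 1 or self.l_filt < 1 or self.pool < 1:
            raise InvalidArchitectureError("k, l_filt and pool must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidArchitectureError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise InvalidArchitectureError("learning_rate must be positive")
        if self.l1_penalty < 0:
            raise InvalidArchitectureError("l1_penalty must be >= 0")


@dataclass
class TrainedModel:
    """Weights plus enough metadata to rebuild the computation graph."""

    variant: str
    config: ModelConfig
    n_channels: int
    n_times: int
    params: dict[str, np.ndarray]
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))  # per-iteration validation AUC
    best_iteration: int | None = None
    trained: bool = False

    @property
    def W(self) -> np.ndarray:
        """Spatial filters, channels x k."""
        return self.params["W"]

    @property
    def temporal_filters(self) -> np.ndarray:
        """LF: (k, l_filt); VAR: (k_out, k_in, l_filt)."""
        return self.params["H"]

    @property
    def output_weights(self) -> np.ndarray:
        """Dense-layer weights, pooled-time x k x 2."""
        return self.params["w_out"]

    @property
    def n_pooled(self) -> int:
        return self.n_times // self.config.pool


def build_model(variant: str, n_channels: int, n_times: int, config: ModelConfig) -> TrainedModel:
    """Initialize an untrained model (small seeded Gaussian weights)."""
    if variant not in (LF, VAR):
        raise InvalidArchitectureError(f"unknown variant {variant!r}")
    if n_times <= config.l_filt:
        raise InvalidArchitectureError(f"n_times ({n_times}) must exceed l_filt ({config.l_filt})")
    k, L, pool = config.k, config.l_filt, config.pool
    n_pooled = n_times // pool
    if n_pooled < 1:
        raise InvalidArchitectureError("pool width exceeds the epoch length")
    rng = np.random.default_rng(config.seed)
    dt = np.dtype(config.dtype)
    params = {
        "W": rng.normal(0.0, 1.0 / np.sqrt(n_channels), (n_channels, k)).astype(dt),
        "H": (
            rng.normal(0.0, 1.0 / np.sqrt(L), (k, L))
            if variant == LF
            else rng.normal(0.0, 1.0 / np.sqrt(k * L), (k, k, L))
        ).astype(dt),
        "b_temp": np.zeros(k, dtype=dt),
        "w_out": rng.normal(0.0, 1.0 / np.sqrt(n_pooled * k), (n_pooled, k, 2)).astype(dt),
        "b_out": np.zeros(2, dtype=dt),
    }
    return TrainedModel(variant=variant, config=config, n_channels=n_channels, n_times=n_times, params=params)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _pad_lr(L: int) -> tuple[int, int]:
    # "same" convolution padding for filter length L
    return (L - 1) // 2, L - (L - 1) // 2


def _windows(S: np.ndarray, L: int) -> np.ndarray:
    """(B, k, T) -> sliding windows (B, k, T, L) with same padding."""
    pl, pr = _pad_lr(L)
    Spad = np.pad(S, ((0, 0), (0, 0), (pl, pr - 1)))
    return np.lib.stride_tricks.sliding_window_view(Spad, L, axis=-1)


def _forward(model: TrainedModel, X: np.ndarray, dropout_mask: np.ndarray | None = None):
    """Forward pass; returns (probabilities, cache for backprop)."""
    p = model.params
    cfg = model.config
    L, pool = cfg.l_filt, cfg.pool
    n_pooled = model.n_pooled

    # spatial projection: S = W^T X, batched as (B,T,C) @ (C,k)
    S = (X.transpose(0, 2, 1) @ p["W"]).transpose(0, 2, 1)  # (B, k, T)
    win = _windows(S, L)  # (B, k, T, L)
    if model.variant == LF:
        Y = np.einsum("bktl,kl->bkt", win, p["H"])
    else:
        Y = np.einsum("bjtl,kjl->bkt", win, p["H"])
    Z = Y + p["b_temp"][None, :, None]
    R = np.maximum(Z, 0.0)

    Rt = R[..., : n_pooled * pool].reshape(R.shape[0], cfg.k, n_pooled, pool)
    pool_idx = Rt.argmax(axis=-1)
    F = np.take_along_axis(Rt, pool_idx[..., None], axis=-1)[..., 0]  # (B, k, P)
    Fd = F if dropout_mask is None else F * dropout_mask
    # dense: logits[b,c] = sum_{p,s} w_out[p,s,c] * Fd[b,s,p]
    logits = np.einsum("bkp,pkc->bc", Fd, p["w_out"]) + p["b_out"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    cache = (X, win, Z, pool_idx, Fd, dropout_mask, probs)
    return probs, cache


def _backward(model: TrainedModel, cache, y: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of mean cross-entropy + l1 on conv weights."""
    p = model.params
    cfg = model.config
    L, pool, k = cfg.l_filt, cfg.pool, cfg.k
    X, win, Z, pool_idx, Fd, dropout_mask, probs = cache
    B = X.shape[0]
    n_pooled = model.n_pooled

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    grads = {}
    grads["w_out"] = np.einsum("bkp,bc->pkc", Fd, dlogits)
    grads["b_out"] = dlogits.sum(axis=0)

    dFd = np.einsum("pkc,bc->bkp", p["w_out"], dlogits)
    dF = dFd if dropout_mask is None else dFd * dropout_mask

    # max-pool backward: route gradient to the argmax sample of each window
    dRt = np.zeros((B, k, n_pooled, pool))
    np.put_along_axis(dRt, pool_idx[..., None], dF[..., None], axis=-1)
    dR = np.zeros_like(Z)
    dR[..., : n_pooled * pool] = dRt.reshape(B, k, n_pooled * pool)

    dZ = dR * (Z > 0.0)
    grads["b_temp"] = dZ.sum(axis=(0, 2))

    if model.variant == LF:
        grads["H"] = np.einsum("bkt,bktl->kl", dZ, win)
        Hrev = p["H"][:, ::-1]
        dYwin = _dY_windows(dZ, L)
        dS = np.einsum("bktl,kl->bkt", dYwin, Hrev)
    else:
        grads["H"] = np.einsum("bkt,bjtl->kjl", dZ, win)
        Hrev = p["H"][:, :, ::-1]
        dYwin = _dY_windows(dZ, L)
        dS = np.einsum("bktl,kjl->bjt", dYwin, Hrev)

    # dW[c,s] = sum_{b,t} X[b,c,t] dS[b,s,t]
    C = X.shape[1]
    grads["W"] = X.transpose(1, 0, 2).reshape(C, -1) @ dS.transpose(1, 0, 2).reshape(k, -1).T

    l1 = cfg.l1_penalty
    if l1 > 0:
        grads["W"] = grads["W"] + l1 * np.sign(p["W"])
        grads["H"] = grads["H"] + l1 * np.sign(p["H"])
    return grads


def _dY_windows(dZ: np.ndarray, L: int) -> np.ndarray:
    """Windows of dZ padded for the transpose (full-correlation) convolution."""
    pl, pr = _pad_lr(L)
    dZpad = np.pad(dZ, ((0, 0), (0, 0), (pr - 1, pl)))
    return np.lib.stride_tricks.sliding_window_view(dZpad, L, axis=-1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train(
    model: TrainedModel,
    train_epochs: EpochSet,
    val_epochs: EpochSet | None = None,
    config: ModelConfig | None = None,
    restore_best: bool = True,
) -> TrainedModel:
    """Adam/cross-entropy training, in place; returns the model.

    With a validation set, the validation ROC AUC after every mini-batch
    update is appended to ``model.trace`` and (when ``restore_best``) the
    weights at the earliest trace maximum are restored at the end.
    """
    from .evaluation import roc_auc  # local import; evaluation imports this module

    cfg = model.config if config is None else config
    dt = model.params["W"].dtype
    X = np.ascontiguousarray(train_epochs.data, dtype=dt)
    y = np.asarray(train_epochs.labels, dtype=int)
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training set contains a single class")
    if X.shape[1] != model.n_channels or X.shape[2] != model.n_times:
        raise InvalidArchitectureError("training data shape does not match the model")

    has_val = val_epochs is not None
    if has_val:
        Xv = np.ascontiguousarray(val_epochs.data, dtype=dt)
        yv = np.asarray(val_epochs.labels, dtype=int)

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    batch = min(cfg.batch_size, n)
    keep = 1.0 - cfg.dropout_rate

    params = model.params
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    order = rng.permutation(n)
    pos = 0
    trace: list[float] = []
    best_auc = -np.inf
    best_params = None
    best_iter = None

    for it in range(1, cfg.max_iterations + 1):
        if pos + batch > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + batch]
        pos += batch

        mask = None
        if cfg.dropout_rate > 0:
            mask = ((rng.random((batch, cfg.k, model.n_pooled)) < keep) / keep).astype(dt)
        _, cache = _forward(model, X[idx], dropout_mask=mask)
        grads = _backward(model, cache, y[idx])

        for key, g in grads.items():
            m[key] = beta1 * m[key] + (1 - beta1) * g
            v[key] = beta2 * v[key] + (1 - beta2) * g * g
            mh = m[key] / (1 - beta1**it)
            vh = v[key] / (1 - beta2**it)
            params[key] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)

        if has_val:
            pv, _ = _forward(model, Xv)
            auc = roc_auc(pv[:, 1], yv)
            trace.append(auc)
            if auc > best_auc:
                best_auc = auc
                best_params = {k: p.copy() for k, p in params.items()}
                best_iter = it

    if has_val:
        model.trace = np.asarray(trace)
        model.best_iteration = best_iter
        if restore_best and best_params is not None:
            model.params = best_params
    model.trained = True
    return model


def predict_proba(model: TrainedModel, epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Per-trial softmax class probabilities, shape (n_trials, 2)."""
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs, float)
    if X.ndim != 3 or X.shape[1] != model.n_channels or X.shape[2] != model.n_times:
        raise InvalidArchitectureError(
            f"expected (trials, {model.n_channels}, {model.n_times}), got {X.shape}"
        )
    probs, _ = _forward(model, np.ascontiguousarray(X, dtype=model.params["W"].dtype))
    return probs


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["variant"] = model.variant
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.config))
        f.attrs["n_channels"] = model.n_channels
        f.attrs["n_times"] = model.n_times
        f.attrs["trained"] = model.trained
        if model.best_iteration is not None:
            f.attrs["best_iteration"] = model.best_iteration
        for key, arr in model.params.items():
            f.create_dataset(f"params/{key}", data=arr)
        f.create_dataset("trace", data=model.trace)


def load_model(path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig(**json.loads(f.attrs["config"]))
        model = TrainedModel(
            variant=str(f.attrs["variant"]),
            config=cfg,
            n_channels=int(f.attrs["n_channels"]),
            n_times=int(f.attrs["n_times"]),
            params={key: f[f"params/{key}"][()] for key in f["params"]},
            trace=f["trace"][()],
            best_iteration=int(f.attrs["best_iteration"]) if "best_iteration" in f.attrs else None,
            trained=bool(f.attrs["trained"]),
        )
    return model
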