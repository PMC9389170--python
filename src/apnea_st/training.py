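"""Mini-batch training of the network: Adam on binary cross-entropy with
per-epoch validation checkpointing, plus minority oversampling and
fine-tuning for second-dataset transfer.

The optimizer implements the rearranged bias-corrected Adam step

    m_t = b1 m_{t-1} + (1-b1) g
    v_t = b2 v_{t-1} + (1-b2) g^2
    theta_t = theta_{t-1} - lr * sqrt(1-b2^t) / (1-b1^t) * m_t / (sqrt(v_t) + eps)

and the loss is J = -(1/n) sum[y ln p + (1-y) ln(1-p)] on the SA-class
probability, clipped away from {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ShapeError
from .model import Model, model_forward
from .preprocessing import WindowSet

__all__ = [
    "TrainConfig",
    "AdamState",
    "TrainResult",
    "bce_loss",
    "adam_update",
    "train",
    "oversample_minority",
    "finetune",
]

_CLIP_EPS = 1e-7  # probability clipping inside the loss, avoids log(0)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published protocol."""

    epochs: int = 40
    learning_rate: float = 0.001
    batch_size: int = 128
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("beta1 and beta2 must lie in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class AdamState:
    """First/second moment estimates and the step counter; m0 = v0 = 0."""

    m: list = field(default_factory=list)
    v: list = field(default_factory=list)
    t: int = 0

    @classmethod
    def for_params(cls, params: list[np.ndarray]) -> "AdamState":
        return cls(m=[np.zeros_like(p) for p in params], v=[np.zeros_like(p) for p in params], t=0)


def bce_loss(y: np.ndarray, y_hat: np.ndarray, clip_eps: float = _CLIP_EPS) -> float:
    """Binary cross-entropy of predicted SA probabilities against 0/1 labels."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ShapeError(f"labels {y.shape} and probabilities {y_hat.shape} differ")
    p = np.clip(y_hat, clip_eps, 1.0 - clip_eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _bce_loss_graph(y: np.ndarray, p_sa: Tensor) -> Tensor:
    p = ad.clip(p_sa, _CLIP_EPS, 1.0 - _CLIP_EPS)
    yt = Tensor(np.asarray(y, dtype=float))
    return -((yt * ad.log(p) + (1.0 - yt) * ad.log(1.0 - p)).mean())


def adam_update(
    params: list[np.ndarray],
    grads: list[np.ndarray],
    state: AdamState,
    cfg: TrainConfig,
) -> list[np.ndarray]:
    """One Adam step over a parameter list; mutates ``state``, returns new parameters."""
    state.t += 1
    t = state.t
    correction = np.sqrt(1.0 - cfg.beta2**t) / (1.0 - cfg.beta1**t)
    out = []
    for i, (p, g) in enumerate(zip(params, grads)):
        state.m[i] = cfg.beta1 * state.m[i] + (1 - cfg.beta1) * g
        state.v[i] = cfg.beta2 * state.v[i] + (1 - cfg.beta2) * g**2
        out.append(p - cfg.learning_rate * correction * state.m[i] / (np.sqrt(state.v[i]) + cfg.eps))
    return out


@dataclass
class TrainResult:
    best_weights: list[np.ndarray]
    history: dict
    best_epoch: int
    best_val_accuracy: float


def _val_accuracy(model: Model, ws: WindowSet) -> float:
    probs = model_forward(model, ws.X)
    pred = probs.argmax(axis=1)
    return float(np.mean(pred == ws.y))


def train(model: Model, train_ws: WindowSet, val_ws: WindowSet, cfg: TrainConfig) -> TrainResult:
    """Seeded mini-batch Adam training with best-on-validation checkpointing.

    After each epoch the validation accuracy is computed; the weights are
    checkpointed whenever it strictly improves (ties keep the earlier
    checkpoint).  With ``cfg.epochs == 0`` the initial weights are returned
    untouched with an empty history.
    """
    if len(train_ws) == 0 or len(val_ws) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    params = model.params()
    state = AdamState.for_params([p.data for p in params])
    best_weights = model.get_weights()
    best_acc = -np.inf
    best_epoch = -1
    history: dict = {"train_loss": [], "val_accuracy": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_ws))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = model.forward(train_ws.X[idx], training=True, rng=rng)
            loss = _bce_loss_graph(train_ws.y[idx], probs[:, 1])
            for p in params:
                p.zero_grad()
            loss.backward()
            grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in params]
            new = adam_update([p.data for p in params], grads, state, cfg)
            for p, w in zip(params, new):
                p.data = w
            losses.append(float(loss.data))
        val_acc = _val_accuracy(model, val_ws)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return TrainResult(
        best_weights=best_weights,
        history=history,
        best_epoch=best_epoch,
        best_val_accuracy=float(best_acc) if np.isfinite(best_acc) else float("nan"),
    )


def oversample_minority(ws: WindowSet, seed: int = 0) -> WindowSet:
    """Duplicate minority-class windows (with replacement) to balance classes."""
    classes, counts = np.unique(ws.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires both classes present")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    deficit = int(counts.max() - counts.min())
    pool = np.flatnonzero(ws.y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(ws)), extra])
    rng.shuffle(idx)
    return ws.subset(idx)


def finetune(
    model: Model,
    pretrained_weights: list[np.ndarray],
    train_ws: WindowSet,
    val_ws: WindowSet,
    cfg: TrainConfig,
) -> TrainResult:
    """Continue training from a checkpoint (e.g. for second-dataset transfer).

    Identical to :func:`train` but initialized from ``pretrained_weights``;
    incompatible shapes raise :class:`~apnea_st.errors.ShapeError`.
    """
    model.set_weights(pretrained_weights)
    if cfg.epochs == 0:
        return TrainResult(
            best_weights=[w.copy() for w in pretrained_weights],
            history={"train_loss": [], "val_accuracy": []},
            best_epoch=-1,
            best_val_accuracy=float("nan"),
        )
    return train(model, train_ws, val_ws, cfg)
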