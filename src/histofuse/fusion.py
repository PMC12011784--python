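"""Deep/handcrafted feature fusion and the feed-forward ANN classifier.

Per image, the two backbone CLS vectors are each concatenated with the
818-dimensional handcrafted vector (deep features first), giving a
small-branch and a large-branch fused vector (1,202 and 1,586 under the
paper-width preset).  By default a single multilayer perceptron consumes the
combined concatenation of both branch vectors; a per-branch mode trains one
MLP per branch and averages their softmax outputs.

The MLP has one hidden layer with ReLU activation and a two-class softmax
output, trained by minibatch Adam on the cross-entropy, with optional
per-feature standardisation fitted on the training split only and early
stopping on the validation loss.  The returned model is the snapshot of the
best validation epoch.  Training is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .backbone import DeepFeatures
from .features import HANDCRAFTED_DIM

__all__ = [
    "FusedVector",
    "TrainConfig",
    "TrainHistory",
    "AnnModel",
    "fuse_features",
    "train_ann",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class FusedVector:
    """Per-branch deep||handcrafted concatenations and their combination."""

    branch_small: np.ndarray
    branch_large: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.branch_small, self.branch_large])


def fuse_features(deep: DeepFeatures, hand: np.ndarray) -> FusedVector:
    """Concatenate deep CLS features with the handcrafted vector per branch."""
    hand = np.asarray(hand, dtype=np.float64)
    if hand.shape != (HANDCRAFTED_DIM,):
        raise ValueError(
            f"handcrafted vector must have length {HANDCRAFTED_DIM}, got {hand.shape}")
    return FusedVector(
        branch_small=np.concatenate([np.asarray(deep.z_cls_small, dtype=np.float64), hand]),
        branch_large=np.concatenate([np.asarray(deep.z_cls_large, dtype=np.float64), hand]),
    )


@dataclass(frozen=True)
class TrainConfig:
    """ANN training hyperparameters."""

    hidden_units: int = 128
    max_epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    early_stop_patience: int = 20
    seed: int = 0
    standardize: bool = True

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience cannot exceed max_epochs")


@dataclass
class TrainHistory:
    """Per-epoch cross-entropy curves and the best-validation epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))

    @property
    def best_val_loss(self) -> float:
        return float(np.min(self.val_loss))


@dataclass
class AnnModel:
    """A trained single-hidden-layer MLP plus its standardisation statistics."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]


def _standardize_stats(x: np.ndarray, enabled: bool):
    if not enabled:
        return np.zeros(x.shape[1]), np.ones(x.shape[1])
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return mean, std


def _ce_loss(x: np.ndarray, y: np.ndarray, w1, b1, w2, b2) -> float:
    h = np.maximum(x @ w1 + b1, 0.0)
    logits = h @ w2 + b2
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].mean())


def train_ann(train_features, train_labels, val_features, val_labels,
              config: TrainConfig) -> tuple[AnnModel, TrainHistory]:
    """Train the MLP; returns the best-validation-epoch snapshot and history.

    Labels use the {1 = normal, 2 = malignant} coding.  Raises if the
    training labels contain only one class or feature widths disagree.
    """
    x_tr = np.asarray(train_features, dtype=np.float64)
    x_va = np.asarray(val_features, dtype=np.float64)
    y_tr = np.asarray(train_labels, dtype=int) - 1
    y_va = np.asarray(val_labels, dtype=int) - 1
    if x_tr.shape[1] != x_va.shape[1]:
        raise ValueError("train and validation feature widths differ")
    if np.unique(y_tr).size < 2:
        raise ValueError("training labels must contain both classes")

    mean, std = _standardize_stats(x_tr, config.standardize)
    x_tr = (x_tr - mean) / std
    x_va = (x_va - mean) / std

    rng = np.random.default_rng(config.seed)
    d, h = x_tr.shape[1], config.hidden_units
    w1 = ad.parameter((d, h), rng, np.sqrt(2.0 / d))
    b1 = ad.parameter(np.zeros(h))
    w2 = ad.parameter((h, 2), rng, np.sqrt(2.0 / h))
    b2 = ad.parameter(np.zeros(2))
    opt = ad.Adam([w1, b1, w2, b2], lr=config.learning_rate)

    history = TrainHistory()
    best = None
    best_loss = np.inf
    since_best = 0
    n = len(y_tr)
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            hidden = ad.relu(ad.linear(ad.Tensor(x_tr[idx]), w1, b1))
            loss = ad.cross_entropy(ad.linear(hidden, w2, b2), y_tr[idx])
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(batch_losses)))
        val_loss = _ce_loss(x_va, y_va, w1.data, b1.data, w2.data, b2.data)
        history.val_loss.append(val_loss)
        if val_loss < best_loss:
            best_loss = val_loss
            best = (w1.data.copy(), b1.data.copy(), w2.data.copy(), b2.data.copy())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
    model = AnnModel(*best, mean=mean, std=std)
    return model, history


def predict(model: AnnModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Class labels {1, 2} and malignant-class probabilities per item.

    Exact probability ties resolve to class 1.  An empty batch yields empty
    outputs.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x[None]
    if x.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0)
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {x.shape[1]} does not match model ({model.n_features})")
    x = (x - model.mean) / model.std
    hidden = np.maximum(x @ model.w1 + model.b1, 0.0)
    logits = hidden @ model.w2 + model.b2
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    labels = np.where(p[:, 1] > p[:, 0], 2, 1)
    return labels, p[:, 1]


def save_model(model: AnnModel, path) -> None:
    np.savez(Path(path), w1=model.w1, b1=model.b1, w2=model.w2, b2=model.b2,
             mean=model.mean, std=model.std)


def load_model(path) -> AnnModel:
    with np.load(Path(path)) as arc:
        return AnnModel(w1=arc["w1"], b1=arc["b1"], w2=arc["w2"], b2=arc["b2"],
                        mean=arc["mean"], std=arc["std"])
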