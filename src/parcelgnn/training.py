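"""Training loop: Adam, mini-batch gradient accumulation, early stopping.

Training minimizes vertex-wise cross-entropy over labeled vertices, summed
over the graphs of a mini-batch before each update. Two regularizers are
applied, mirroring the reference protocol: an optimizer weight-decay rate
(0.0005, added to the gradient) and an explicit L2 penalty on the weights
(0.005, added to the loss). The model with the lowest validation loss seen
so far is retained; training stops when the validation loss has not
strictly improved for ``patience`` epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from parcelgnn.autograd import Tensor
from parcelgnn.features import FeatureMatrix
from parcelgnn.labels import LabelMap
from parcelgnn.models import ModelSpec, TrainedModel, forward, init_params
from parcelgnn.surface import SurfaceGraph

__all__ = ["TrainingConfig", "Dataset", "cross_entropy_loss", "train"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    max_epochs: int = 1000
    patience: int = 150
    batch_graphs: int = 10
    learning_rate: float = 0.01
    weight_decay: float = 0.0005
    l2_penalty: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.batch_graphs < 1:
            raise ValueError("batch_graphs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class Dataset:
    """(graph, features, labels) samples plus a train/validation/test split."""

    samples: list[tuple[SurfaceGraph, FeatureMatrix, LabelMap]]
    split: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        widths = {s[1].n_features for s in self.samples}
        if len(widths) > 1:
            raise ValueError(f"feature width differs across samples: {sorted(widths)}")
        for g, x, y in self.samples:
            if not (g.num_vertices == x.n_vertices == y.n_vertices):
                raise ValueError("graph/features/labels disagree on vertex count")

    def subset(self, part: str) -> list[tuple[SurfaceGraph, FeatureMatrix, LabelMap]]:
        return [self.samples[i] for i in self.split.get(part, [])]

    @property
    def feature_width(self) -> int:
        return self.samples[0][1].n_features

    @property
    def num_classes(self) -> int:
        return max(s[2].num_classes for s in self.samples)


def cross_entropy_loss(logits, labels: LabelMap):
    """Mean negative log softmax probability of the true class, labeled vertices only.

    Accepts a raw N x C array or an autograd Tensor; label codes 1..C map to
    class indices 0..C-1 and the unlabeled code contributes nothing.
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    mask = labels.labeled_mask
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no labeled vertices")
    classes = labels.labels[idx] - 1
    if classes.max() >= logits.shape[1]:
        raise ValueError(
            f"label code {classes.max() + 1} exceeds logit width {logits.shape[1]}"
        )
    shift = logits.data.max(axis=1, keepdims=True)
    lse = (logits - shift).exp().sum(axis=1, keepdims=True).log() + shift
    logp = logits - lse
    picked = logp[(idx, classes)]
    return -picked.sum() * (1.0 / idx.size)


class _Adam:
    """Adam with PyTorch-style coupled weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _mean_validation_loss(model: TrainedModel, samples) -> float:
    losses = []
    for g, x, y in samples:
        logits = forward(model, g, x, train_mode=False)
        losses.append(float(cross_entropy_loss(logits, y).data))
    return float(np.mean(losses))


def train(spec: ModelSpec, data: Dataset, cfg: TrainingConfig) -> TrainedModel:
    """Train ``spec`` on ``data`` with the reference optimization protocol.

    Fully reproducible for a fixed ``cfg.seed``: initialization, mini-batch
    shuffling, and dropout all derive from it. Returns the model whose
    weights achieved the lowest validation loss.
    """
    train_samples = data.subset("train")
    val_samples = data.subset("val")
    if not train_samples or not val_samples:
        raise ValueError("train and validation splits must both be non-empty")
    rng = np.random.default_rng(cfg.seed)
    model = TrainedModel(
        spec=spec, params=init_params(spec, seed=int(rng.integers(2**31)))
    )
    opt = _Adam(model.params, cfg.learning_rate, cfg.weight_decay)

    best_val = np.inf
    best_weights = {k: v.data.copy() for k, v in model.params.items()}
    best_epoch = 0
    since_improve = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_graphs):
            batch = order[start : start + cfg.batch_graphs]
            model.zero_grad()
            # gradients accumulate across the graphs of the batch; each
            # graph's tape is freed right after its backward pass
            batch_loss = 0.0
            for i in batch:
                g, x, y = train_samples[i]
                logits = forward(model, g, x, train_mode=True, rng=rng)
                loss = cross_entropy_loss(logits, y) * (1.0 / len(batch))
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {float(loss.data)}"
                    )
                loss.backward()
                batch_loss += float(loss.data)
            if cfg.l2_penalty:
                # L2 penalty cfg.l2_penalty * sum(w^2): closed-form gradient
                for _, w in model.weight_params():
                    batch_loss += cfg.l2_penalty * float((w.data**2).sum())
                    w._accum(2.0 * cfg.l2_penalty * w.data)
            opt.step()
            epoch_losses.append(batch_loss)

        val_loss = _mean_validation_loss(model, val_samples)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        model.training_log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_weights = {k: v.data.copy() for k, v in model.params.items()}
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break

    for k, v in model.params.items():
        v.data = best_weights[k]
    model.training_log.append(
        {"epoch": best_epoch, "train_loss": np.nan, "val_loss": best_val, "best": True}
    )
    return model
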