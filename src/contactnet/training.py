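"""Loss, validation metric, and the training loop.

Training follows the per-example gradient-accumulation scheme: examples
(which may differ in length) are passed through the network one at a time,
their gradients accumulated, and one Adam step taken per batch of eight.
The loss is binary cross-entropy restricted to residue pairs more than
four apart in sequence; validation quality is the Matthews correlation
coefficient at a 0.5 threshold (same separation mask, averaged
per-protein), and training stops when it has not improved for ``patience``
consecutive epochs, returning the best-MCC weights.

During training the network output is symmetrized on the logit scale
(z_sym = (z + z^T)/2) before the sigmoid, so both triangles of the output
receive gradient; at inference time probabilities are averaged over
(i, j)/(j, i) as usual.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, TrainingExample, augment_batch
from .network import ContactNetwork
from .nn import sigmoid

CLAMP = 1e-7


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr: float = 1e-3
    min_sep: int = 5
    patience: int = 10
    max_epochs: int = 100
    mcc_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.lr <= 0 or self.min_sep < 1:
            raise ValueError("invalid training configuration")


def pair_mask(L: int, min_sep: int = 5) -> np.ndarray:
    """Upper-triangle mask of residue pairs with separation >= min_sep."""
    idx = np.arange(L)
    return (idx[None, :] - idx[:, None]) >= min_sep


def masked_bce(pred: np.ndarray, truth: np.ndarray, min_sep: int = 5) -> float:
    """Mean binary cross-entropy over eligible upper-triangle pairs.

    Probabilities are clamped to [1e-7, 1 - 1e-7]; pairs closer than
    ``min_sep`` in sequence are excluded entirely.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    mask = pair_mask(pred.shape[0], min_sep)
    if not mask.any():
        raise ValueError(f"no residue pairs with separation >= {min_sep}")
    p = np.clip(pred[mask], CLAMP, 1 - CLAMP)
    y = truth[mask]
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def mcc(
    pred: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    min_sep: int = 5,
) -> float:
    """Matthews correlation coefficient over eligible pairs; 0 on degenerate margins."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    mask = pair_mask(pred.shape[0], min_sep)
    p = pred[mask] >= threshold
    y = truth[mask].astype(bool)
    tp = float(np.sum(p & y))
    tn = float(np.sum(~p & ~y))
    fp = float(np.sum(p & ~y))
    fn = float(np.sum(~p & y))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def example_loss_and_grad(
    model: ContactNetwork, ex: TrainingExample, min_sep: int, scale: float = 1.0
) -> float:
    """Forward one example, backprop its (scaled) loss; returns the loss.

    The gradient of ``scale * loss`` is accumulated into the model's
    parameter gradients (this is the per-example half of gradient
    accumulation).
    """
    z = model.forward_logits(ex.x)
    z_sym = 0.5 * (z + z.T)
    p = sigmoid(z_sym)
    L = z.shape[0]
    mask = pair_mask(L, min_sep)
    n_elig = int(mask.sum())
    if n_elig == 0:
        raise ValueError("example too short for the separation mask")
    pc = np.clip(p[mask], CLAMP, 1 - CLAMP)
    y = ex.y[mask]
    loss = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
    if not np.isfinite(loss):
        raise TrainingDiverged(f"non-finite loss on example {ex.name!r}")
    # dL/dz_sym = (p - y) / n on masked cells; route through symmetrization
    g = np.zeros((L, L))
    g[mask] = (p[mask] - y) * (scale / n_elig)
    model.backward(0.5 * (g + g.T))
    return loss


@dataclass
class TrainingResult:
    """Outcome of a training run: best weights, metric history, stop epoch."""

    model: ContactNetwork
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_mcc: float = float("-inf")

    def summary(self) -> str:
        lines = [
            f"epochs run        : {len(self.history)}",
            f"best epoch        : {self.best_epoch + 1}",
            f"best val MCC      : {self.best_mcc:.4f}",
            f"parameters        : {self.model.n_parameters}",
            "",
            f"{'epoch':>5} {'train_loss':>11} {'val_mcc':>8}",
        ]
        for h in self.history:
            lines.append(f"{h['epoch'] + 1:>5} {h['train_loss']:>11.5f} {h['val_mcc']:>8.4f}")
        return "\n".join(lines)


def evaluate_mcc(
    model: ContactNetwork, examples: list[TrainingExample], cfg: TrainConfig
) -> float:
    """Per-protein validation MCC, averaged over proteins."""
    vals = [mcc(model.predict(ex.x), ex.y, cfg.mcc_threshold, cfg.min_sep) for ex in examples]
    return float(np.mean(vals))


def train(
    model: ContactNetwork,
    train_set: list[TrainingExample],
    val_set: list[TrainingExample],
    cfg: TrainConfig,
    augment_cfg: AugmentConfig | None = None,
) -> TrainingResult:
    """Optimize the model with Adam, per-example gradient accumulation and
    MCC early stopping; returns the best-validation-MCC checkpoint."""
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be nonempty")
    if augment_cfg is None:
        augment_cfg = AugmentConfig.disabled()
    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer(cfg.lr)
    result = TrainingResult(model=model)
    best_state: dict | None = None
    epochs_without_improvement = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_set))
        losses: list[float] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            batch = augment_batch(batch, augment_cfg, rng)
            opt.zero_grad()
            scale = 1.0 / len(batch)
            for ex in batch:
                losses.append(example_loss_and_grad(model, ex, cfg.min_sep, scale))
            opt.step()
        val_mcc = evaluate_mcc(model, val_set, cfg)
        result.history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_mcc": val_mcc}
        )
        if val_mcc >= result.best_mcc:
            if val_mcc > result.best_mcc:
                epochs_without_improvement = 0
            else:
                epochs_without_improvement += 1
            result.best_mcc = val_mcc
            result.best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
        else:
            epochs_without_improvement += 1
        if epochs_without_improvement >= cfg.patience:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return result
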