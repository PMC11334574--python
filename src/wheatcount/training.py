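"""Count-supervised optimisation: SGD + momentum, multi-step lr decay, L1 loss.

The loop mirrors the standard recipe for count regression: mini-batches of
preprocessed images with scalar count targets, mean-absolute-error loss
(robust to the occasional very dense outlier image), SGD with momentum, and
a MultiStepLR schedule.  After every epoch the model is scored on the
validation set with dropout disabled; the returned weights are those of the
epoch with the lowest validation MAE, never simply the last epoch.

Everything is seeded: parameter init lives in the model seed, while data
order and dropout masks derive from ``TrainConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .metrics import MetricsReport, compute_report
from .model import CountingNetwork

__all__ = ["TrainConfig", "TrainResult", "l1_loss", "train", "evaluate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 0.0
    milestones: tuple[int, ...] = (60, 90)
    gamma: float = 0.1
    clip_norm: float | None = None         # global gradient-norm clip, off by default
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if list(self.milestones) != sorted(set(self.milestones)):
            raise ValueError("milestones must be strictly increasing")


def l1_loss(predictions: nn.Tensor | np.ndarray,
            targets: np.ndarray) -> nn.Tensor:
    """Mean absolute difference between predicted and true counts."""
    p = predictions if isinstance(predictions, nn.Tensor) else nn.Tensor(predictions)
    t = np.asarray(targets, dtype=np.float32)
    if p.shape != t.shape or p.data.size == 0:
        raise ValueError(f"need equal-length nonempty vectors, "
                         f"got {p.shape} and {t.shape}")
    return (p - nn.Tensor(t)).abs().mean()


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


@dataclass
class TrainResult:
    history: list[dict]                    # per epoch: lr, train_loss, val_mae, ...
    best_epoch: int                        # 1-based epoch with minimum val MAE
    best_val_mae: float
    best_state: dict[str, np.ndarray]      # weights at the best epoch


def evaluate(model: CountingNetwork, data: tuple[np.ndarray, np.ndarray],
             batch_size: int = 16) -> MetricsReport:
    """Full-set metrics with dropout disabled; order-invariant."""
    images, counts = data
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    preds = predict_counts(model, images, batch_size)
    return compute_report(preds, counts)


def predict_counts(model: CountingNetwork, images: np.ndarray,
                   batch_size: int = 16) -> np.ndarray:
    out = [model.predict(images[i:i + batch_size]).count
           for i in range(0, len(images), batch_size)]
    return np.concatenate(out)


def train(model: CountingNetwork,
          train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray],
          config: TrainConfig,
          verbose: bool = False) -> TrainResult:
    """Optimise `model` in place and return the best-validation checkpoint."""
    x_train, y_train = train_data
    if len(x_train) == 0 or len(val_data[0]) == 0:
        raise ValueError("train and validation sets must be nonempty")
    y_train = np.asarray(y_train, dtype=np.float32)
    rng = np.random.default_rng(config.seed)
    model.head.dropout.rng = rng           # dropout masks follow the train seed
    opt = nn.SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    sched = nn.MultiStepLR(opt, config.milestones, config.gamma)
    history: list[dict] = []
    best = TrainResult(history=history, best_epoch=0,
                       best_val_mae=float("inf"), best_state={})
    n = len(x_train)
    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            c_hat, _ = model(nn.Tensor(x_train[idx]))
            loss = l1_loss(c_hat, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lower the learning rate ({opt.lr})")
            opt.zero_grad()
            loss.backward()
            if config.clip_norm is not None:
                _clip_grad_norm(opt.params, config.clip_norm)
            opt.step()
            losses.append(float(loss.data))
        report = evaluate(model, val_data, config.batch_size)
        record = {"epoch": epoch, "lr": opt.lr,
                  "train_l1": float(np.mean(losses)),
                  "val_mae": report.mae, "val_rmse": report.rmse}
        history.append(record)
        if verbose:
            print("epoch {epoch:3d}  lr {lr:.2e}  train L1 {train_l1:7.3f}  "
                  "val MAE {val_mae:7.3f}  val RMSE {val_rmse:7.3f}"
                  .format(**record))
        if report.mae < best.best_val_mae:
            best.best_epoch = epoch
            best.best_val_mae = report.mae
            best.best_state = model.state_dict()
        sched.step()
    model.load_state_dict(best.best_state)
    model.eval()
    return best


def save_checkpoint(path: str | Path, model: CountingNetwork,
                    result: TrainResult | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with history and best epoch."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    if result is not None:
        meta = {"best_epoch": result.best_epoch,
                "best_val_mae": result.best_val_mae,
                "history": result.history}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path, model: CountingNetwork) -> CountingNetwork:
    state = np.load(Path(path))
    model.load_state_dict({k: state[k] for k in state.files})
    model.eval()
    return model
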