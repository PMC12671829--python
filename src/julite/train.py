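"""Training loop, learning-rate schedule, checkpointing and evaluation.

The full-scale recipe the architecture is designed for: AdamW (beta1 0.9,
decoupled weight decay 5e-2), initial learning rate 5e-4 with one linear
warm-up epoch followed by cosine decay to zero, batch size 32, 200 epochs,
training from scratch.  Desk-scale runs use the same loop with a smaller
corpus, reduced width and fewer epochs; see docs/methods.md for the sizes
this repository's tests use.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .backbone import JuLiteMobileAtt, ModelSpec, build_ju_lite_mobileatt
from .datapipe import CLASSES, FolderDataset
from .metrics_eval import ConfusionMatrix, MetricsReport, confusion_matrix, metrics_from_cm
from .nn import Tensor

__all__ = [
    "TrainConfig", "TrainingHistory", "evaluate", "load_checkpoint", "lr_at",
    "save_checkpoint", "train",
]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 5e-4
    warmup_epochs: int = 1
    optimizer: str = "adamw"
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 5e-2
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0
    from_scratch: bool = True

    def validate(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.warmup_epochs <= self.epochs:
            raise ValueError("warm-up cannot exceed the training length")


def lr_at(epoch_fraction: float, cfg: TrainConfig) -> float:
    """Learning rate at training progress t in [0, 1].

    Linear ramp from 0 to `initial_lr` over the warm-up fraction w, then
    cosine decay `initial_lr * 0.5 * (1 + cos(pi * (t - w) / (1 - w)))`
    reaching 0 at t = 1.
    """
    t = float(epoch_fraction)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"epoch fraction must lie in [0, 1], got {t}")
    w = cfg.warmup_epochs / cfg.epochs
    if w > 0 and t <= w:
        return cfg.initial_lr * (t / w)
    if w >= 1.0:  # degenerate all-warm-up schedule (single-epoch smoke runs)
        return cfg.initial_lr
    return cfg.initial_lr * 0.5 * (1.0 + math.cos(math.pi * (t - w) / (1.0 - w)))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_accuracy,val_macro_f1,learning_rate,seconds\n")
            for i in range(len(self.train_loss)):
                fh.write(f"{i},{self.train_loss[i]:.6f},{self.val_accuracy[i]:.6f},"
                         f"{self.val_macro_f1[i]:.6f},{self.learning_rate[i]:.8f},"
                         f"{self.epoch_seconds[i]:.2f}\n")


def _iterate_batches(dataset: FolderDataset, rng: np.random.Generator,
                     batch_size: int, epoch: int, dtype):
    order = rng.permutation(len(dataset))
    for start in range(0, len(order), batch_size):
        idx = order[start:start + batch_size]
        xs, ys = zip(*(dataset.get(int(i), epoch=epoch) for i in idx))
        yield np.stack(xs).astype(dtype), np.asarray(ys, dtype=int)


def _predict_dataset(model: nn.Module, dataset: FolderDataset,
                     batch_size: int, dtype) -> tuple[np.ndarray, np.ndarray]:
    model.eval()
    preds, trues = [], []
    with nn.no_grad():
        for start in range(0, len(dataset), batch_size):
            xs, ys = zip(*(dataset.get(i) for i in
                           range(start, min(start + batch_size, len(dataset)))))
            logits = model(Tensor(np.stack(xs).astype(dtype)))
            preds.append(logits.data.argmax(axis=1))
            trues.append(np.asarray(ys))
    return np.concatenate(trues), np.concatenate(preds)


def _default_log(msg: str) -> None:
    print(msg, flush=True)


def train(model: JuLiteMobileAtt, datasets: tuple[FolderDataset, FolderDataset],
          cfg: TrainConfig, out_dir: str | Path | None = None,
          dtype=np.float32, log=_default_log) -> tuple[dict, TrainingHistory]:
    """Train `model` on (train_dataset, validation_dataset).

    Returns (checkpoint, history); the checkpoint holds the weights of the
    best-validation-accuracy epoch.  Cross-entropy objective, AdamW updates,
    per-step cosine schedule via :func:`lr_at`.
    """
    cfg.validate()
    train_ds, val_ds = datasets
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train/validation splits must be non-empty")
    model.astype(dtype).train()
    opt = nn.AdamW(model.parameters(), lr=cfg.initial_lr,
                   betas=(cfg.beta1, cfg.beta2), weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = math.ceil(len(train_ds) / cfg.batch_size)
    total_steps = steps_per_epoch * cfg.epochs
    history = TrainingHistory()
    best = {"val_accuracy": -1.0}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    step = 0
    for epoch in range(cfg.epochs):
        t_start = time.perf_counter()
        model.train()
        losses = []
        for xb, yb in _iterate_batches(train_ds, rng, cfg.batch_size, epoch, dtype):
            opt.lr = lr_at((step + 1) / total_steps, cfg)
            logits = model(Tensor(xb))
            loss = nn.cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
        y_true, y_pred = _predict_dataset(model, val_ds,
                                          max(cfg.batch_size, 128), dtype)
        report = metrics_from_cm(confusion_matrix(y_true, y_pred, len(CLASSES)))
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(report.accuracy)
        history.val_macro_f1.append(report.macro_f1)
        history.learning_rate.append(opt.lr)
        history.epoch_seconds.append(time.perf_counter() - t_start)
        if report.accuracy > best["val_accuracy"]:
            best = {
                "val_accuracy": report.accuracy,
                "val_macro_f1": report.macro_f1,
                "epoch": epoch,
                "state": {k: v.copy() for k, v in model.state_dict().items()},
            }
        log(f"epoch {epoch:3d}  loss {history.train_loss[-1]:.4f}  "
            f"val_acc {report.accuracy:.4f}  val_f1 {report.macro_f1:.4f}  "
            f"lr {opt.lr:.2e}  ({history.epoch_seconds[-1]:.1f}s)")
    checkpoint = {
        "model_spec": model.spec.to_dict(),
        "train_config": asdict(cfg),
        "classes": list(CLASSES),
        "best_epoch": best["epoch"],
        "val_accuracy": best["val_accuracy"],
        "val_macro_f1": best["val_macro_f1"],
        "state": best["state"],
    }
    if out_dir is not None:
        save_checkpoint(checkpoint, out_dir / "checkpoint.npz")
        history.to_csv(out_dir / "history.csv")
    return checkpoint, history


def save_checkpoint(checkpoint: dict, path: str | Path) -> None:
    meta = {k: v for k, v in checkpoint.items() if k != "state"}
    arrays = {f"state/{k}": v for k, v in checkpoint["state"].items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> dict:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    meta["state"] = state
    return meta


def model_from_checkpoint(checkpoint: dict | str | Path) -> JuLiteMobileAtt:
    if not isinstance(checkpoint, dict):
        checkpoint = load_checkpoint(checkpoint)
    spec = ModelSpec.from_dict(checkpoint["model_spec"])
    model = build_ju_lite_mobileatt(spec, seed=0)
    sample = next(iter(checkpoint["state"].values()))
    model.astype(sample.dtype)
    model.load_state_dict(checkpoint["state"])
    return model


def evaluate(checkpoint: dict | str | Path, dataset: FolderDataset,
             batch_size: int = 32,
             out_dir: str | Path | None = None) -> tuple[MetricsReport, ConfusionMatrix]:
    """Deterministic evaluation of a checkpoint on one dataset split."""
    if not isinstance(checkpoint, dict):
        checkpoint = load_checkpoint(checkpoint)
    if list(checkpoint.get("classes", CLASSES)) != list(CLASSES):
        raise ValueError("class vocabulary mismatch between checkpoint and data")
    model = model_from_checkpoint(checkpoint)
    dtype = next(iter(checkpoint["state"].values())).dtype
    y_true, y_pred = _predict_dataset(model, dataset, batch_size, dtype)
    cm = confusion_matrix(y_true, y_pred, len(CLASSES), class_names=CLASSES)
    report = metrics_from_cm(cm)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        cm.to_csv(out_dir / "confusion_matrix.csv")
    return report, cm
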