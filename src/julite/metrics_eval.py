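"""Confusion matrix, one-vs-rest classification metrics, inference timing
and Grad-CAM heatmaps.

Metrics follow the standard per-class one-vs-rest definitions derived from
the confusion matrix (rows = ground truth, columns = predictions):

    recall      = TP / (TP + FN)
    accuracy    = (TP + TN) / total          (multiclass: trace / total)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

Summary values are macro averages (unweighted means over classes), the
natural choice for a class-balanced corpus.  A class whose denominator is
zero scores 0 and is flagged in the report.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor

__all__ = [
    "ConfusionMatrix", "Heatmap", "MetricsReport", "TimingReport",
    "confusion_matrix", "grad_cam", "measure_fps", "metrics_from_cm",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray            # (n, n) int, rows true, cols predicted
    class_names: tuple[str, ...] | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        n = self.counts.shape[0]
        names = self.class_names or tuple(str(i) for i in range(n))
        with open(path, "w") as fh:
            fh.write("true\\pred," + ",".join(names) + "\n")
            for i, row in enumerate(self.counts):
                fh.write(names[i] + "," + ",".join(str(int(v)) for v in row) + "\n")


def confusion_matrix(y_true, y_pred, n_classes: int,
                     class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    t = np.asarray(y_true, dtype=int).ravel()
    p = np.asarray(y_pred, dtype=int).ravel()
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels out of range [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_specificity: float
    macro_f1: float
    degenerate_classes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_specificity": self.macro_specificity,
            "macro_f1": self.macro_f1,
            "per_class": {
                "precision": self.precision.tolist(),
                "recall": self.recall.tolist(),
                "specificity": self.specificity.tolist(),
                "f1": self.f1.tolist(),
            },
            "degenerate_classes": list(self.degenerate_classes),
        }


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.where(den > 0, num / np.maximum(den, 1), 0.0)


def metrics_from_cm(cm: ConfusionMatrix | np.ndarray) -> MetricsReport:
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    total = counts.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
    degenerate = tuple(int(i) for i in np.where((tp + fp == 0) | (tp + fn == 0))[0])
    return MetricsReport(
        accuracy=float(np.trace(counts) / total),
        precision=precision, recall=recall, specificity=specificity, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_specificity=float(specificity.mean()),
        macro_f1=float(f1.mean()),
        degenerate_classes=degenerate,
    )


@dataclass(frozen=True)
class TimingReport:
    mean_inference_time: float   # seconds per sample
    fps: float

    @staticmethod
    def from_time(tm: float) -> "TimingReport":
        if tm <= 0:
            raise ValueError("mean inference time must be positive")
        return TimingReport(mean_inference_time=tm, fps=1.0 / tm)


def measure_fps(model: nn.Module, batch: np.ndarray, n_repeats: int = 5,
                warmup: int = 1) -> TimingReport:
    """Mean per-sample forward time (warm-up iterations excluded)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    model.eval()
    x = Tensor(np.asarray(batch))
    with nn.no_grad():
        for _ in range(warmup):
            model(x)
        t0 = time.perf_counter()
        for _ in range(n_repeats):
            model(x)
        elapsed = time.perf_counter() - t0
    tm = elapsed / (n_repeats * batch.shape[0])
    return TimingReport.from_time(tm)


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray            # (H, W) in [0, 1]
    target_class: int
    target_layer: str


def _find_layer(model: nn.Module, layer: "str | nn.Module") -> tuple[str, nn.Module]:
    if isinstance(layer, nn.Module):
        for name, mod in model.named_modules():
            if mod is layer:
                return name, mod
        raise ValueError("target layer is not part of the model")
    for name, mod in model.named_modules():
        if name == layer:
            return name, mod
    raise ValueError(f"no module named {layer!r} in the model")


def grad_cam(model: nn.Module, image: np.ndarray, target_class: int,
             target_layer: "str | nn.Module" = "tail") -> Heatmap:
    """Gradient-weighted class-activation map.

    Channel weights are the spatial means of the target-class logit's
    gradient w.r.t. the chosen layer's activations; the map is the ReLU of
    the weighted activation sum, bicubically upsampled to the input size and
    min-max normalized to [0, 1].
    """
    name, layer = _find_layer(model, target_layer)
    model.eval()
    captured: list[Tensor] = []
    hook = layer.add_forward_hook(lambda _m, out: captured.append(out))
    try:
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        logits = model(Tensor(x))
        if not 0 <= target_class < logits.shape[1]:
            raise ValueError(f"target_class {target_class} out of range")
        onehot = np.zeros(logits.shape)
        onehot[:, target_class] = 1.0
        logits.backward(onehot)
    finally:
        layer._forward_hooks.remove(hook)
    act = captured[-1]
    if act.grad is None or act.ndim != 4:
        raise ValueError(f"layer {name!r} did not produce a differentiable feature map")
    weights = act.grad.mean(axis=(2, 3))                       # (N, C)
    cam = np.maximum((weights[:, :, None, None] * act.data).sum(axis=1), 0.0)[0]
    h, w = x.shape[2], x.shape[3]
    if cam.shape != (h, w):
        zoom = (h / cam.shape[0], w / cam.shape[1])
        cam = ndimage.zoom(cam, zoom, order=3, grid_mode=True, mode="nearest")
        cam = np.maximum(cam[:h, :w], 0.0)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return Heatmap(values=cam, target_class=int(target_class), target_layer=name)


def save_heatmap_overlay(heatmap: Heatmap, image_rgb: np.ndarray, path,
                         alpha: float = 0.45) -> None:
    """Blend a jet-style colormap of the heatmap onto the image; save PNG."""
    import matplotlib
    from PIL import Image as _Image

    base = np.asarray(image_rgb, dtype=np.float64)
    if base.max() <= 1.0:
        base = base * 255.0
    hm = matplotlib.colormaps["jet"](heatmap.values)[..., :3] * 255.0
    if hm.shape[:2] != base.shape[:2]:
        raise ValueError("heatmap and image sizes differ")
    out = np.clip((1 - alpha) * base + alpha * hm, 0, 255).astype(np.uint8)
    _Image.fromarray(out, "RGB").save(path)
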