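"""Evaluation and privacy metrics.

Privacy of the generated data is probed geometrically (the inf–inf
Euclidean distance between the generated and original sets — large
distances mean no generated image sits near a real one) and perceptually
(the maximum SSIM over all generated/original pairs — values well below 1
mean no generated image visually reproduces a real one). Training-level
fidelity is probed by Dpgo, the absolute difference in mean cross-entropy
loss of a fixed task model between real and generated data: near zero
means the generated data drive the model the way the real data would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from skimage.metrics import structural_similarity

from . import nn

__all__ = [
    "set_distance",
    "max_ssim",
    "dpgo",
    "delta_accuracy_loss",
    "evaluate_accuracy",
    "MetricsReport",
]


def _as_matrix(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a.reshape(a.shape[0], -1)


def set_distance(a: np.ndarray, b: np.ndarray, block: int = 1024) -> float:
    """inf over x∈A, y∈B of ||x − y||₂ (images flattened to vectors).

    Symmetric in its arguments; 0 whenever the sets intersect. Computed
    blockwise so large sets never materialize the full distance matrix.
    """
    a, b = _as_matrix(a), _as_matrix(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both sets must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("elements of A and B must have equal dimension")
    best = np.inf
    for start in range(0, len(a), block):
        d = cdist(a[start : start + block], b)
        best = min(best, float(d.min()))
    return best


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    if img.ndim != 2:
        raise ValueError("expected grayscale images (H, W) or (1, H, W)")
    return img


def max_ssim(a, b, data_range: float = 1.0) -> float:
    """max over all pairs (x∈A, y∈B) of the structural similarity index.

    Standard windowed SSIM with default constants; ``data_range`` follows
    the [0, 1] pixel normalization. Returns 1.0 iff some generated image
    is an exact copy of an original.
    """
    a = [_as_gray(x) for x in a]
    b = [_as_gray(y) for y in b]
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    if a[0].shape != b[0].shape:
        raise ValueError("images in A and B must share one shape")
    best = -1.0
    for x in a:
        for y in b:
            best = max(best, float(structural_similarity(
                x, y, data_range=data_range)))
    return best


def _mean_cross_entropy(model, images: np.ndarray, labels: np.ndarray) -> float:
    logits = model.logits(images, train=False)
    loss, _ = nn.softmax_cross_entropy(logits, labels)
    return float(loss)


def dpgo(model, real_images, real_labels, gen_images, gen_labels,
         batch_size: int = 512) -> float:
    """|E[loss on real] − E[loss on generated]| under fixed parameters.

    Zero when the generated set is the real set; small values mean
    generated data exert the same training pressure as real data.
    """
    real_labels = np.asarray(real_labels)
    gen_labels = np.asarray(gen_labels)
    if len(real_labels) == 0 or len(gen_labels) == 0:
        raise ValueError("both sets must be non-empty and labeled")
    if not set(np.unique(gen_labels)) <= set(range(model.n_classes)):
        raise ValueError("generated labels outside the model's classes")

    def mean_loss(images, labels):
        total, n = 0.0, len(labels)
        for s in range(0, n, batch_size):
            m = len(labels[s : s + batch_size])
            total += _mean_cross_entropy(
                model, images[s : s + batch_size], labels[s : s + batch_size]) * m
        return total / n

    return abs(mean_loss(real_images, real_labels)
               - mean_loss(gen_images, gen_labels))


def delta_accuracy_loss(federated_acc: float, centralized_acc: float) -> float:
    """Federated minus centralized test accuracy, both in percent.

    Negative values mean the federated method beat centralized training
    (possible here because augmentation gives the federation more training
    data than the centralized baseline).
    """
    for v in (federated_acc, centralized_acc):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must be on the percent scale [0, 100]")
    return federated_acc - centralized_acc


def evaluate_accuracy(model, images: np.ndarray, labels: np.ndarray,
                      batch_size: int = 512) -> float:
    """Top-1 accuracy in percent; ties broken toward the lowest class index."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty test set")
    correct = 0
    for s in range(0, len(labels), batch_size):
        logits = model.logits(images[s : s + batch_size], train=False)
        correct += int((logits.argmax(axis=1) == labels[s : s + batch_size]).sum())
    return 100.0 * correct / len(labels)


@dataclass
class MetricsReport:
    """Bundle of everything an experiment measures, serializable to JSON."""

    accuracy_history: list = field(default_factory=list)
    final_accuracy: float | None = None
    pairwise_emd_before: list | None = None
    pairwise_emd_after: list | None = None
    set_distance: float | None = None
    max_ssim: float | None = None
    dpgo: float | None = None
    delta_accuracy_loss: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    def save_accuracy_csv(self, path) -> None:
        lines = ["round,accuracy"]
        lines += [f"{i},{a}" for i, a in enumerate(self.accuracy_history)]
        Path(path).write_text("\n".join(lines) + "\n")
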