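"""Synthetic labeled image datasets for exercising the full pipeline.

Stands in for a small grayscale medical-imaging set: each class is a
deterministic structural motif — a Gaussian blob at a class-specific
position with a class-specific width — under per-sample position jitter,
amplitude variation and additive pixel noise. ``difficulty`` controls the
jitter and noise amplitudes; the "easy" setting is linearly separable
enough for a small CNN to exceed 90% test accuracy within a few epochs,
while keeping enough within-class variation that a VAE has something to
learn.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.stats import truncnorm

__all__ = [
    "ImageDataset",
    "make_image_dataset",
    "make_latent_fixture",
    "save_image_folder",
    "load_image_folder",
    "load_idx",
]

_DIFFICULTY = {
    # (center jitter px, noise std, amplitude std)
    "easy": (1.5, 0.05, 0.1),
    "hard": (3.0, 0.20, 0.15),
}


@dataclass
class ImageDataset:
    train_images: np.ndarray
    train_labels: np.ndarray
    test_images: np.ndarray
    test_labels: np.ndarray
    n_classes: int

    @property
    def input_shape(self):
        return self.train_images.shape[1:]


def _render_class(n: int, label: int, n_classes: int, shape, jitter: float,
                  noise: float, amp_std: float, rng) -> np.ndarray:
    c, h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # class motif: blob center on a circle, width grows with the label
    angle = 2 * np.pi * label / n_classes
    cy0 = h / 2 + (h / 4) * np.sin(angle)
    cx0 = w / 2 + (w / 4) * np.cos(angle)
    width = 0.09 * h * (1 + 0.35 * label)
    images = np.empty((n, c, h, w))
    for i in range(n):
        cy = cy0 + rng.normal(0, jitter)
        cx = cx0 + rng.normal(0, jitter)
        amp = np.clip(rng.normal(0.8, amp_std), 0.3, 1.0)
        blob = amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * width ** 2))
        img = 0.1 + blob + rng.normal(0, noise, size=(h, w))
        images[i] = np.clip(img, 0.0, 1.0)[None]
    return images


def make_image_dataset(n_classes: int = 2, n_per_class: int = 300,
                       shape=(1, 32, 32), difficulty: str = "easy",
                       seed: int = 0,
                       n_test_per_class: int = 100) -> ImageDataset:
    """Generate a stratified train/test image set with class-dependent
    structure; bit-deterministic under ``seed``."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    c, h, w = shape
    if h < 16 or w < 16:
        raise ValueError("images must be at least 16x16")
    if difficulty not in _DIFFICULTY:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    jitter, noise, amp_std = _DIFFICULTY[difficulty]
    rng = np.random.default_rng(seed)
    tr_im, tr_lb, te_im, te_lb = [], [], [], []
    for label in range(n_classes):
        block = _render_class(n_per_class + n_test_per_class, label, n_classes,
                              shape, jitter, noise, amp_std, rng)
        tr_im.append(block[:n_per_class])
        te_im.append(block[n_per_class:])
        tr_lb.append(np.full(n_per_class, label, dtype=int))
        te_lb.append(np.full(n_test_per_class, label, dtype=int))
    train_images = np.concatenate(tr_im)
    train_labels = np.concatenate(tr_lb)
    test_images = np.concatenate(te_im)
    test_labels = np.concatenate(te_lb)
    # one seeded shuffle so class blocks are interleaved
    p = rng.permutation(len(train_labels))
    q = rng.permutation(len(test_labels))
    return ImageDataset(train_images[p], train_labels[p],
                        test_images[q], test_labels[q], n_classes)


def make_latent_fixture(family: str, theta: dict, n: int, d: int,
                        seed: int = 0) -> np.ndarray:
    """Ground-truth latent draws from a known θ (independent of the
    package's own sampler, so estimator-recovery tests have an external
    reference)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, d))
    if family == "uniform":
        return rng.uniform(theta["lower"], theta["upper"], size=(n, d))
    if family == "normal":
        return rng.normal(theta["mean"], theta["std"], size=(n, d))
    if family == "truncated_normal":
        mean = np.broadcast_to(np.asarray(theta["mean"], dtype=float), (d,))
        std = np.broadcast_to(np.asarray(theta["std"], dtype=float), (d,))
        lo = np.broadcast_to(np.asarray(theta["lower"], dtype=float), (d,))
        hi = np.broadcast_to(np.asarray(theta["upper"], dtype=float), (d,))
        a, b = (lo - mean) / std, (hi - mean) / std
        return truncnorm.rvs(a, b, loc=mean, scale=std, size=(n, d),
                             random_state=rng)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# class-subfolder PNG layout
# ---------------------------------------------------------------------------

def save_image_folder(images: np.ndarray, labels: np.ndarray, root) -> None:
    """Write images as ``root/<label>/<index>.png`` (8-bit grayscale/RGB)."""
    root = Path(root)
    for i, (img, label) in enumerate(zip(images, labels)):
        d = root / str(int(label))
        d.mkdir(parents=True, exist_ok=True)
        arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        if arr.shape[0] == 1:
            pil = Image.fromarray(arr[0], mode="L")
        else:
            pil = Image.fromarray(arr.transpose(1, 2, 0), mode="RGB")
        pil.save(d / f"{i:05d}.png")


def load_image_folder(root):
    """Read a class-subfolder layout back into (images, labels, class_names).

    Subfolder names sorted lexicographically define the label indices;
    pixels are normalized to [0, 1], channel-first.
    """
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subfolders under {root}")
    images, labels = [], []
    for label, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg", ".bmp"):
                continue
            arr = np.asarray(Image.open(f), dtype=float) / 255.0
            if arr.ndim == 2:
                arr = arr[None]
            else:
                arr = arr.transpose(2, 0, 1)
            images.append(arr)
            labels.append(label)
    return (np.stack(images), np.asarray(labels, dtype=int),
            [d.name for d in class_dirs])


def load_idx(path) -> np.ndarray:
    """Read an IDX-format array (the MNIST container format)."""
    data = Path(path).read_bytes()
    zero, dtype_code, ndim = data[0], data[2], data[3]
    if zero != 0 or data[1] != 0:
        raise ValueError("not an IDX file")
    dtypes = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.dtype(">i2"),
              0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"),
              0x0E: np.dtype(">f8")}
    if dtype_code not in dtypes:
        raise ValueError(f"unsupported IDX dtype 0x{dtype_code:02x}")
    dims = struct.unpack(f">{ndim}i", data[4 : 4 + 4 * ndim])
    arr = np.frombuffer(data, dtype=dtypes[dtype_code], offset=4 + 4 * ndim)
    return arr.reshape(dims).astype(np.float64 if dtype_code >= 0x0D
                                    else np.int64 if dtype_code > 0x09
                                    else np.uint8)
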