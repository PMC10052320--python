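"""Latent-space mathematics: σ-point expansion, distribution estimation,
and latent sampling.

Each image is encoded to a diagonal-Gaussian posterior (mean m, variance
diag(σ²)). Instead of drawing one noisy reparameterization sample per
image, the posterior is expanded deterministically into 2d σ-points

    z_n = m + α·sqrt(σ²_n)·e_n   (n = 1..d)
    z_n = m − α·sqrt(σ²_n)·e_n   (n = d+1..2d)

borrowed from the unscented transform: their empirical mean is exactly m
and their population covariance is (α²/d)·diag(σ²), so the expanded cloud
carries the posterior's location and spread without ever sampling noise.
A client pools the σ-points of all its images per class, fits a simple
per-dimension distribution family (normal, truncated normal or uniform),
and shares only the fitted parameters θ plus per-class counts — the
``DistributionInfo`` payload — never the images or their encodings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr, ndtri

from .partitioning import ClientDataset

__all__ = [
    "FAMILIES",
    "STD_FLOOR",
    "LatentEncoding",
    "SigmaPointSet",
    "DistributionInfo",
    "encode",
    "encode_dataset",
    "sigma_points",
    "reparameterized_set",
    "estimate_distribution",
    "sample_latent",
    "build_distribution_info",
]

FAMILIES = ("normal", "truncated_normal", "uniform")

# degenerate (zero-variance) dimensions get their std clamped here
STD_FLOOR = 1e-6


@dataclass
class LatentEncoding:
    """Per-image posterior: mean vector and the diagonal of its covariance."""

    mean: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape or self.mean.ndim != 1:
            raise ValueError("mean and variance must be 1-D of equal length")
        if not np.all(self.variance > 0):
            raise ValueError("variance entries must be strictly positive")

    @property
    def d(self) -> int:
        return len(self.mean)


@dataclass
class SigmaPointSet:
    """The 2d deterministic samples for one encoding; row n and row n+d are
    reflections of each other about the mean."""

    points: np.ndarray  # (2d, d)
    alpha: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] != 2 * self.points.shape[1]:
            raise ValueError("expected exactly 2d points of dimension d")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass
class DistributionInfo:
    """The shared payload: family, per-class θ, per-class counts, client id.

    θ records are per-dimension arrays — ``mean``/``std`` for normal,
    ``lower``/``upper`` for uniform, all four for truncated normal. This is
    the only thing a client ever transmits about its data.
    """

    client_id: int
    family: str
    per_class_params: dict = field(default_factory=dict)
    per_class_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if set(self.per_class_params) != set(self.per_class_counts):
            raise ValueError("params and counts must cover the same classes")
        for label, theta in self.per_class_params.items():
            _validate_theta(theta, self.family)
            if self.per_class_counts[label] < 0:
                raise ValueError("class counts must be non-negative")

    @property
    def total_count(self) -> int:
        return int(sum(self.per_class_counts.values()))

    # -- JSON exchange format ------------------------------------------------
    def to_json(self) -> str:
        classes = [
            {
                "label": int(label),
                "count": int(self.per_class_counts[label]),
                "params": {k: np.asarray(v).tolist()
                           for k, v in self.per_class_params[label].items()},
            }
            for label in sorted(self.per_class_params)
        ]
        return json.dumps({
            "client_id": int(self.client_id),
            "family": self.family,
            "total_count": self.total_count,
            "classes": classes,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DistributionInfo":
        doc = json.loads(text)
        params = {c["label"]: {k: np.asarray(v, dtype=float)
                               for k, v in c["params"].items()}
                  for c in doc["classes"]}
        counts = {c["label"]: c["count"] for c in doc["classes"]}
        di = cls(client_id=doc["client_id"], family=doc["family"],
                 per_class_params=params, per_class_counts=counts)
        if di.total_count != doc["total_count"]:
            raise ValueError("total_count does not match the class counts")
        return di

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "DistributionInfo":
        return cls.from_json(Path(path).read_text())


def _validate_theta(theta: dict, family: str) -> None:
    if family in ("normal", "truncated_normal"):
        if np.any(np.asarray(theta["std"]) <= 0):
            raise ValueError("stds must be positive")
    if family in ("uniform", "truncated_normal"):
        lo, hi = np.asarray(theta["lower"]), np.asarray(theta["upper"])
        if np.any(lo > hi):
            raise ValueError("lower bounds must not exceed upper bounds")


# ---------------------------------------------------------------------------
# encoding and σ-point expansion
# ---------------------------------------------------------------------------

def encode(image: np.ndarray, encoder) -> LatentEncoding:
    """Encode one image to its latent mean and (diagonal) variance.

    ``encoder`` is any object with an ``encode(batch) -> (mean, logvar)``
    method and an ``input_shape``; the variance is the exponentiated
    log-variance head, hence strictly positive by construction.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(encoder.input_shape):
        raise ValueError(
            f"image shape {image.shape} does not match encoder input "
            f"{tuple(encoder.input_shape)}")
    mean, logvar = encoder.encode(image[None])
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(logvar))):
        raise FloatingPointError("encoder produced non-finite output")
    return LatentEncoding(mean=mean[0], variance=np.exp(logvar[0]))


def encode_dataset(images: np.ndarray, encoder,
                   batch_size: int = 256):
    """Vectorized encoding: (k, C, H, W) -> means (k, d), variances (k, d)."""
    means, variances = [], []
    for start in range(0, len(images), batch_size):
        mean, logvar = encoder.encode(images[start : start + batch_size])
        means.append(mean)
        variances.append(np.exp(logvar))
    mean = np.concatenate(means)
    var = np.concatenate(variances)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(var))):
        raise FloatingPointError("encoder produced non-finite output")
    return mean, var


def sigma_points(enc: LatentEncoding, alpha: float) -> SigmaPointSet:
    """Expand one encoding into its 2d σ-points.

    With a diagonal covariance the matrix square root is element-wise, so
    column n of sqrt(Σ) is sqrt(σ²_n)·e_n.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    pts = _sigma_points_batch(enc.mean[None], enc.variance[None], alpha)[0]
    return SigmaPointSet(points=pts, alpha=alpha)


def _sigma_points_batch(means: np.ndarray, variances: np.ndarray,
                        alpha: float) -> np.ndarray:
    """(k, d) means/variances -> (k, 2d, d) σ-points."""
    k, d = means.shape
    deltas = alpha * np.sqrt(variances)  # (k, d)
    eye = np.eye(d)
    plus = means[:, None, :] + deltas[:, :, None] * eye[None]
    minus = means[:, None, :] - deltas[:, :, None] * eye[None]
    return np.concatenate([plus, minus], axis=1)


def reparameterized_set(dataset: ClientDataset, encoder,
                        alpha: float) -> dict[int, np.ndarray]:
    """σ-point cloud of a whole shard, grouped by class label.

    Each of the k images contributes 2d points carrying its label, so class
    c contributes exactly 2d × (count of class-c images) points and
    |Z| = 2dk in total.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    means, variances = encode_dataset(dataset.images, encoder)
    points = _sigma_points_batch(means, variances, alpha)  # (k, 2d, d)
    d = means.shape[1]
    out: dict[int, np.ndarray] = {}
    for label in np.unique(dataset.labels):
        mask = dataset.labels == label
        out[int(label)] = points[mask].reshape(-1, d)
    return out


# ---------------------------------------------------------------------------
# distribution fitting and sampling
# ---------------------------------------------------------------------------

def estimate_distribution(z_class: np.ndarray, family: str,
                          ddof: int = 1) -> dict:
    """Fit per-dimension parameters θ of ``family`` to one class's samples.

    uniform: per-dimension (min, max); normal: per-dimension mean and
    sample std (``ddof`` fixes the divisor convention); truncated normal:
    mean/std plus min/max as the truncation bounds. Zero-variance
    dimensions are clamped to ``STD_FLOOR`` with a warning.
    """
    z = np.asarray(z_class, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise ValueError("need at least 2 samples of shape (n, d)")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    theta: dict = {}
    if family in ("uniform", "truncated_normal"):
        theta["lower"] = z.min(axis=0)
        theta["upper"] = z.max(axis=0)
    if family in ("normal", "truncated_normal"):
        theta["mean"] = z.mean(axis=0)
        std = z.std(axis=0, ddof=ddof)
        if np.any(std < STD_FLOOR):
            warnings.warn(
                "zero-variance latent dimension(s); clamping std to "
                f"{STD_FLOOR}", RuntimeWarning, stacklevel=2)
            std = np.maximum(std, STD_FLOOR)
        theta["std"] = std
    return theta


def _sample_truncated_normal(mean, std, lower, upper, n, rng,
                             max_rejection_rounds: int = 50) -> np.ndarray:
    """Rejection sampling with a round cap; stragglers filled by the clipped
    inverse-CDF transform (exact for a truncated normal)."""
    d = len(mean)
    out = np.empty((n, d))
    pending = np.ones((n, d), dtype=bool)
    for _ in range(max_rejection_rounds):
        if not pending.any():
            break
        draw = rng.normal(mean, std, size=(n, d))
        ok = pending & (draw >= lower) & (draw <= upper)
        out[ok] = draw[ok]
        pending &= ~ok
    if pending.any():
        a = ndtr((lower - mean) / std)
        b = ndtr((upper - mean) / std)
        u = rng.uniform(size=(n, d))
        inv = mean + std * ndtri(a + u * (b - a))
        inv = np.clip(inv, lower, upper)
        out[pending] = inv[pending]
    return out


def sample_latent(theta: dict, family: str, n: int, seed) -> np.ndarray:
    """Draw ``n`` latent vectors from a fitted θ; reproducible under seed.

    ``seed`` may be an int or an already-constructed Generator (so callers
    can chain draws off one stream).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    _validate_theta(theta, family)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if family == "uniform":
        lo = np.asarray(theta["lower"], dtype=float)
        hi = np.asarray(theta["upper"], dtype=float)
        return rng.uniform(lo, hi, size=(n, len(lo)))
    mean = np.asarray(theta["mean"], dtype=float)
    std = np.asarray(theta["std"], dtype=float)
    if family == "normal":
        return rng.normal(mean, std, size=(n, len(mean)))
    lo = np.asarray(theta["lower"], dtype=float)
    hi = np.asarray(theta["upper"], dtype=float)
    return _sample_truncated_normal(mean, std, lo, hi, n, rng)


def build_distribution_info(dataset: ClientDataset, encoder, alpha: float,
                            family: str, ddof: int = 1) -> DistributionInfo:
    """Full encoder-side pipeline for one client: encode, σ-point-expand,
    fit a per-class θ, and package the shareable payload."""
    z_by_class = reparameterized_set(dataset, encoder, alpha)
    params = {label: estimate_distribution(z, family, ddof=ddof)
              for label, z in z_by_class.items()}
    counts = {int(label): int((dataset.labels == label).sum())
              for label in np.unique(dataset.labels)}
    return DistributionInfo(
        client_id=dataset.client_id, family=family,
        per_class_params=params, per_class_counts=counts)
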