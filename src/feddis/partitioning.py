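"""Non-IID client sharding and heterogeneity measurement.

Builds label-skewed client shards from a labeled image set in two ways —
explicit per-class proportion tables and Dirichlet(β) label skew — and
quantifies inter-client heterogeneity with the earth mover's distance
between per-client class distributions. Class labels are nominal, so the
ground metric is the unit cost between distinct classes, under which the
EMD reduces to half the L1 distance between the probability vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ClientDataset",
    "PartitionSpec",
    "partition_by_proportions",
    "partition_dirichlet",
    "emd",
    "pairwise_emd",
    "save_partition_manifest",
    "load_partition_manifest",
]


@dataclass
class ClientDataset:
    """One client's disjoint labeled shard plus its augmented extension.

    ``images`` is an (N, C, H, W) float array in [0, 1]; ``labels`` an (N,)
    integer array. ``sample_ids`` index into the source dataset so
    partitions are replayable. Augmented (decoder-generated) samples are
    kept separate so they can be flagged, weighted or excluded.
    """

    client_id: int
    images: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray | None = None
    augmented_images: np.ndarray | None = None
    augmented_labels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_augmented(self) -> int:
        return 0 if self.augmented_labels is None else len(self.augmented_labels)

    def class_counts(self, n_classes: int) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)

    def class_distribution(self, n_classes: int) -> np.ndarray:
        """Empirical label distribution of the shard (original samples only)."""
        c = self.class_counts(n_classes).astype(float)
        return c / c.sum()

    def merged_class_distribution(self, n_classes: int) -> np.ndarray:
        """Label distribution of original plus augmented samples."""
        c = self.class_counts(n_classes).astype(float)
        if self.augmented_labels is not None:
            c += np.bincount(self.augmented_labels, minlength=n_classes)
        return c / c.sum()

    def training_arrays(self, include_augmented: bool = True):
        """(images, labels, is_real flags) of the shard used for training."""
        if include_augmented and self.augmented_images is not None:
            images = np.concatenate([self.images, self.augmented_images])
            labels = np.concatenate([self.labels, self.augmented_labels])
            real = np.concatenate([
                np.ones(len(self.labels), dtype=bool),
                np.zeros(len(self.augmented_labels), dtype=bool),
            ])
            return images, labels, real
        return self.images, self.labels, np.ones(len(self.labels), dtype=bool)


@dataclass
class PartitionSpec:
    """Partition recipe: explicit proportions or Dirichlet label skew.

    ``proportions`` is a (n_classes, m) matrix; row c gives the fraction of
    class-c samples each client receives and must sum to 1. ``beta`` is the
    Dirichlet concentration: smaller beta, higher label skew.
    """

    mode: str = "proportions"
    proportions: np.ndarray | None = None
    beta: float = 0.5
    m: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("proportions", "dirichlet"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if self.mode == "proportions":
            if self.proportions is None:
                raise ValueError("proportions mode requires a proportions matrix")
            self.proportions = np.asarray(self.proportions, dtype=float)
            rows = self.proportions.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise ValueError(f"proportion rows must sum to 1, got {rows}")
            self.m = self.proportions.shape[1]
        if self.mode == "dirichlet" and self.beta <= 0:
            raise ValueError("beta must be > 0")


def uniform_spec(n_classes: int, m: int, seed: int = 0) -> PartitionSpec:
    """IID reference split: every client gets an equal share of each class."""
    return PartitionSpec(
        mode="proportions",
        proportions=np.full((n_classes, m), 1.0 / m),
        seed=seed,
    )


def _split_class(ids: np.ndarray, fractions: np.ndarray, rng) -> list[np.ndarray]:
    """Shuffle one class's sample ids and split per ``fractions``.

    Clients 1..m-1 receive round(fraction*count); the last client absorbs
    the remainder so the split is an exact disjoint cover.
    """
    ids = rng.permutation(ids)
    n = len(ids)
    counts = [int(np.round(f * n)) for f in fractions[:-1]]
    counts.append(n - sum(counts))
    if counts[-1] < 0:
        raise ValueError("rounding produced a negative remainder share")
    out, start = [], 0
    for c in counts:
        out.append(ids[start : start + c])
        start += c
    return out


def partition_by_proportions(images: np.ndarray, labels: np.ndarray,
                             spec: PartitionSpec) -> list[ClientDataset]:
    """Split a labeled set into shards following an explicit proportion table."""
    if spec.mode != "proportions":
        raise ValueError("spec.mode must be 'proportions'")
    rng = np.random.default_rng(spec.seed)
    n_classes, m = spec.proportions.shape
    per_client: list[list[np.ndarray]] = [[] for _ in range(m)]
    for c in range(n_classes):
        ids = np.flatnonzero(labels == c)
        for j, chunk in enumerate(_split_class(ids, spec.proportions[c], rng)):
            per_client[j].append(chunk)
    shards = []
    for j in range(m):
        ids = np.sort(np.concatenate(per_client[j]))
        shards.append(ClientDataset(
            client_id=j, images=images[ids], labels=labels[ids], sample_ids=ids))
    return shards


def partition_dirichlet(images: np.ndarray, labels: np.ndarray, beta: float,
                        m: int, seed: int = 0,
                        max_retries: int = 100) -> list[ClientDataset]:
    """Dirichlet label-skew partition.

    For each class a Dirichlet(beta·1_m) proportion vector is drawn and the
    class's samples are allocated to clients in those proportions. Draws
    that leave any client empty are rejected and redrawn, up to
    ``max_retries`` attempts.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    for _ in range(max_retries):
        assignment = [[] for _ in range(m)]
        for c in classes:
            ids = rng.permutation(np.flatnonzero(labels == c))
            props = rng.dirichlet(np.full(m, beta))
            cuts = (np.cumsum(props)[:-1] * len(ids)).astype(int)
            for j, chunk in enumerate(np.split(ids, cuts)):
                assignment[j].append(chunk)
        sizes = [sum(len(ch) for ch in chunks) for chunks in assignment]
        if min(sizes) > 0:
            shards = []
            for j in range(m):
                ids = np.sort(np.concatenate(assignment[j]))
                shards.append(ClientDataset(
                    client_id=j, images=images[ids], labels=labels[ids],
                    sample_ids=ids))
            return shards
    raise RuntimeError(
        f"could not draw a partition with all {m} shards non-empty "
        f"in {max_retries} attempts (beta={beta})")


def emd(p: np.ndarray, q: np.ndarray) -> float:
    """Earth mover's distance between two class-probability vectors.

    Under the categorical unit-cost ground metric (moving mass between any
    two distinct classes costs 1) the optimal transport cost is half the L1
    distance: EMD(p, q) = 0.5 * sum |p_c - q_c|.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if not (np.isclose(p.sum(), 1.0, atol=1e-6)
            and np.isclose(q.sum(), 1.0, atol=1e-6)):
        raise ValueError("p and q must each sum to 1")
    return float(0.5 * np.abs(p - q).sum())


def pairwise_emd(clients: list[ClientDataset], n_classes: int,
                 merged: bool = False) -> np.ndarray:
    """Symmetric matrix of EMDs between per-client label distributions.

    ``merged=True`` measures the post-augmentation distributions.
    """
    if len(clients) < 2:
        raise ValueError("need at least 2 clients")
    dists = [
        (c.merged_class_distribution(n_classes) if merged
         else c.class_distribution(n_classes))
        for c in clients
    ]
    m = len(clients)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = emd(dists[i], dists[j])
    return out


def save_partition_manifest(clients: list[ClientDataset], path) -> None:
    manifest = {
        str(c.client_id): [int(i) for i in c.sample_ids]
        for c in clients
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def load_partition_manifest(images: np.ndarray, labels: np.ndarray,
                            path) -> list[ClientDataset]:
    manifest = json.loads(Path(path).read_text())
    shards = []
    for cid, id_list in manifest.items():
        ids = np.asarray(id_list, dtype=int)
        shards.append(ClientDataset(
            client_id=int(cid), images=images[ids], labels=labels[ids],
            sample_ids=ids))
    return shards
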