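"""Client/server federated-learning simulation.

Single-process, in-memory message passing. One communication round is:
sample ceil(r·m) clients, each trains ``local_epochs_per_round`` epochs
from the current global parameters, the server aggregates with FedAvg
(parameter average weighted by local sample counts), optionally evaluates
on the shared test set.

The full method runs in two stages. Stage 1 federally trains the VAE,
then every client turns its shard into a DistributionInfo payload with the
*global* encoder (all clients must share one latent geometry) and the
server broadcasts each payload to all other clients. Between the stages
every client generates and merges its augmented set (see
:mod:`feddis.augmentation`), after which every shard carries the global
label histogram. Stage 2 federally trains the task classifier on the
augmented shards. Since augmentation equalizes shard sizes, stage-2
FedAvg weighting by augmented counts is effectively uniform; a config
switch restores original-count weighting.
"""

from __future__ import annotations

import math
import zlib
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np

from . import vae as vae_mod
from .augmentation import augment_clients
from .latent_space import DistributionInfo, build_distribution_info
from .metrics import evaluate_accuracy
from .partitioning import ClientDataset
from .vae import TrainingConfig, train_local

__all__ = [
    "FederationConfig",
    "RoundRecord",
    "derive_seed",
    "fedavg_aggregate",
    "train_standalone",
    "run_stage1",
    "run_stage2",
    "broadcast",
    "run_feddis",
    "run_fedavg",
]


@dataclass
class FederationConfig:
    """Federation-level knobs.

    ``rounds`` counts communication rounds (one aggregation per round);
    ``active_ratio`` r is the fraction of clients sampled each round
    (uniform without replacement, fresh each round); ``weights_source``
    picks the FedAvg weight n_i: post-augmentation shard sizes (default —
    equalized by construction) or original counts.
    """

    rounds: int = 50
    active_ratio: float = 1.0
    local_epochs_per_round: int = 2
    weights_source: str = "augmented_counts"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.active_ratio <= 1:
            raise ValueError("active_ratio must be in (0, 1]")
        if self.weights_source not in ("augmented_counts", "original_counts"):
            raise ValueError(f"unknown weights_source {self.weights_source!r}")


@dataclass
class RoundRecord:
    round_index: int
    participants: list
    accuracy: float | None
    mean_local_loss: float


def derive_seed(base: int, *parts) -> int:
    """Deterministic child seed (< 2^31) from a base seed and context tags."""
    entropy = [int(base)] + [zlib.crc32(p.encode()) if isinstance(p, str)
                             else int(p) for p in parts]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


def fedavg_aggregate(updates) -> "OrderedDict[str, np.ndarray]":
    """Weighted parameter average Σ nᵢwᵢ / Σ nᵢ over state dicts.

    Weights are normalized first, so a single update is returned bit-
    identically (its normalized weight is exactly 1.0).
    """
    if not updates:
        raise ValueError("no updates to aggregate")
    weights = np.asarray([float(w) for _, w in updates])
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    weights = weights / total
    keys = list(updates[0][0].keys())
    for state, _ in updates[1:]:
        if list(state.keys()) != keys or any(
                state[k].shape != updates[0][0][k].shape for k in keys):
            raise ValueError("parameter names/shapes do not match across updates")
    out: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for k in keys:
        acc = weights[0] * updates[0][0][k]
        for (state, _), w in zip(updates[1:], weights[1:]):
            acc = acc + w * state[k]
        out[k] = acc
    return out


def _shard_weight(shard: ClientDataset, source: str) -> int:
    if source == "original_counts":
        return len(shard)
    return len(shard) + shard.n_augmented


def _sample_participants(m: int, ratio: float, rng) -> list[int]:
    n_active = math.ceil(ratio * m)
    return sorted(rng.choice(m, size=n_active, replace=False).tolist())


def train_standalone(model, shard, train_cfg: TrainingConfig, rounds: int,
                     base_seed: int, client_index: int = 0):
    """Reference loop: ``rounds`` consecutive local-training rounds on one
    shard with the same per-round seed derivation the federation uses.

    With m=1 and r=1 federated training degenerates to exactly this (the
    single normalized FedAvg weight is 1.0), which tests assert
    bit-for-bit.
    """
    state = model.state_dict()
    for rnd in range(rounds):
        model.load_state_dict(state)
        state, _ = train_local(
            model, shard, train_cfg, epochs=train_cfg.local_epochs_per_round,
            seed=derive_seed(base_seed, "local", rnd, client_index))
    return state


def _federated_fit(model, clients, fed_cfg: FederationConfig,
                   train_cfg: TrainingConfig, test=None,
                   include_augmented: bool = True):
    """Generic FedAvg loop shared by both stages."""
    m = len(clients)
    state = model.state_dict()
    sampler = np.random.default_rng(derive_seed(fed_cfg.seed, "sampling"))
    records: list[RoundRecord] = []
    for rnd in range(fed_cfg.rounds):
        participants = _sample_participants(m, fed_cfg.active_ratio, sampler)
        updates, losses = [], []
        for cid in participants:
            shard = clients[cid]
            data = shard if include_augmented else (shard.images, shard.labels)
            model.load_state_dict(state)
            local_state, trace = train_local(
                model, data, train_cfg,
                epochs=fed_cfg.local_epochs_per_round,
                seed=derive_seed(fed_cfg.seed, "local", rnd, cid))
            weight = (_shard_weight(shard, fed_cfg.weights_source)
                      if include_augmented else len(shard))
            updates.append((local_state, weight))
            losses.append(trace[-1])
        state = fedavg_aggregate(updates)
        acc = None
        if test is not None:
            model.load_state_dict(state)
            acc = evaluate_accuracy(model, test[0], test[1])
        records.append(RoundRecord(rnd, participants, acc,
                                   float(np.mean(losses))))
    model.load_state_dict(state)
    return state, records


def run_stage1(clients: list[ClientDataset], input_shape,
               fed_cfg: FederationConfig, train_cfg: TrainingConfig,
               d: int = 64, widths=(16, 32), alpha: float = 2.0,
               family: str = "uniform"):
    """Stage 1: federally train the VAE, then collect every client's
    DistributionInfo built with the aggregated (global) VAE.

    Returns ``(global_vae, distribution_infos, round_records)``.
    """
    if any(len(c) == 0 for c in clients):
        raise ValueError("every client shard must be non-empty")
    _check_disjoint(clients)
    model = vae_mod.build_vae(input_shape, d=d, widths=widths,
                              seed=derive_seed(fed_cfg.seed, "vae-init"))
    state, records = _federated_fit(model, clients, fed_cfg, train_cfg,
                                    include_augmented=False)
    model.load_state_dict(state)
    dis = [build_distribution_info(shard, model, alpha=alpha, family=family)
           for shard in clients]
    return model, dis, records


def _check_disjoint(clients):
    seen: set[int] = set()
    for c in clients:
        if c.sample_ids is None:
            return  # provenance unknown; nothing to check
        ids = set(int(i) for i in c.sample_ids)
        if seen & ids:
            raise ValueError("client shards are not pairwise disjoint")
        seen |= ids


def broadcast(dis: list[DistributionInfo]) -> dict[int, list[DistributionInfo]]:
    """Server broadcast: every client receives all DIs but its own."""
    return {
        di.client_id: [other for other in dis
                       if other.client_id != di.client_id]
        for di in dis
    }


def run_stage2(clients: list[ClientDataset], task_model_factory,
               fed_cfg: FederationConfig, train_cfg: TrainingConfig,
               test_images=None, test_labels=None,
               include_augmented: bool = True):
    """Stage 2: FedAvg training of the task model on the (augmented) shards.

    Returns ``(final_state, round_records)``. With ``rounds=0`` the
    returned state is the factory's initial parameters.
    """
    model = task_model_factory()
    test = None if test_images is None else (test_images, test_labels)
    if fed_cfg.rounds == 0:
        return model.state_dict(), []
    return _federated_fit(model, clients, fed_cfg, train_cfg, test=test,
                          include_augmented=include_augmented)


def run_feddis(clients: list[ClientDataset], input_shape,
               task_model_factory, vae_fed_cfg: FederationConfig,
               task_fed_cfg: FederationConfig,
               vae_train_cfg: TrainingConfig, task_train_cfg: TrainingConfig,
               test_images=None, test_labels=None, d: int = 64,
               widths=(16, 32), alpha: float = 2.0, family: str = "uniform"):
    """End-to-end method: stage 1 → DI broadcast → augmentation → stage 2.

    Returns a dict with the global VAE, the DIs, the augmented clients,
    the final task-model state and both stages' round records.
    """
    vae, dis, vae_records = run_stage1(
        clients, input_shape, vae_fed_cfg, vae_train_cfg,
        d=d, widths=widths, alpha=alpha, family=family)
    augmented, manifest = augment_clients(
        clients, dis, vae, seed=derive_seed(vae_fed_cfg.seed, "augment"))
    state, task_records = run_stage2(
        augmented, task_model_factory, task_fed_cfg, task_train_cfg,
        test_images=test_images, test_labels=test_labels)
    return {
        "vae": vae,
        "distribution_infos": dis,
        "augmented_clients": augmented,
        "augmentation_manifest": manifest,
        "task_state": state,
        "vae_records": vae_records,
        "task_records": task_records,
    }


def run_fedavg(clients: list[ClientDataset], task_model_factory,
               fed_cfg: FederationConfig, train_cfg: TrainingConfig,
               test_images=None, test_labels=None):
    """Plain FedAvg baseline on the raw (un-augmented) shards."""
    return run_stage2(clients, task_model_factory, fed_cfg, train_cfg,
                      test_images=test_images, test_labels=test_labels,
                      include_augmented=False)
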