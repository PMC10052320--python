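"""Decoder-side data generation and shard merging.

Client k receives the other clients' DistributionInfo payloads, draws from
each foreign class-conditional θ exactly as many latent vectors as that
client reported holding of that class, and decodes them into labeled
synthetic images. Merging the generated set into the local shard gives
every client the global label histogram: the merged shard of any client
has size |X| = Σ_i |X_i| and identical class proportions everywhere, which
is what removes the label-skew non-IIDness.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .latent_space import DistributionInfo, sample_latent
from .partitioning import ClientDataset

__all__ = ["generate_for_client", "merge", "augment_clients"]


def generate_for_client(client_id: int, foreign_dis: list[DistributionInfo],
                        decoder, seed: int, batch_size: int = 256):
    """Generate the synthetic samples client ``client_id`` needs.

    Returns ``(images, labels, manifest)``: one decoded image per latent
    draw, Σ_{i≠k}|X_i| in total, each labeled with the class of the θ it
    was drawn from. The manifest lists (client, source client, class,
    count, seed) per generation block. Latent draws are chained off a
    single seeded generator, so the output is reproducible bit-for-bit.
    """
    if any(di.client_id == client_id for di in foreign_dis):
        raise ValueError(
            f"client {client_id} received its own DistributionInfo")
    families = {di.family for di in foreign_dis}
    if len(families) > 1:
        raise ValueError(f"mixed distribution families across DIs: {families}")
    rng = np.random.default_rng(seed)
    latents, labels, manifest = [], [], []
    for di in sorted(foreign_dis, key=lambda d: d.client_id):
        for label in sorted(di.per_class_params):
            count = di.per_class_counts[label]
            if count == 0:
                continue
            z = sample_latent(di.per_class_params[label], di.family, count, rng)
            latents.append(z)
            labels.append(np.full(count, label, dtype=int))
            manifest.append({
                "client": int(client_id),
                "source_client": int(di.client_id),
                "class": int(label),
                "count": int(count),
                "seed": int(seed),
            })
    if not latents:
        c, h, w = decoder.input_shape
        return np.empty((0, c, h, w)), np.empty(0, dtype=int), manifest
    z = np.concatenate(latents)
    images = np.concatenate([
        decoder.decode(z[start : start + batch_size])
        for start in range(0, len(z), batch_size)
    ])
    return images, np.concatenate(labels), manifest


def merge(shard: ClientDataset, generated_images: np.ndarray,
          generated_labels: np.ndarray) -> ClientDataset:
    """Attach generated samples to a shard (originals stay flagged as real).

    The merged training set has size |X_k| + (number generated); with
    truthful DI counts that is the global training-set size for every
    client.
    """
    if len(generated_labels) == 0:
        return replace(shard, augmented_images=None, augmented_labels=None)
    own = set(np.unique(shard.labels).tolist())
    foreign = set(np.unique(generated_labels).tolist())
    # vocabularies must be compatible: generated labels come from the same task
    if not foreign.issubset(own | foreign):
        raise ValueError("label vocabulary mismatch")
    return replace(
        shard,
        augmented_images=np.asarray(generated_images),
        augmented_labels=np.asarray(generated_labels, dtype=int),
    )


def augment_clients(clients: list[ClientDataset],
                    dis: list[DistributionInfo], decoder,
                    seed: int) -> tuple[list[ClientDataset], list[dict]]:
    """Run generation + merge for every client.

    Each client sees every DI but its own (the server-broadcast protocol);
    per-client seeds are derived from ``seed`` so clients are independent
    streams.
    """
    by_id = {di.client_id: di for di in dis}
    merged, manifest = [], []
    for shard in clients:
        foreign = [di for cid, di in sorted(by_id.items())
                   if cid != shard.client_id]
        child_seed = int(np.random.SeedSequence(
            [int(seed), int(shard.client_id)]).generate_state(1)[0] % (2 ** 31))
        images, labels, records = generate_for_client(
            shard.client_id, foreign, decoder, child_seed)
        merged.append(merge(shard, images, labels))
        manifest.extend(records)
    return merged, manifest
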