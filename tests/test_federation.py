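"""FedAvg aggregation algebra and the two-stage orchestration."""

from collections import OrderedDict

import numpy as np
import pytest

from feddis import (
    ClientDataset,
    FederationConfig,
    TrainingConfig,
    broadcast,
    build_task_cnn,
    derive_seed,
    fedavg_aggregate,
    run_stage1,
    run_stage2,
    train_standalone,
)

from conftest import shard_from_labels


def _state(**tensors):
    return OrderedDict((k, np.asarray(v, dtype=float))
                       for k, v in tensors.items())


class TestFedavgAggregate:
    def test_idempotent_on_identical_updates(self):
        s = _state(w=[[1.0, 2.0], [3.0, 4.0]], b=[0.5])
        out = fedavg_aggregate([(s, 10), (s, 20), (s, 5)])
        assert all(np.allclose(out[k], s[k]) for k in s)

    def test_equal_weights_arithmetic_mean(self):
        out = fedavg_aggregate([(_state(w=[1.0]), 3), (_state(w=[3.0]), 3)])
        assert out["w"][0] == pytest.approx(2.0)

    def test_hand_computed_weighted_mean(self):
        out = fedavg_aggregate([(_state(w=[0.0]), 1), (_state(w=[4.0]), 3)])
        assert out["w"][0] == pytest.approx(3.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        updates = [(_state(w=rng.normal(size=(3, 2))), w)
                   for w in (1.0, 2.5, 4.0)]
        a = fedavg_aggregate(updates)
        b = fedavg_aggregate(updates[::-1])
        assert np.allclose(a["w"], b["w"])

    def test_homogeneous_degree_one(self):
        rng = np.random.default_rng(1)
        updates = [(_state(w=rng.normal(size=4)), w) for w in (1.0, 3.0)]
        scaled = [(_state(w=3.0 * s["w"]), w) for s, w in updates]
        assert np.allclose(fedavg_aggregate(scaled)["w"],
                           3.0 * fedavg_aggregate(updates)["w"])

    def test_matches_unweighted_mean_brute_force(self):
        rng = np.random.default_rng(2)
        states = [_state(a=rng.normal(size=(2, 2)), b=rng.normal(size=3))
                  for _ in range(5)]
        out = fedavg_aggregate([(s, 7) for s in states])
        for k in ("a", "b"):
            assert np.allclose(out[k], np.mean([s[k] for s in states], axis=0))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            fedavg_aggregate([(_state(w=[1.0]), 1), (_state(w=[1.0, 2.0]), 1)])

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            fedavg_aggregate([(_state(w=[1.0]), 0)])
        with pytest.raises(ValueError):
            fedavg_aggregate([])


def _image_shard(client_id, labels, seed, hw=32):
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=int)
    return ClientDataset(client_id=client_id,
                         images=rng.random((len(labels), 1, hw, hw)),
                         labels=labels)


class TestStage2:
    def _factory(self, hw=32):
        return lambda: build_task_cnn((1, hw, hw), 2, widths=(2, 3), hidden=8,
                                      seed=derive_seed(0, "task-init"))

    def test_full_participation_lists_all_clients(self):
        clients = [_image_shard(i, [0, 1] * 4, seed=i) for i in range(3)]
        cfg = FederationConfig(rounds=2, active_ratio=1.0, seed=0)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=8)
        _, records = run_stage2(clients, self._factory(), cfg, tc)
        assert all(r.participants == [0, 1, 2] for r in records)

    def test_half_participation_samples_without_replacement(self):
        clients = [_image_shard(i, [0, 1], seed=i, hw=16) for i in range(20)]
        cfg = FederationConfig(rounds=3, active_ratio=0.5, seed=1)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=4)
        _, records = run_stage2(clients, self._factory(hw=16), cfg, tc)
        for r in records:
            assert len(r.participants) == 10
            assert len(set(r.participants)) == 10

    def test_zero_rounds_returns_initial_parameters(self):
        clients = [_image_shard(0, [0, 1], seed=0)]
        cfg = FederationConfig(rounds=0, seed=0)
        state, records = run_stage2(clients, self._factory(), cfg,
                                    TrainingConfig())
        init = self._factory()().state_dict()
        assert records == []
        assert all(np.array_equal(state[k], init[k]) for k in state)

    def test_single_client_equals_standalone_training_bitwise(self):
        """m=1, r=1 federation degenerates exactly to local training."""
        shard = _image_shard(0, [0, 1, 0, 1, 1, 0], seed=5)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=4)
        cfg = FederationConfig(rounds=3, active_ratio=1.0, seed=11,
                               local_epochs_per_round=tc.local_epochs_per_round)
        fed_state, _ = run_stage2([shard], self._factory(), cfg, tc,
                                  include_augmented=False)
        ref_state = train_standalone(self._factory()(), (shard.images,
                                                         shard.labels),
                                     tc, rounds=3, base_seed=11)
        assert all(np.array_equal(fed_state[k], ref_state[k])
                   for k in fed_state)


class TestStage1:
    def test_end_to_end_on_three_clients(self):
        clients = [
            _image_shard(0, [0, 0, 0, 1], seed=0, hw=16),
            _image_shard(1, [0, 1, 1, 1], seed=1, hw=16),
            _image_shard(2, [0, 0, 1, 1], seed=2, hw=16),
        ]
        for i, c in enumerate(clients):  # disjoint provenance
            c.sample_ids = np.arange(4) + 4 * i
        fed = FederationConfig(rounds=2, seed=0)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=4)
        vae, dis, records = run_stage1(clients, (1, 16, 16), fed, tc,
                                       d=4, widths=(2, 3), alpha=2.0,
                                       family="uniform")
        assert len(records) == 2
        assert [di.total_count for di in dis] == [4, 4, 4]
        inboxes = broadcast(dis)
        for cid, received in inboxes.items():
            assert len(received) == 2
            assert all(di.client_id != cid for di in received)

    def test_identical_shards_give_equal_class_counts(self):
        rng = np.random.default_rng(3)
        images = rng.random((6, 1, 16, 16))
        labels = np.array([0, 0, 1, 1, 1, 0])
        clients = [ClientDataset(client_id=i, images=images.copy(),
                                 labels=labels.copy()) for i in range(2)]
        fed = FederationConfig(rounds=1, seed=0)
        tc = TrainingConfig(learning_rate=1e-3, batch_size=4)
        _, dis, _ = run_stage1(clients, (1, 16, 16), fed, tc, d=4,
                               widths=(2, 3))
        assert dis[0].per_class_counts == dis[1].per_class_counts

    def test_empty_shard_rejected(self):
        clients = [_image_shard(0, [0, 1], seed=0, hw=16),
                   shard_from_labels([], client_id=1)]
        with pytest.raises(ValueError):
            run_stage1(clients, (1, 16, 16), FederationConfig(rounds=1),
                       TrainingConfig(), d=4, widths=(2, 3))

    def test_overlapping_shards_rejected(self):
        a = _image_shard(0, [0, 1], seed=0, hw=16)
        b = _image_shard(1, [0, 1], seed=1, hw=16)
        a.sample_ids = np.array([0, 1])
        b.sample_ids = np.array([1, 2])
        with pytest.raises(ValueError):
            run_stage1([a, b], (1, 16, 16), FederationConfig(rounds=1),
                       TrainingConfig(), d=4, widths=(2, 3))


def test_federation_config_validation():
    with pytest.raises(ValueError):
        FederationConfig(active_ratio=0.0)
    with pytest.raises(ValueError):
        FederationConfig(weights_source="gradient_norm")


def test_derive_seed_stable_and_bounded():
    a = derive_seed(1, "local", 3, 2)
    assert a == derive_seed(1, "local", 3, 2)
    assert a != derive_seed(1, "local", 3, 1)
    assert 0 <= a < 2 ** 31
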