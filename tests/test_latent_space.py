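"""σ-point expansion, distribution estimation, latent sampling, and the
DistributionInfo exchange payload."""

import json

import numpy as np
import pytest

from feddis import (
    DistributionInfo,
    LatentEncoding,
    build_distribution_info,
    encode,
    estimate_distribution,
    make_latent_fixture,
    reparameterized_set,
    sample_latent,
    sigma_points,
)
from feddis.latent_space import FAMILIES

from conftest import shard_from_labels


# ---------------------------------------------------------------------------
# σ-points
# ---------------------------------------------------------------------------

class TestSigmaPoints:
    def test_unit_one_dimensional_case(self):
        enc = LatentEncoding(mean=[0.0], variance=[1.0])
        pts = sigma_points(enc, alpha=1.0).points
        assert sorted(pts.ravel().tolist()) == [-1.0, 1.0]

    def test_hand_worked_two_dimensional_case(self):
        enc = LatentEncoding(mean=[2.0, -1.0], variance=[4.0, 9.0])
        pts = sigma_points(enc, alpha=2.0).points
        expected = {(6, -1), (2, 5), (-2, -1), (2, -7)}
        assert {tuple(p) for p in pts.tolist()} == expected

    def test_reflection_pairing(self):
        enc = LatentEncoding(mean=[0.5, 1.5, -2.0],
                             variance=[1.0, 2.0, 0.25])
        pts = sigma_points(enc, alpha=1.7).points
        d = enc.d
        assert np.allclose(pts[:d] + pts[d:], 2 * enc.mean)

    @pytest.mark.parametrize("trial", range(20))
    def test_mean_and_covariance_identities(self, trial):
        """Empirical mean is m; population covariance is (α²/d)·diag(σ²)."""
        rng = np.random.default_rng(trial)
        d = int(rng.integers(1, 17))
        enc = LatentEncoding(mean=rng.normal(size=d),
                             variance=rng.uniform(0.1, 5.0, size=d))
        alpha = float(rng.uniform(0.1, 4.0))
        pts = sigma_points(enc, alpha).points
        assert np.abs(pts.mean(axis=0) - enc.mean).max() < 1e-10
        cov = (pts - enc.mean).T @ (pts - enc.mean) / (2 * d)
        target = (alpha ** 2 / d) * np.diag(enc.variance)
        assert np.abs(cov - target).max() < 1e-10

    def test_nonpositive_alpha_rejected(self):
        enc = LatentEncoding(mean=[0.0], variance=[1.0])
        with pytest.raises(ValueError):
            sigma_points(enc, alpha=0.0)

    def test_invalid_encoding_rejected(self):
        with pytest.raises(ValueError):
            LatentEncoding(mean=[0.0, 1.0], variance=[1.0])
        with pytest.raises(ValueError):
            LatentEncoding(mean=[0.0], variance=[0.0])


# ---------------------------------------------------------------------------
# encoding and the reparameterized set
# ---------------------------------------------------------------------------

class TestEncodeAndReparameterizedSet:
    def test_encode_contract(self, tiny_vae):
        img = np.random.default_rng(0).random((1, 32, 32))
        enc1 = encode(img, tiny_vae)
        enc2 = encode(img, tiny_vae)
        assert enc1.d == tiny_vae.d
        assert np.all(enc1.variance > 0)
        assert np.array_equal(enc1.mean, enc2.mean)  # deterministic inference
        with pytest.raises(ValueError):
            encode(np.zeros((1, 16, 16)), tiny_vae)

    def test_counting_and_label_conservation(self, tiny_vae):
        shard = shard_from_labels([0, 0, 1])
        shard.images = np.random.default_rng(1).random((3, 1, 32, 32))
        z = reparameterized_set(shard, tiny_vae, alpha=2.0)
        d = tiny_vae.d
        assert sum(len(v) for v in z.values()) == 2 * d * 3
        assert len(z[0]) == 2 * d * 2 and len(z[1]) == 2 * d * 1

    def test_identical_inputs_give_identical_clouds(self, tiny_vae):
        imgs = np.random.default_rng(2).random((4, 1, 32, 32))
        a = shard_from_labels([0, 1, 0, 1]); a.images = imgs
        b = shard_from_labels([0, 1, 0, 1], client_id=1); b.images = imgs.copy()
        za = reparameterized_set(a, tiny_vae, alpha=1.0)
        zb = reparameterized_set(b, tiny_vae, alpha=1.0)
        for label in za:
            assert np.array_equal(za[label], zb[label])

    def test_empty_dataset_rejected(self, tiny_vae):
        with pytest.raises(ValueError):
            reparameterized_set(shard_from_labels([]), tiny_vae, alpha=1.0)


# ---------------------------------------------------------------------------
# estimation and sampling
# ---------------------------------------------------------------------------

class TestEstimateDistribution:
    def test_uniform_is_min_max(self):
        z = np.array([[0.1], [0.5], [0.9]])
        theta = estimate_distribution(z, "uniform")
        assert theta["lower"][0] == 0.1 and theta["upper"][0] == 0.9

    def test_normal_closed_form(self):
        z = np.array([[-1.0], [1.0]])
        theta = estimate_distribution(z, "normal")
        assert theta["mean"][0] == 0.0
        assert theta["std"][0] == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_bounds_recovered_from_large_uniform_sample(self):
        z = make_latent_fixture("uniform", {"lower": -2.0, "upper": 3.0},
                                n=10_000, d=1, seed=5)
        theta = estimate_distribution(z, "uniform")
        assert theta["lower"][0] == pytest.approx(-2.0, abs=0.01)
        assert theta["upper"][0] == pytest.approx(3.0, abs=0.01)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            estimate_distribution(np.zeros((1, 3)), "normal")

    def test_zero_variance_dimension_clamped_with_warning(self):
        z = np.ones((5, 2))
        with pytest.warns(RuntimeWarning):
            theta = estimate_distribution(z, "normal")
        assert np.all(theta["std"] > 0)


class TestSampleLatent:
    def test_zero_draws(self):
        z = sample_latent({"lower": np.zeros(3), "upper": np.ones(3)},
                          "uniform", 0, seed=0)
        assert z.shape == (0, 3)

    def test_uniform_support_containment(self):
        theta = {"lower": np.zeros(4), "upper": np.ones(4)}
        z = sample_latent(theta, "uniform", 500, seed=1)
        assert z.min() >= 0.0 and z.max() <= 1.0

    def test_truncated_support_containment(self):
        theta = {"mean": np.zeros(3), "std": np.ones(3) * 5,
                 "lower": -np.ones(3), "upper": np.ones(3) * 0.5}
        z = sample_latent(theta, "truncated_normal", 2000, seed=2)
        assert z.min() >= -1.0 and z.max() <= 0.5

    def test_seed_reproducibility(self):
        theta = {"mean": np.zeros(2), "std": np.ones(2)}
        assert np.array_equal(sample_latent(theta, "normal", 50, seed=9),
                              sample_latent(theta, "normal", 50, seed=9))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_round_trip_recovery(self, family):
        """Sample 10k points from a known θ and re-estimate within 5%."""
        d = 4
        theta = {"mean": np.linspace(0.5, 2, d), "std": np.linspace(0.5, 2, d),
                 "lower": np.linspace(-3, -1, d), "upper": np.linspace(2, 4, d)}
        theta = {k: v for k, v in theta.items()
                 if k in (("lower", "upper") if family == "uniform"
                          else ("mean", "std") if family == "normal"
                          else ("mean", "std", "lower", "upper"))}
        z = sample_latent(theta, family, 10_000, seed=11)
        est = estimate_distribution(z, family)
        for key in ("mean", "std"):
            if key in theta and family != "truncated_normal":
                rel = np.abs(est[key] - theta[key]) / np.abs(theta[key])
                assert rel.max() < 0.05
        if "lower" in theta:
            span = theta["upper"] - theta["lower"]
            assert (np.abs(est["lower"] - theta["lower"]) / span).max() < 0.005 \
                or family == "truncated_normal"
            # truncated-normal min/max converge more slowly in the tails
            if family == "truncated_normal":
                assert np.all(est["lower"] >= theta["lower"] - 1e-9)
                assert np.all(est["upper"] <= theta["upper"] + 1e-9)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            sample_latent({"lower": np.ones(2), "upper": np.zeros(2)},
                          "uniform", 5, seed=0)
        with pytest.raises(ValueError):
            sample_latent({"mean": np.zeros(2), "std": np.zeros(2)},
                          "normal", 5, seed=0)


# ---------------------------------------------------------------------------
# DistributionInfo payload
# ---------------------------------------------------------------------------

class TestDistributionInfo:
    def _di(self):
        return DistributionInfo(
            client_id=2, family="uniform",
            per_class_params={0: {"lower": np.zeros(3), "upper": np.ones(3)},
                              1: {"lower": -np.ones(3), "upper": np.ones(3)}},
            per_class_counts={0: 30, 1: 70})

    def test_total_count_is_sum_of_class_counts(self):
        assert self._di().total_count == 100

    def test_json_round_trip(self, tmp_path):
        di = self._di()
        path = tmp_path / "di.json"
        di.save(path)
        loaded = DistributionInfo.load(path)
        assert loaded.client_id == di.client_id
        assert loaded.family == di.family
        assert loaded.per_class_counts == di.per_class_counts
        for label in di.per_class_params:
            for k in di.per_class_params[label]:
                assert np.allclose(loaded.per_class_params[label][k],
                                   di.per_class_params[label][k])
        doc = json.loads(path.read_text())
        assert set(doc) == {"client_id", "family", "total_count", "classes"}

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            DistributionInfo(client_id=0, family="gaussian_mixture")
        with pytest.raises(ValueError):
            DistributionInfo(
                client_id=0, family="uniform",
                per_class_params={0: {"lower": np.ones(2), "upper": np.zeros(2)}},
                per_class_counts={0: 5})

    def test_build_from_shard(self, tiny_vae):
        shard = shard_from_labels([0, 0, 0, 1, 1])
        shard.images = np.random.default_rng(3).random((5, 1, 32, 32))
        di = build_distribution_info(shard, tiny_vae, alpha=2.0,
                                     family="uniform")
        assert di.per_class_counts == {0: 3, 1: 2}
        assert di.total_count == len(shard)
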