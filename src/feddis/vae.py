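"""Convolutional VAE, task CNN, and seeded local training.

The VAE encoder is a stack of stride-2 convolutions with batch
normalization and LeakyReLU activations, followed by two linear heads
emitting the latent mean and log-variance; the decoder mirrors it with
transposed convolutions and a sigmoid output so reconstructions live in
[0, 1]. The training objective is the standard ELBO with a Gaussian
likelihood: reconstruction error summed over pixels (mean over the batch)
plus the closed-form KL divergence of the diagonal-Gaussian posterior from
N(0, I); a KL-weight knob is exposed for annealing experiments.

``train_local`` is the unit of client work in the federation: a fixed
number of epochs of Adam on one shard, fully deterministic under its seed.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from . import nn
from .partitioning import ClientDataset

__all__ = [
    "TrainingConfig",
    "VAEModel",
    "TaskCNN",
    "build_vae",
    "build_task_cnn",
    "vae_loss",
    "train_local",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainingConfig:
    """Local-training hyperparameters (Adam throughout).

    ``local_epochs_per_round`` is the number of epochs a client runs
    between parameter uploads.
    """

    learning_rate: float = 1e-4
    batch_size: int = 64
    local_epochs_per_round: int = 2
    kl_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.local_epochs_per_round <= 0:
            raise ValueError("local_epochs_per_round must be positive")


def _check_input_shape(input_shape):
    c, h, w = input_shape
    if h % 4 != 0 or w % 4 != 0 or h < 16 or w < 16:
        raise ValueError(
            f"input height/width must be multiples of 4 and >= 16 for the "
            f"two stride-2 stages, got {input_shape}")
    return c, h, w


class VAEModel:
    """Encoder/decoder pair with a shared latent dimensionality ``d``.

    Inference (``encode``/``decode``) runs in eval mode — batch-norm uses
    running statistics — so the encoder is a deterministic function of its
    input, which the distribution-sharing stage relies on.
    """

    def __init__(self, input_shape, d: int, widths=(16, 32), rng=0):
        c, h, w = _check_input_shape(input_shape)
        rng = nn._rng(rng)
        w1, w2 = widths
        self.input_shape = (c, h, w)
        self.d = d
        self.widths = tuple(widths)
        hh, ww = h // 4, w // 4
        flat = w2 * hh * ww
        self.encoder = nn.Sequential(
            nn.Conv2d(c, w1, kernel=4, stride=2, pad=1, rng=rng),
            nn.BatchNorm2d(w1),
            nn.LeakyReLU(),
            nn.Conv2d(w1, w2, kernel=4, stride=2, pad=1, rng=rng),
            nn.BatchNorm2d(w2),
            nn.LeakyReLU(),
            nn.Flatten(),
        )
        self.head_mean = nn.Sequential(nn.Dense(flat, d, rng=rng))
        self.head_logvar = nn.Sequential(nn.Dense(flat, d, rng=rng))
        self.decoder = nn.Sequential(
            nn.Dense(d, flat, rng=rng),
            nn.Reshape((w2, hh, ww)),
            nn.ConvTranspose2d(w2, w1, kernel=4, stride=2, pad=1, rng=rng),
            nn.BatchNorm2d(w1),
            nn.LeakyReLU(),
            nn.ConvTranspose2d(w1, c, kernel=4, stride=2, pad=1, rng=rng),
            nn.Sigmoid(),
        )
        self.kl_weight = 1.0

    # -- inference ----------------------------------------------------------
    def encode(self, x: np.ndarray, train: bool = False):
        """Map images to (mean, log-variance) latent vectors."""
        h = self.encoder.forward(x, train=train)
        return (self.head_mean.forward(h, train=train),
                self.head_logvar.forward(h, train=train))

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.decoder.forward(z, train=train)

    # -- training -----------------------------------------------------------
    def loss_backward(self, x: np.ndarray, y=None,
                      rng: np.random.Generator | None = None) -> float:
        """One forward/backward pass; accumulates gradients, returns loss."""
        rng = rng if rng is not None else np.random.default_rng(0)
        h = self.encoder.forward(x, train=True)
        mean = self.head_mean.forward(h, train=True)
        logvar = self.head_logvar.forward(h, train=True)
        eps = rng.standard_normal(mean.shape)
        sigma = np.exp(0.5 * logvar)
        z = mean + sigma * eps
        recon = self.decoder.forward(z, train=True)

        total, _, _ = vae_loss(x, recon, mean, logvar, kl_weight=self.kl_weight)
        n = x.shape[0]
        dz = self.decoder.backward(2.0 * (recon - x) / n)
        dmean = dz + self.kl_weight * mean / n
        dlogvar = (dz * eps * 0.5 * sigma
                   + self.kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n)
        dh = self.head_mean.backward(dmean) + self.head_logvar.backward(dlogvar)
        self.encoder.backward(dh)
        return float(total)

    # -- plumbing -----------------------------------------------------------
    def zero_grad(self):
        for part in (self.encoder, self.head_mean, self.head_logvar,
                     self.decoder):
            part.zero_grad()

    def named_params(self):
        for prefix, part in (("enc", self.encoder), ("mu", self.head_mean),
                             ("lv", self.head_logvar), ("dec", self.decoder)):
            for name, params, grads, key in part.named_params():
                yield f"{prefix}.{name}", params, grads, key

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        out.update(self.encoder.state_dict("enc."))
        out.update(self.head_mean.state_dict("mu."))
        out.update(self.head_logvar.state_dict("lv."))
        out.update(self.decoder.state_dict("dec."))
        return out

    def load_state_dict(self, state):
        self.encoder.load_state_dict(state, "enc.")
        self.head_mean.load_state_dict(state, "mu.")
        self.head_logvar.load_state_dict(state, "lv.")
        self.decoder.load_state_dict(state, "dec.")


class TaskCNN:
    """Small image classifier: two stride-2 convolutions, two dense layers."""

    def __init__(self, input_shape, n_classes: int, widths=(8, 16),
                 hidden: int = 64, rng=0):
        c, h, w = _check_input_shape(input_shape)
        rng = nn._rng(rng)
        w1, w2 = widths
        flat = w2 * (h // 4) * (w // 4)
        self.input_shape = (c, h, w)
        self.n_classes = n_classes
        self.net = nn.Sequential(
            nn.Conv2d(c, w1, kernel=3, stride=2, pad=1, rng=rng),
            nn.LeakyReLU(),
            nn.Conv2d(w1, w2, kernel=3, stride=2, pad=1, rng=rng),
            nn.LeakyReLU(),
            nn.Flatten(),
            nn.Dense(flat, hidden, rng=rng),
            nn.LeakyReLU(),
            nn.Dense(hidden, n_classes, rng=rng),
        )

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def loss_backward(self, x, y, rng=None) -> float:
        logits = self.net.forward(x, train=True)
        loss, dlogits = nn.softmax_cross_entropy(logits, y)
        self.net.backward(dlogits)
        return float(loss)

    def zero_grad(self):
        self.net.zero_grad()

    def named_params(self):
        yield from self.net.named_params()

    def state_dict(self):
        return self.net.state_dict()

    def load_state_dict(self, state):
        self.net.load_state_dict(state)


def build_vae(input_shape, d: int = 64, widths=(16, 32), seed: int = 0) -> VAEModel:
    """Construct a VAE for ``input_shape`` = (channels, height, width)."""
    return VAEModel(input_shape, d=d, widths=widths,
                    rng=np.random.default_rng(seed))


def build_task_cnn(input_shape, n_classes: int, widths=(8, 16),
                   hidden: int = 64, seed: int = 0) -> TaskCNN:
    return TaskCNN(input_shape, n_classes, widths=widths, hidden=hidden,
                   rng=np.random.default_rng(seed))


def vae_loss(x: np.ndarray, recon: np.ndarray, mean: np.ndarray,
             log_variance: np.ndarray, kl_weight: float = 1.0):
    """ELBO-style loss: (total, reconstruction term, KL term).

    Reconstruction: squared error summed over pixels, mean over the batch.
    KL: 0.5 * sum_dims(mu^2 + sigma^2 - log sigma^2 - 1), mean over batch —
    zero exactly when the posterior is N(0, I), and non-negative always.
    """
    if x.shape != recon.shape or mean.shape != log_variance.shape:
        raise ValueError("shape mismatch between inputs")
    if not (np.all(np.isfinite(recon)) and np.all(np.isfinite(mean))
            and np.all(np.isfinite(log_variance))):
        raise FloatingPointError("non-finite values in VAE outputs")
    n = x.shape[0]
    recon_term = float(((recon - x) ** 2).sum() / n)
    kl_term = float(0.5 * (mean ** 2 + np.exp(log_variance)
                           - log_variance - 1.0).sum() / n)
    return recon_term + kl_weight * kl_term, recon_term, kl_term


def _as_arrays(shard):
    if isinstance(shard, ClientDataset):
        images, labels, _ = shard.training_arrays()
        return images, labels
    images, labels = shard
    return np.asarray(images), (None if labels is None else np.asarray(labels))


def train_local(model, shard, config: TrainingConfig, epochs: int | None = None,
                seed: int | None = None):
    """Train ``model`` on one shard for ``epochs`` epochs of minibatch Adam.

    ``shard`` is a :class:`~feddis.partitioning.ClientDataset` (augmented
    samples included) or an (images, labels) pair; labels may be None for
    the VAE. Returns ``(state_dict, loss_trace)`` where ``loss_trace`` is
    the per-epoch mean minibatch loss; the model is updated in place. The
    whole procedure — shuffling, reparameterization noise, optimizer — is
    driven by a single seeded generator, so identical (model, shard,
    config, seed) give bit-identical results.
    """
    images, labels = _as_arrays(shard)
    if len(images) == 0:
        raise ValueError("cannot train on an empty shard")
    if epochs is None:
        epochs = config.local_epochs_per_round
    if epochs == 0:
        return model.state_dict(), []
    if hasattr(model, "kl_weight"):
        model.kl_weight = config.kl_weight
    rng = np.random.default_rng(config.seed if seed is None else seed)
    opt = nn.Adam(lr=config.learning_rate)
    trace = []
    n = len(images)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = images[idx]
            yb = None if labels is None else labels[idx]
            model.zero_grad()
            losses.append(model.loss_backward(xb, yb, rng=rng))
            opt.step(model.named_params())
        trace.append(float(np.mean(losses)))
    return model.state_dict(), trace


def save_checkpoint(state: "OrderedDict[str, np.ndarray]", path) -> None:
    """Save a parameter snapshot as a single ``.npz`` archive."""
    np.savez(path, **state)


def load_checkpoint(path) -> "OrderedDict[str, np.ndarray]":
    with np.load(path) as data:
        return OrderedDict((k, data[k].copy()) for k in data.files)
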