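# Methods

## Model and procedure

The package addresses label-skew non-IIDness in cross-silo federated
image classification by *indirect* data sharing: clients exchange the
parameters of class-conditional latent-space distributions instead of
images.

A convolutional VAE is first trained federally (FedAvg over all clients).
Its encoder maps an image to a diagonal-Gaussian posterior (mean m,
variance diag(σ²)) in a d-dimensional latent space. Each encoding is
expanded into 2d σ-points, m ± α·sqrt(σ²ₙ)·eₙ, whose empirical mean equals
m exactly and whose population covariance equals (α²/d)·diag(σ²); the
expansion multiplies the number of latent samples per image by 2d without
drawing noise, and avoids decodable single samples at the posterior mean.
σ-points are pooled per class label, a per-dimension distribution family
is fitted, and the fitted parameters θ plus per-class counts are shared.
Receiving clients sample each foreign class-conditional θ (count-matched
to the sender's holdings) and decode, so every merged shard acquires the
global label histogram exactly; pairwise label-distribution EMD drops to
zero by construction. The task classifier is then trained with ordinary
FedAvg on the merged shards.

Assumptions: the latent geometry is shared (all clients build their
DistributionInfo from the *aggregated* VAE, never a local one); labels are
nominal and trustworthy; class-conditional latent distributions are
adequately summarized per dimension (no cross-covariance, see below); and
client counts reported in the payload are truthful — heterogeneity
elimination is exact only under truthful counts.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| d (latent dim) | 64 | dimensionality of the latent space; a config value, smaller values (16) suffice for 32×32 fixtures and make the per-class fit better conditioned |
| α (σ-point placement) | 2.0 | scales the σ-point spread; together with the `uniform` family the best-performing setting in the reference experiments |
| family | uniform | per-dimension latent family; `normal` and `truncated_normal` are supported |
| learning rate | 1e-4 | Adam, for both VAE and task model |
| batch size | 64 | minibatch size for local training |
| local epochs / round | 2 | clients upload parameters after every two local epochs |
| active ratio r | 1.0 | fraction of clients sampled per round (0.5 in the many-client configuration) |
| KL weight | 1.0 | unit-weight ELBO by default; exposed for annealing |
| β (Dirichlet) | — | label-skew concentration for the Dirichlet partitioner; smaller β, more skew |
| std floor | 1e-6 | degenerate (zero-variance) latent dimensions are clamped here with a warning |

The VAE objective is the standard ELBO with a Gaussian likelihood:
squared reconstruction error **summed over pixels** (mean over the batch)
plus the closed-form KL of the diagonal posterior from N(0, I). Summing
over pixels keeps the two terms on the ELBO's natural scale; a per-pixel
mean would let the KL term dominate and collapse the posterior, defeating
the σ-point expansion (which needs informative per-image variances).

Estimators: uniform → per-dimension min/max; normal → sample mean and
sample std (ddof=1); truncated normal → sample min/max as bounds plus
sample mean/std. Truncated-normal sampling uses rejection with a capped
number of rounds, falling back to the clipped inverse-CDF transform
(exact; the clip only guards floating-point overshoot at the bounds).

## Federation mechanics

One communication round = local training for `local_epochs_per_round`
epochs on each sampled client followed by one FedAvg aggregation,
Σᵢ nᵢwᵢ / Σᵢ nᵢ over all parameters and batch-norm running statistics.
Weights are normalized before averaging, so a single-client round returns
its update bit-identically; with m=1 and r=1 the federation is
bit-identical to standalone local training (tested). Client sampling is
uniform without replacement, fresh each round. Stage-2 weights use
post-augmentation shard sizes by default (equalized by construction, so
aggregation is effectively uniform); a switch restores original-count
weighting. All per-round, per-client seeds derive from one base seed via
`SeedSequence`, making every experiment reproducible end to end. The
simulation is single-process with in-memory message passing; the
DistributionInfo JSON file is the unit of exchange.

Proportion-based partitions shuffle each class (seeded) and give client j
`round(fraction·count)` samples with the remainder absorbed by the last
client — the convention that reproduces the reference three-client shard
sizes (2049, 1024, 2048) from a 2560+2561 split. The EMD between client
label distributions uses the categorical unit-cost ground metric, under
which the optimal transport cost is half the L1 distance; class labels
are nominal, so any geometric ground metric would be arbitrary.

## Synthetic data

`make_image_dataset` emulates a small grayscale imaging dataset: each
class is a Gaussian blob at a class-specific position (on a circle) with a
class-specific width, under per-sample center jitter, amplitude variation
and additive pixel noise, clipped to [0, 1]. The default fixture is
2 classes × 300 training + 100 test images of 1×32×32; `difficulty`
("easy"/"hard") sets jitter and noise amplitudes. It reproduces the
*structure* the method needs — class-dependent image statistics that a
VAE can capture and a small CNN can classify — but none of the hardness of
real medical images: no anatomical variability, acquisition artifacts,
class overlap or long-tailed appearance. Passing tests therefore
demonstrate the mechanics (heterogeneity elimination, estimator
consistency, federation correctness), not clinical-grade accuracy. On
this fixture the classification task saturates: both FedDIS and FedAvg
reach ceiling accuracy at desk scale, so the end-to-end comparison
verifies that augmentation does not harm accuracy while removing
heterogeneity, rather than a strict accuracy gap.

Desk-scale experiment sizes (the package's own choices): end-to-end runs
use d=16, 15 VAE rounds, 12 task rounds, learning rate 1e-3, three seeds;
Dirichlet ordering uses 2,000 samples, 10 classes, 10 clients, 20 seeds.

## Numerical choices and edge cases

- All arithmetic is float64; inference (encoding, decoding, evaluation)
  runs with batch-norm in running-statistics mode, so it is a
  deterministic function of the inputs.
- Accuracy ties break toward the lowest class index (argmax convention).
- SSIM uses the standard windowed formulation with default constants and
  `data_range=1.0` per the pixel normalization.
- Dirichlet partitions that leave a client empty are redrawn up to a retry
  cap (default 100) before erroring.
- Proportion rows must sum to 1 within 1e-9; probability vectors passed to
  `emd` must sum to 1 within 1e-6.
- `fedavg_aggregate` refuses mismatched parameter names/shapes and
  non-positive weights.

## Limitations

- Per-dimension independent latent families only: no cross-covariance,
  mixtures or flows. Strongly multi-modal within-class latent structure is
  summarized coarsely (the uniform family covers the support but flattens
  its shape).
- No formal privacy accounting: set distance, max-SSIM and Dpgo are
  empirical indicators, not differential-privacy guarantees, and the DI
  payload itself is shared in the clear.
- Batch-norm running statistics are FedAvg-averaged like ordinary
  parameters — standard practice, but approximate under severe
  heterogeneity.
- Single-process simulation: no stragglers, asynchrony, compression or
  secure aggregation.
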