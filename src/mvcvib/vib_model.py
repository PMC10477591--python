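"""The multi-view convolutional variational information bottleneck model.

Each data view gets a dedicated stochastic encoder producing a diagonal
Gaussian posterior over a shared K-dimensional latent code U. The abundance
view's encoder starts with a 2-D convolution + max-pooling front end (the
vector is zero-padded to the smallest square grid), followed by three fully
connected SiLU layers; the distance view uses the same fully connected head
without convolution. The per-view posteriors are fused with the standard
normal prior by a product of experts — for diagonal Gaussians the product
is Gaussian with summed precisions — and a latent sample u = mu + sigma*eps
is decoded by logistic regression sigmoid(w'u + b).

The training objective is the variational information bottleneck:

    J = (1/N) sum_n [ -log q(y_n | u_n) ]  +  beta * (1/N) sum_n KL[q(U|x_n) || N(0, I)]

with q(U|x_n) the joint product-of-experts posterior of sample n and a
single reparameterized draw per sample per step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._autograd import Tensor, conv2d_same, maxpool2d
from .io_tables import AbundanceTable
from .views import MultiViewInput

__all__ = [
    "ModelConfig",
    "GaussianPosterior",
    "init_params",
    "encode_view",
    "poe_combine",
    "reparameterize",
    "decode",
    "kl_to_standard_normal",
    "mvcvib_loss",
    "loss_and_grads",
    "predict_proba",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and objective hyperparameters.

    Defaults follow the published setting where one exists (K = 256,
    beta = 1e-5, dropout 0.2, SiLU activations, three fully connected
    layers, one 2-D convolution + max-pooling on the abundance view);
    quantities the publication leaves open (hidden widths, convolution
    channels/kernel, optimizer settings) are explicit here and
    configurable.
    """

    latent_dim: int = 256
    beta: float = 1e-5
    dropout_p: float = 0.2
    activation: str = "silu"
    multi_view: bool = True
    use_conv: bool = True
    conv_channels: int = 8
    conv_kernel: int = 3
    pool_size: int = 2
    hidden_sizes: tuple[int, int, int] = (512, 256, 256)
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    seed: int = 42
    squared_distance: bool = False

    def __post_init__(self):
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.activation != "silu":
            raise ValueError("only the SiLU activation is supported")
        if len(self.hidden_sizes) != 3:
            raise ValueError("exactly three fully connected layers are used")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


@dataclass(frozen=True)
class GaussianPosterior:
    """Diagonal Gaussian q(U) = N(mu, diag sigma^2) over the latent code."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=np.float64)
        sigma = np.asarray(self.sigma, dtype=np.float64)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have identical shape")
        if not (np.all(np.isfinite(sigma)) and np.all(sigma > 0)):
            raise ValueError("sigma must be positive and finite")


# ----------------------------------------------------------------------
# parameters


def _grid_side(dim: int) -> int:
    """Side of the smallest square grid holding a `dim`-vector."""
    return int(math.ceil(math.sqrt(dim)))


def _fc_input_dim(view_name: str, input_dim: int, config: ModelConfig) -> int:
    if view_name == "abundance" and config.use_conv:
        s = _grid_side(input_dim)
        pooled = s // config.pool_size
        if pooled == 0:
            raise ValueError("pool_size too large for input grid")
        return config.conv_channels * pooled * pooled
    return input_dim


def init_params(
    config: ModelConfig,
    input_dims: Mapping[str, int],
    rng: np.random.Generator,
) -> dict[str, Tensor]:
    """He-style initialization of all encoder and decoder weights.

    The (mu, logvar) output heads start near zero so the initial posterior
    is close to the standard-normal prior.
    """
    params: dict[str, Tensor] = {}

    def weight(name, fan_in, shape, scale=None):
        std = scale if scale is not None else math.sqrt(2.0 / fan_in)
        params[name] = Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

    def zeros(name, shape):
        params[name] = Tensor(np.zeros(shape), requires_grad=True)

    K = config.latent_dim
    for view, dim in input_dims.items():
        if view == "abundance" and config.use_conv:
            k, c = config.conv_kernel, config.conv_channels
            weight(f"{view}.conv_w", k * k, (c, 1, k, k))
            zeros(f"{view}.conv_b", (c,))
        fan = _fc_input_dim(view, dim, config)
        for i, h in enumerate(config.hidden_sizes, start=1):
            weight(f"{view}.fc{i}_w", fan, (fan, h))
            zeros(f"{view}.fc{i}_b", (h,))
            fan = h
        # output layer emits 2K numbers: K means and K log-variances
        weight(f"{view}.mu_w", fan, (fan, K), scale=1e-2)
        zeros(f"{view}.mu_b", (K,))
        weight(f"{view}.logvar_w", fan, (fan, K), scale=1e-2)
        zeros(f"{view}.logvar_b", (K,))
    weight("decoder.w", K, (K, 1), scale=1.0 / math.sqrt(K))
    zeros("decoder.b", (1,))
    return params


# ----------------------------------------------------------------------
# forward pass (autodiff tensor path)


def _encode_tensor(
    x: np.ndarray,
    view_name: str,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    training: bool,
    dropout_rng: np.random.Generator | None,
) -> tuple[Tensor, Tensor]:
    """Encode a (N, dim) batch for one view; returns (mu, logvar), each (N, K)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n, dim = x.shape
    if training and config.dropout_p > 0 and dropout_rng is None:
        raise ValueError("training-mode encoding with dropout needs an rng")

    if view_name == "abundance" and config.use_conv:
        s = _grid_side(dim)
        padded = np.zeros((n, s * s))
        padded[:, :dim] = x  # zero-pad to the smallest square, row-major
        t = Tensor(padded.reshape(n, 1, s, s))
        t = conv2d_same(t, params[f"{view_name}.conv_w"],
                        params[f"{view_name}.conv_b"]).silu()
        t = maxpool2d(t, config.pool_size)
        t = t.reshape(n, -1)
    else:
        t = Tensor(x)

    for i in range(1, 4):
        t = (t @ params[f"{view_name}.fc{i}_w"] + params[f"{view_name}.fc{i}_b"]).silu()
        if training and config.dropout_p > 0:
            keep = 1.0 - config.dropout_p
            mask = (dropout_rng.random(t.shape) < keep) / keep
            t = t * mask

    mu = t @ params[f"{view_name}.mu_w"] + params[f"{view_name}.mu_b"]
    logvar = t @ params[f"{view_name}.logvar_w"] + params[f"{view_name}.logvar_b"]
    return mu, logvar


def _poe_tensor(mus: Sequence[Tensor], logvars: Sequence[Tensor]) -> tuple[Tensor, Tensor]:
    """Product-of-experts fusion with the N(0, I) prior, on (N, K) batches.

    Precisions add: T = 1 + sum_i sigma_i^-2; mean = sum_i mu_i sigma_i^-2 / T.
    Returns (mu, var) of the joint Gaussian.
    """
    if not mus:
        raise ValueError("tensor PoE path requires at least one expert")
    precision_sum = None
    weighted_mu = None
    for mu, logvar in zip(mus, logvars):
        prec = (-logvar).exp()
        term = mu * prec
        precision_sum = prec if precision_sum is None else precision_sum + prec
        weighted_mu = term if weighted_mu is None else weighted_mu + term
    total_precision = precision_sum + 1.0  # the prior expert
    return weighted_mu / total_precision, 1.0 / total_precision


def _forward(
    batch_views: MultiViewInput,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    training: bool,
    epsilon: np.ndarray | None,
    dropout_rng: np.random.Generator | None,
) -> tuple[Tensor, Tensor, Tensor]:
    """Full forward pass; returns (logits (N,), joint mu (N,K), joint var (N,K))."""
    mus, logvars = [], []
    for name, x in zip(batch_views.view_names, batch_views.views):
        mu, logvar = _encode_tensor(x, name, params, config, training, dropout_rng)
        mus.append(mu)
        logvars.append(logvar)
    mu_joint, var_joint = _poe_tensor(mus, logvars)
    if epsilon is None:
        u = mu_joint  # posterior mean at evaluation time
    else:
        eps = np.asarray(epsilon, dtype=np.float64)
        if eps.shape != mu_joint.shape:
            raise ValueError(f"epsilon shape {eps.shape} != {mu_joint.shape}")
        u = mu_joint + var_joint ** 0.5 * eps
    n = u.shape[0]
    logits = (u @ params["decoder.w"] + params["decoder.b"]).reshape(n)
    return logits, mu_joint, var_joint


def _loss_tensor(
    batch_views: MultiViewInput,
    labels: np.ndarray,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    epsilon: np.ndarray | None,
    training: bool = True,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    y = np.asarray(labels, dtype=np.float64)
    logits, mu, var = _forward(batch_views, params, config, training, epsilon,
                               dropout_rng)
    # stable binary cross-entropy: softplus(z) - y z = -[y log s(z) + (1-y) log(1-s(z))]
    nll = (logits.softplus() - logits * y).mean()
    kl = (0.5 * (mu ** 2.0 + var - 1.0 - var.log()).sum(axis=1)).mean()
    total = nll + config.beta * kl
    return total, nll, kl


# ----------------------------------------------------------------------
# public numpy-level operations


def encode_view(
    x: np.ndarray,
    view_name: str,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    training: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> GaussianPosterior:
    """Encode one sample (1-D) or a batch (2-D) into its view posterior."""
    single = np.asarray(x).ndim == 1
    mu, logvar = _encode_tensor(x, view_name, params, config, training, dropout_rng)
    mu_a, sigma_a = mu.data, np.exp(logvar.data / 2.0)
    if single:
        mu_a, sigma_a = mu_a[0], sigma_a[0]
    return GaussianPosterior(mu_a, sigma_a)


def poe_combine(
    posteriors: Sequence[GaussianPosterior],
    latent_dim: int | None = None,
) -> GaussianPosterior:
    """Fuse expert posteriors with the standard-normal prior.

    An empty list returns the prior itself (``latent_dim`` must then be
    given); absent views are thereby marginalized naturally — the product
    runs over present experts only.
    """
    if not posteriors:
        if latent_dim is None:
            raise ValueError("empty expert list: latent_dim is required")
        return poe_combine_prior(latent_dim)
    K = posteriors[0].mu.shape
    precision = np.ones(K)
    weighted = np.zeros(K)
    for p in posteriors:
        if p.mu.shape != K:
            raise ValueError("mismatched latent dimension across experts")
        prec = 1.0 / p.sigma ** 2
        precision += prec
        weighted += p.mu * prec
    return GaussianPosterior(weighted / precision, 1.0 / np.sqrt(precision))


def poe_combine_prior(latent_dim: int) -> GaussianPosterior:
    """The empty product: the N(0, I) prior."""
    return GaussianPosterior(np.zeros(latent_dim), np.ones(latent_dim))


def reparameterize(posterior: GaussianPosterior, epsilon: np.ndarray) -> np.ndarray:
    """u = mu + sigma * eps (elementwise)."""
    eps = np.asarray(epsilon, dtype=np.float64)
    if eps.shape != posterior.mu.shape:
        raise ValueError("epsilon must match the posterior shape")
    return posterior.mu + posterior.sigma * eps


def decode(u: np.ndarray, params: Mapping[str, Tensor]) -> float | np.ndarray:
    """Logistic decoder q(y=1|u) = sigmoid(w'u + b), strictly in (0, 1)."""
    u = np.asarray(u, dtype=np.float64)
    w = params["decoder.w"].data[:, 0]
    b = params["decoder.b"].data[0]
    z = u @ w + b
    out = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                   np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return float(out) if out.ndim == 0 else out


def kl_to_standard_normal(posterior: GaussianPosterior) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)).

    0.5 * sum_k (mu_k^2 + sigma_k^2 - 1 - ln sigma_k^2); nonnegative.
    """
    mu, sigma = posterior.mu, posterior.sigma
    return float(0.5 * np.sum(mu ** 2 + sigma ** 2 - 1.0 - 2.0 * np.log(sigma)))


def mvcvib_loss(
    batch_views: MultiViewInput,
    labels: np.ndarray,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    epsilon: np.ndarray | None,
    training: bool = True,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Evaluate the objective on a batch; returns (total, nll, kl)."""
    total, nll, kl = _loss_tensor(batch_views, labels, params, config, epsilon,
                                  training, dropout_rng)
    return total.item(), nll.item(), kl.item()


def loss_and_grads(
    batch_views: MultiViewInput,
    labels: np.ndarray,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    epsilon: np.ndarray | None,
    training: bool = True,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[tuple[float, float, float], dict[str, np.ndarray]]:
    """Objective value plus backpropagated gradients for every parameter."""
    for p in params.values():
        p.grad = None
    total, nll, kl = _loss_tensor(batch_views, labels, params, config, epsilon,
                                  training, dropout_rng)
    total.backward()
    grads = {name: (p.grad if p.grad is not None else np.zeros_like(p.data))
             for name, p in params.items()}
    return (total.item(), nll.item(), kl.item()), grads


def predict_proba(
    batch_views: MultiViewInput,
    params: Mapping[str, Tensor],
    config: ModelConfig,
) -> np.ndarray:
    """Deterministic class-1 probabilities using the posterior mean latent."""
    logits, _, _ = _forward(batch_views, params, config, training=False,
                            epsilon=None, dropout_rng=None)
    z = logits.data
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                    np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


# ----------------------------------------------------------------------
# persistence


def save_checkpoint(
    path: str | Path,
    params: Mapping[str, Tensor],
    config: ModelConfig,
    reference: AbundanceTable,
) -> None:
    """Write weights (+ the training reference table needed to rebuild the
    distance view) to ``<path>.npz`` with a JSON config sidecar ``<path>.json``."""
    path = Path(path)
    arrays = {f"param/{k}": v.data for k, v in params.items()}
    arrays["reference/values"] = reference.values
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "config": config.to_dict(),
        "reference_sample_ids": list(reference.sample_ids),
        "feature_ids": list(reference.feature_ids),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[dict[str, Tensor], ModelConfig, AbundanceTable]:
    """Restore a checkpoint; forward passes are bit-identical to pre-save."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig.from_dict(sidecar["config"])
    with np.load(path.with_suffix(".npz")) as npz:
        params = {k[len("param/"):]: Tensor(npz[k], requires_grad=True)
                  for k in npz.files if k.startswith("param/")}
        reference = AbundanceTable(
            tuple(sidecar["reference_sample_ids"]),
            tuple(sidecar["feature_ids"]),
            npz["reference/values"],
        )
    return params, config, reference
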