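"""Loss components of the conditional VAE and its extensions.

Each loss exists in two forms: a graph form operating on autodiff
:class:`~crossvae.nn.autodiff.Tensor` objects (used by the trainer) and a
plain-array convenience wrapper returning a float. Conventions, fixed
throughout the package:

* reconstruction: negative Gaussian log-likelihood with unit variance,
  additive constant dropped — ``0.5 * mean_cells( sum_genes (x - x_hat)^2 )``;
* KL terms: summed over latent dimensions, averaged over cells;
* cycle distance: per-dimension minibatch standardisation (mean and
  population std, separately for the original and the cycled set), then
  mean squared difference over all entries;
* adversarial: mean cross-entropy of the discriminator on system labels.
"""

from __future__ import annotations

import numpy as np

from .nn.autodiff import Tensor, logsumexp

_LOG2PI = float(np.log(2.0 * np.pi))
EPS = 1e-8


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.atleast_2d(np.asarray(x, dtype=float)))


# -- reconstruction ------------------------------------------------------------


def gaussian_nll_t(x: Tensor, x_hat: Tensor, include_const: bool = False) -> Tensor:
    diff = x - x_hat
    out = (diff * diff).sum(axis=1).mean() * 0.5
    if include_const:
        out = out + 0.5 * _LOG2PI * x.shape[1]
    return out


def reconstruction_loss(x, x_hat, include_const: bool = False) -> float:
    """Unit-variance Gaussian NLL on normalised-log expression (scaled MSE)."""
    x, x_hat = _t(x), _t(x_hat)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(gaussian_nll_t(x, x_hat, include_const).data)


# -- KL divergences ------------------------------------------------------------


def kl_standard_t(mu: Tensor, logvar: Tensor) -> Tensor:
    var = logvar.exp()
    return ((mu * mu + var - 1.0 - logvar).sum(axis=1) * 0.5).mean()


def kl_standard(mu, logvar) -> float:
    """Closed-form KL( N(mu, diag e^logvar) || N(0, I) ), mean over cells."""
    return float(kl_standard_t(_t(mu), _t(logvar)).data)


def diag_gaussian_log_prob_t(z: Tensor, mu: Tensor, logvar: Tensor) -> Tensor:
    """Log N(z; mu, diag e^logvar) summed over the trailing dimension."""
    diff = z - mu
    return ((diff * diff) / logvar.exp() + logvar + _LOG2PI).sum(axis=-1) * -0.5


def mixture_log_prob_t(
    z: Tensor, comp_mu: Tensor, comp_logvar: Tensor, weight_logits: Tensor
) -> Tensor:
    """Log density of a Gaussian mixture at z.

    z: (..., D); comp_mu/comp_logvar: (L, D); weight_logits: (L,).
    Returns shape (...,). Uses log-sum-exp over components.
    """
    log_w = weight_logits - logsumexp(weight_logits, axis=0, keepdims=True)
    z_exp = z.reshape(*z.shape[:-1], 1, z.shape[-1])
    comp_lp = diag_gaussian_log_prob_t(z_exp, comp_mu, comp_logvar)  # (..., L)
    return logsumexp(comp_lp + log_w, axis=-1)


def mixture_log_prob(z, comp_mu, comp_logvar, weight_logits) -> np.ndarray:
    out = mixture_log_prob_t(
        Tensor(np.atleast_2d(z)), Tensor(np.atleast_2d(comp_mu)),
        Tensor(np.atleast_2d(comp_logvar)), Tensor(np.asarray(weight_logits, float)),
    )
    return np.asarray(out.data)


def kl_mixture_t(
    z: Tensor,
    mu_q: Tensor,
    logvar_q: Tensor,
    comp_mu: Tensor,
    comp_logvar: Tensor,
    weight_logits: Tensor,
) -> Tensor:
    """Single-draw MC term E_q[log q(z) - log p(z)] given sampled z (..., B, D)."""
    log_q = diag_gaussian_log_prob_t(z, mu_q, logvar_q)
    log_p = mixture_log_prob_t(z, comp_mu, comp_logvar, weight_logits)
    return (log_q - log_p).mean()


def kl_mixture(
    mu, logvar, comp_mu, comp_logvar, weight_logits, n_mc: int = 1, seed: int = 0
) -> float:
    """Monte-Carlo KL( q || mixture prior ), averaged over n_mc draws and cells."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    mu = np.atleast_2d(np.asarray(mu, float))
    logvar = np.atleast_2d(np.asarray(logvar, float))
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_mc,) + mu.shape)
    z = mu[None] + np.exp(0.5 * logvar)[None] * eps
    out = kl_mixture_t(
        Tensor(z), Tensor(mu), Tensor(logvar),
        Tensor(np.atleast_2d(comp_mu)), Tensor(np.atleast_2d(comp_logvar)),
        Tensor(np.asarray(weight_logits, float)),
    )
    return float(out.data)


# -- cycle consistency ---------------------------------------------------------


def standardize_t(z: Tensor) -> Tensor:
    """Per-dimension z-score with batch mean and population std (+eps guard)."""
    if z.shape[0] < 2:
        raise ValueError("standardisation needs a minibatch of at least 2 cells")
    m = z.mean(axis=0, keepdims=True)
    centered = z - m
    std = (centered * centered).mean(axis=0, keepdims=True).sqrt() + EPS
    return centered / std


def cycle_mse_t(z: Tensor, z_cyc: Tensor) -> Tensor:
    diff = standardize_t(z) - standardize_t(z_cyc)
    return (diff * diff).mean()


def standardized_mse(z, z_cyc) -> float:
    """Cycle distance: MSE between separately standardised latent sets."""
    z, z_cyc = _t(z), _t(z_cyc)
    if z.shape != z_cyc.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {z_cyc.shape}")
    return float(cycle_mse_t(z, z_cyc).data)


# -- adversarial ---------------------------------------------------------------


def cross_entropy_t(logits: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=int)
    lse = logsumexp(logits, axis=1)
    picked = logits[(np.arange(logits.shape[0]), labels)]
    return (lse - picked).mean()


def cross_entropy(logits, labels) -> float:
    return float(cross_entropy_t(_t(logits), labels).data)
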