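"""Conditional VAE for cross-system integration, statsmodels-style.

:class:`CrossSystemVAE` is constructed from a normalised-log
:class:`~crossvae.data.ExpressionDataset` plus a :class:`ModelConfig`;
``fit()`` trains a fresh set of parameters and returns a
:class:`VAEResults` object carrying the trained state, the per-epoch loss
history and diagnostics (latent extraction, active-dimension counts,
prior-component assignment, a ``summary()`` table).

The architecture: an encoder MLP maps ``[x, one-hot(system, sample)]`` to a
diagonal Gaussian posterior over an ``n_latent``-dimensional code z; a
decoder MLP maps ``[z, one-hot]`` back to expression. The latent prior is
either standard normal, a VampPrior (mixture of the encoder's posteriors at
trainable pseudoinputs), or a Gaussian mixture parameterised directly in
latent space. Optional extensions: a latent cycle-consistency penalty on
system-swapped counterfactuals, or an adversarial system discriminator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import h5py
import numpy as np
import pandas as pd

from .data import CovariateEncoding, ExpressionDataset, ProcessingState, encode_covariates
from .losses import (
    EPS,
    cross_entropy_t,
    cycle_mse_t,
    gaussian_nll_t,
    kl_mixture_t,
    kl_standard_t,
)
from .nn.autodiff import Tensor, concat
from .nn.layers import MLP, Adam, GaussianHead

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LatentPosterior",
    "ModelState",
    "CrossSystemVAE",
    "VAEResults",
    "init_prior",
    "default_n_epochs",
]


@dataclass
class ModelConfig:
    """Architecture and loss weights.

    Defaults follow common large-scale integration practice: 2 hidden
    layers of 256 units, 15 latent dimensions, 5 prior components for the
    mixture priors.
    """

    n_latent: int = 15
    n_hidden: int = 256
    n_layers: int = 2
    prior: str = "standard"  # standard | vamp | gmm
    n_prior_components: int = 5
    vamp_trainable: bool = True
    gmm_init: str = "encoded_cells"  # encoded_cells | random_unit
    kl_weight: float = 1.0
    cycle_weight: float = 0.0
    adv_weight: float = 0.0  # Kappa
    disc_hidden: int = 256
    disc_layers: int = 2

    def __post_init__(self):
        if min(self.n_latent, self.n_hidden, self.n_layers) <= 0:
            raise ValueError("n_latent, n_hidden, n_layers must be positive")
        if self.prior not in ("standard", "vamp", "gmm"):
            raise ValueError(f"unknown prior {self.prior!r}")
        if self.n_prior_components < 1:
            raise ValueError("n_prior_components must be >= 1")
        if min(self.kl_weight, self.cycle_weight, self.adv_weight) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.cycle_weight > 0 and self.adv_weight > 0:
            raise ValueError(
                "cycle_weight and adv_weight are mutually exclusive in the "
                "shipped model variants"
            )


@dataclass
class TrainConfig:
    n_epochs: int | None = None
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    n_mc: int = 1  # MC draws for mixture-prior KL during training
    deterministic_latent_for_eval: bool = True

    def __post_init__(self):
        if self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("batch_size and learning_rate must be positive")


def default_n_epochs(n_cells: int) -> int:
    """Epoch rule scaling inversely with dataset size (~2e6 cell passes)."""
    return int(min(500, max(50, math.ceil(2e6 / n_cells))))


@dataclass
class LatentPosterior:
    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray


# -- priors --------------------------------------------------------------------


class StandardPrior:
    kind = "standard"


class VampPrior:
    """Mixture of encoder posteriors at (optionally trainable) pseudoinputs."""

    kind = "vamp"

    def __init__(self, pseudoinputs: np.ndarray, pseudo_cov: np.ndarray, trainable: bool):
        self.pseudoinputs = Tensor(pseudoinputs, requires_grad=trainable)
        self.pseudo_cov = np.asarray(pseudo_cov, dtype=float)
        self.weight_logits = Tensor(np.zeros(pseudoinputs.shape[0]), requires_grad=trainable)
        self.trainable = trainable

    @property
    def n_components(self) -> int:
        return self.pseudoinputs.shape[0]

    def component_params(self, encoder: GaussianHead) -> tuple[Tensor, Tensor]:
        inp = concat([self.pseudoinputs, Tensor(self.pseudo_cov)], axis=1)
        return encoder(inp)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.pseudoinputs, self.weight_logits] if self.trainable else []


class GmmPrior:
    """Trainable Gaussian mixture parameterised directly in latent space."""

    kind = "gmm"

    def __init__(self, means: np.ndarray, logvars: np.ndarray):
        self.means = Tensor(means, requires_grad=True)
        self.logvars = Tensor(logvars, requires_grad=True)
        self.weight_logits = Tensor(np.zeros(means.shape[0]), requires_grad=True)

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    def component_params(self, encoder=None) -> tuple[Tensor, Tensor]:
        return self.means, self.logvars

    @property
    def parameters(self) -> list[Tensor]:
        return [self.means, self.logvars, self.weight_logits]


def init_prior(
    config: ModelConfig,
    x: np.ndarray,
    cov: np.ndarray,
    seed: int,
    encoder: GaussianHead | None = None,
    restrict_mask: np.ndarray | None = None,
):
    """Build the prior state for a model.

    VampPrior components are cells sampled without replacement (optionally
    restricted via ``restrict_mask``, e.g. to one cell type or system); the
    sampled cell keeps its own covariate vector. GMM components are either
    sampled cells passed through the untrained encoder, or means drawn
    uniformly from [0, 1) with unit variance. Component weights start uniform.
    """
    if config.prior == "standard":
        return StandardPrior()
    rng = np.random.default_rng(seed)
    L = config.n_prior_components
    pool = np.flatnonzero(restrict_mask) if restrict_mask is not None else np.arange(len(x))
    if config.prior == "vamp" or config.gmm_init == "encoded_cells":
        if L > len(pool):
            raise ValueError(f"cannot sample {L} pseudoinputs from {len(pool)} cells")
        idx = rng.choice(pool, size=L, replace=False)
    if config.prior == "vamp":
        return VampPrior(x[idx].copy(), cov[idx].copy(), trainable=config.vamp_trainable)
    if config.gmm_init == "encoded_cells":
        if encoder is None:
            raise ValueError("encoded_cells GMM init needs the encoder")
        mu, logvar = encoder(Tensor(np.concatenate([x[idx], cov[idx]], axis=1)))
        return GmmPrior(mu.data.copy(), logvar.data.copy())
    if config.gmm_init == "random_unit":
        return GmmPrior(
            rng.uniform(0.0, 1.0, (L, config.n_latent)),
            np.zeros((L, config.n_latent)),
        )
    raise ValueError(f"unknown gmm_init {config.gmm_init!r}")


# -- model state ---------------------------------------------------------------


class ModelState:
    """Networks, prior state and covariate encoding of one (fitted) model."""

    def __init__(
        self,
        config: ModelConfig,
        encoding: CovariateEncoding,
        gene_ids: list[str],
        seed: int,
        x: np.ndarray | None = None,
        cov: np.ndarray | None = None,
    ):
        self.config = config
        self.encoding = encoding
        self.gene_ids = list(gene_ids)
        n_genes = len(gene_ids)
        rng = np.random.default_rng(seed)
        self.encoder = GaussianHead(
            n_genes + encoding.width, config.n_latent, config.n_hidden, config.n_layers, rng
        )
        self.decoder = MLP(
            config.n_latent + encoding.width, n_genes, config.n_hidden, config.n_layers, rng
        )
        self.discriminator = None
        if config.adv_weight > 0:
            if encoding.n_systems < 2:
                raise ValueError("adversarial training needs at least two systems")
            self.discriminator = MLP(
                config.n_latent, encoding.n_systems, config.disc_hidden, config.disc_layers, rng
            )
        if config.prior != "standard" and x is None:
            raise ValueError("mixture priors need data for initialisation")
        self.prior = (
            init_prior(config, x, cov, seed=seed + 1, encoder=self.encoder)
            if config.prior != "standard"
            else StandardPrior()
        )

    # -- train/eval mode -------------------------------------------------------
    def _norm_layers(self):
        nets = [self.encoder, self.decoder]
        if self.discriminator is not None:
            nets.append(self.discriminator)
        for net in nets:
            for norm in net.norms:
                if norm is not None:
                    yield norm

    def set_training(self, mode: bool) -> None:
        """Toggle minibatch-statistics mode on all normalisation layers."""
        for norm in self._norm_layers():
            norm.training = mode

    @property
    def training(self) -> bool:
        return any(norm.training for norm in self._norm_layers())

    # -- forward passes --------------------------------------------------------
    def encode_t(self, x: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        return self.encoder(concat([x, c], axis=1))

    def decode_t(self, z: Tensor, c: Tensor) -> Tensor:
        return self.decoder(concat([z, c], axis=1))

    def encode(
        self, x: np.ndarray, c: np.ndarray, deterministic: bool = True,
        rng: np.random.Generator | None = None,
    ) -> LatentPosterior:
        x = np.atleast_2d(np.asarray(x, float))
        c = np.atleast_2d(np.asarray(c, float))
        if x.shape[1] + c.shape[1] != len(self.gene_ids) + self.encoding.width:
            raise ValueError(
                f"expected {len(self.gene_ids)} genes + {self.encoding.width} covariates, "
                f"got {x.shape[1]} + {c.shape[1]}"
            )
        was_training = self.training
        self.set_training(False)
        try:
            mu, logvar = self.encode_t(Tensor(x), Tensor(c))
        finally:
            self.set_training(was_training)
        mu, logvar = mu.data, logvar.data
        if deterministic:
            z = mu.copy()
        else:
            rng = rng or np.random.default_rng()
            z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
        return LatentPosterior(mu=mu, logvar=logvar, z=z)

    def decode(self, z: np.ndarray, c: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, float))
        c = np.atleast_2d(np.asarray(c, float))
        if z.shape[1] != self.config.n_latent or c.shape[1] != self.encoding.width:
            raise ValueError("latent or covariate width mismatch")
        was_training = self.training
        self.set_training(False)
        try:
            return self.decode_t(Tensor(z), Tensor(c)).data
        finally:
            self.set_training(was_training)

    def prior_component_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if isinstance(self.prior, StandardPrior):
            raise ValueError("the standard prior has no components")
        was_training = self.training
        self.set_training(False)
        try:
            mu, logvar = self.prior.component_params(self.encoder)
        finally:
            self.set_training(was_training)
        return mu.data, logvar.data, self.prior.weight_logits.data

    def cycle_covariates(
        self, c: np.ndarray, system_idx: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Swap the system one-hot block to another system, keep the sample block.

        With more than two systems the target is drawn uniformly from the
        other systems per cell.
        """
        n_sys = self.encoding.n_systems
        if n_sys < 2:
            raise ValueError("cycling needs at least two systems")
        offsets = rng.integers(1, n_sys, size=len(system_idx))
        target = (system_idx + offsets) % n_sys
        c_j = c.copy()
        c_j[:, :n_sys] = 0.0
        c_j[np.arange(len(c)), target] = 1.0
        return c_j

    def cycle_consistency_loss(
        self, x: np.ndarray, c_i: np.ndarray, c_j: np.ndarray
    ) -> float:
        """Standardised-MSE cycle loss for an explicit covariate pair,
        computed on posterior means."""
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[0] < 2:
            raise ValueError("cycle loss needs a minibatch of at least 2 cells")
        n_sys = self.encoding.n_systems
        if np.any(c_i[:, n_sys:] != c_j[:, n_sys:]):
            raise ValueError("cycle covariates may differ only in the system block")
        z_i = self.encode(x, c_i, deterministic=True).mu
        x_cf = self.decode(z_i, c_j)
        z_j = self.encode(x_cf, c_j, deterministic=True).mu
        return float(cycle_mse_t(Tensor(z_i), Tensor(z_j)).data)

    # -- parameter bookkeeping -------------------------------------------------
    def main_parameters(self) -> list[Tensor]:
        params = self.encoder.parameters + self.decoder.parameters
        if not isinstance(self.prior, StandardPrior):
            params = params + self.prior.parameters
        return params

    def named_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.main_parameters()):
            out[f"main/{i}"] = p.data
        if self.discriminator is not None:
            for i, p in enumerate(self.discriminator.parameters):
                out[f"disc/{i}"] = p.data
        for i, norm in enumerate(self._norm_layers()):
            out[f"norm/{i}/mean"] = norm.running_mean
            out[f"norm/{i}/var"] = norm.running_var
        if isinstance(self.prior, VampPrior):
            out["prior/pseudo_cov"] = self.pseudo_cov_array()
        return out

    def pseudo_cov_array(self) -> np.ndarray:
        return self.prior.pseudo_cov

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "system_categories": self.encoding.system_categories,
            "sample_categories": self.encoding.sample_categories,
            "gene_ids": self.gene_ids,
        }
        with h5py.File(path, "w") as f:
            f.attrs["meta"] = json.dumps(meta)
            for name, arr in self.named_arrays().items():
                f.create_dataset(name, data=arr)
            if isinstance(self.prior, VampPrior):
                f.attrs["vamp_trainable"] = self.prior.trainable

    @classmethod
    def load(cls, path) -> "ModelState":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            config = ModelConfig(**meta["config"])
            encoding = CovariateEncoding(
                meta["system_categories"], meta["sample_categories"]
            )
            arrays = {name: f[name][...] for name in _h5_dataset_names(f)}
        # rebuild with dummy init data for mixture priors, then overwrite
        n_genes = len(meta["gene_ids"])
        dummy_x = np.zeros((max(2, config.n_prior_components), n_genes))
        dummy_c = np.zeros((max(2, config.n_prior_components), encoding.width))
        state = cls(config, encoding, meta["gene_ids"], seed=0, x=dummy_x, cov=dummy_c)
        for i, p in enumerate(state.main_parameters()):
            p.data = arrays[f"main/{i}"]
        if state.discriminator is not None:
            for i, p in enumerate(state.discriminator.parameters):
                p.data = arrays[f"disc/{i}"]
        for i, norm in enumerate(state._norm_layers()):
            norm.running_mean = arrays[f"norm/{i}/mean"]
            norm.running_var = arrays[f"norm/{i}/var"]
        state.set_training(False)
        if isinstance(state.prior, VampPrior):
            state.prior.pseudo_cov = arrays["prior/pseudo_cov"]
        return state


def _h5_dataset_names(f) -> list[str]:
    names = []
    f.visititems(lambda name, obj: names.append(name) if isinstance(obj, h5py.Dataset) else None)
    return names


# -- adversarial losses (spec surface) ------------------------------------------


def adversarial_losses(
    z: np.ndarray, system_labels: np.ndarray, discriminator: MLP, kappa: float = 1.0
) -> tuple[float, float]:
    """(discriminator cross-entropy, encoder penalty = -kappa * CE).

    Update separation is the caller's contract: the discriminator loss
    updates discriminator parameters only, the penalty updates encoder-side
    parameters only (the trainer enforces this with separate optimisers).
    """
    labels = np.asarray(system_labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("adversarial losses are undefined with a single system")
    logits = discriminator(Tensor(np.atleast_2d(z)))
    ce = float(cross_entropy_t(logits, labels).data)
    return ce, -kappa * ce


# -- the model / results pair ----------------------------------------------------


class CrossSystemVAE:
    """Conditional VAE built from an expression dataset.

    Parameters
    ----------
    dataset
        Normalised-log :class:`ExpressionDataset` with system and sample
        covariates.
    config
        :class:`ModelConfig`; keyword arguments override its fields.
    """

    def __init__(self, dataset: ExpressionDataset, config: ModelConfig | None = None, **kw):
        if dataset.state != ProcessingState.NORMALIZED_LOG:
            raise ValueError("the model expects normalised-log data; run preprocess() first")
        if config is None:
            config = ModelConfig(**kw)
        elif kw:
            config = ModelConfig(**{**asdict(config), **kw})
        self.config = config
        self.dataset = dataset
        self.encoding, self.cov = encode_covariates(dataset)
        self.x = dataset.dense()
        self.system_idx = np.array(
            [self.encoding.system_index(s) for s in dataset.system]
        )
        if config.adv_weight > 0 and self.encoding.n_systems < 2:
            raise ValueError("adversarial training needs at least two systems")

    @classmethod
    def from_anndata(cls, adata, system_key="system", sample_key="sample", **kw):
        ds = ExpressionDataset.from_anndata(adata, system_key=system_key, sample_key=sample_key)
        return cls(ds, **kw)

    def initialize_state(self, seed: int = 0) -> ModelState:
        return ModelState(
            self.config, self.encoding, self.dataset.gene_ids, seed,
            x=self.x, cov=self.cov,
        )

    # -- loss breakdown on one batch (spec surface) ----------------------------
    def total_loss(
        self, state: ModelState, idx: np.ndarray, seed: int = 0
    ) -> dict[str, float]:
        """Loss components and their weighted total on the given cells."""
        rng = np.random.default_rng(seed)
        parts = self._batch_losses(state, np.asarray(idx, int), rng, n_mc=1)
        breakdown = {k: float(v.data) for k, v in parts.items()}
        cfg = self.config
        breakdown["total"] = (
            breakdown["reconstruction"]
            + cfg.kl_weight * breakdown["kl"]
            + cfg.cycle_weight * breakdown["cycle"]
            + cfg.adv_weight * breakdown["adversarial_generator"]
        )
        return breakdown

    def _batch_losses(
        self, state: ModelState, idx: np.ndarray, rng: np.random.Generator, n_mc: int
    ) -> dict[str, Tensor]:
        cfg = self.config
        x = Tensor(self.x[idx])
        c = Tensor(self.cov[idx])
        mu, logvar = state.encode_t(x, c)
        eps = Tensor(rng.standard_normal(mu.shape))
        z = mu + (logvar * 0.5).exp() * eps
        x_hat = state.decode_t(z, c)
        parts: dict[str, Tensor] = {"reconstruction": gaussian_nll_t(x, x_hat)}

        if isinstance(state.prior, StandardPrior):
            parts["kl"] = kl_standard_t(mu, logvar)
        else:
            # pseudoinputs are encoded with running (eval-mode) statistics so
            # the tiny component batch neither distorts nor pollutes them
            was_training = state.training
            state.set_training(False)
            try:
                comp_mu, comp_logvar = state.prior.component_params(state.encoder)
            finally:
                state.set_training(was_training)
            if n_mc == 1:
                z_mc = z
            else:
                eps_mc = Tensor(rng.standard_normal((n_mc,) + mu.shape))
                z_mc = mu + (logvar * 0.5).exp() * eps_mc
            parts["kl"] = kl_mixture_t(
                z_mc, mu, logvar, comp_mu, comp_logvar, state.prior.weight_logits
            )

        if cfg.cycle_weight > 0:
            # noise-free cycle: compare posterior means; sampling noise in the
            # cycle pair otherwise puts a floor on the loss that is easiest to
            # reduce by trivialising the counterfactual
            c_j = Tensor(state.cycle_covariates(self.cov[idx], self.system_idx[idx], rng))
            x_cf = state.decode_t(mu, c_j)
            mu_j, _ = state.encode_t(x_cf, c_j)
            parts["cycle"] = cycle_mse_t(mu, mu_j)
        else:
            parts["cycle"] = Tensor(0.0)

        if cfg.adv_weight > 0:
            logits = state.discriminator(z)
            ce = cross_entropy_t(logits, self.system_idx[idx])
            parts["adversarial_disc"] = ce
            parts["adversarial_generator"] = -ce
        else:
            parts["adversarial_disc"] = Tensor(0.0)
            parts["adversarial_generator"] = Tensor(0.0)
        return parts

    # -- fitting ----------------------------------------------------------------
    def fit(self, train_config: TrainConfig | None = None, **kw) -> "VAEResults":
        tc = train_config or TrainConfig(**kw)
        if train_config is not None and kw:
            tc = TrainConfig(**{**asdict(train_config), **kw})
        n = self.dataset.n_cells
        n_epochs = tc.n_epochs or default_n_epochs(n)
        rng = np.random.default_rng(tc.seed)
        state = self.initialize_state(seed=int(rng.integers(0, 2**31 - 1)))
        cfg = self.config

        main_opt = Adam(state.main_parameters(), lr=tc.learning_rate)
        disc_opt = (
            Adam(state.discriminator.parameters, lr=tc.learning_rate)
            if state.discriminator is not None
            else None
        )

        history: list[dict[str, float]] = []
        batch = min(tc.batch_size, n)
        state.set_training(True)
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            sums: dict[str, float] = {}
            n_batches = 0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                if len(idx) < 2:
                    continue  # cycle standardisation and batch stats need >= 2 cells

                if disc_opt is not None:
                    # discriminator step on detached latents
                    with_np = state.encode(self.x[idx], self.cov[idx], deterministic=False, rng=rng)
                    d_logits = state.discriminator(Tensor(with_np.z))
                    d_loss = cross_entropy_t(d_logits, self.system_idx[idx])
                    disc_opt.zero_grad()
                    main_opt.zero_grad()
                    d_loss.backward()
                    disc_opt.step()

                parts = self._batch_losses(state, idx, rng, n_mc=tc.n_mc)
                total = (
                    parts["reconstruction"]
                    + cfg.kl_weight * parts["kl"]
                    + cfg.cycle_weight * parts["cycle"]
                    + cfg.adv_weight * parts["adversarial_generator"]
                )
                if not np.isfinite(total.data):
                    comps = {k: float(v.data) for k, v in parts.items()}
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {comps}"
                    )
                main_opt.zero_grad()
                if disc_opt is not None:
                    disc_opt.zero_grad()
                total.backward()
                main_opt.step()  # discriminator grads from this pass are discarded

                n_batches += 1
                for k, v in parts.items():
                    sums[k] = sums.get(k, 0.0) + float(v.data)
                sums["total"] = sums.get("total", 0.0) + float(total.data)
            history.append(
                {"epoch": epoch, **{k: v / max(n_batches, 1) for k, v in sums.items()}}
            )
        state.set_training(False)
        return VAEResults(self, state, pd.DataFrame(history), tc)

    def fit_multiseed(self, seeds=(0, 1, 2), train_config: TrainConfig | None = None, **kw):
        """One full run per seed; returns a list of :class:`VAEResults`."""
        out = []
        for seed in seeds:
            try:
                out.append(self.fit(train_config=train_config, seed=seed, **kw))
            except Exception as err:  # noqa: BLE001 - annotate failing seed
                raise RuntimeError(f"run with seed {seed} failed") from err
        return out


class VAEResults:
    """Fitted-model results: state, loss history and diagnostics."""

    def __init__(
        self,
        model: CrossSystemVAE,
        state: ModelState,
        history: pd.DataFrame,
        train_config: TrainConfig,
    ):
        self.model = model
        self.state = state
        self.history = history
        self.train_config = train_config

    @property
    def final_loss(self) -> float:
        return float(self.history["total"].iloc[-1])

    def get_latent(
        self,
        dataset: ExpressionDataset | None = None,
        standardized: bool = False,
        use_sampled: bool = False,
        seed: int = 0,
    ) -> np.ndarray:
        """Cells x n_latent embedding (posterior means by default)."""
        if dataset is None:
            x, cov = self.model.x, self.model.cov
        else:
            if dataset.gene_ids != self.state.gene_ids:
                raise ValueError("dataset gene set differs from the training gene set")
            cov = self.state.encoding.encode(dataset.system, dataset.sample)
            x = dataset.dense()
        post = self.state.encode(
            x, cov, deterministic=not use_sampled, rng=np.random.default_rng(seed)
        )
        z = post.z
        if standardized:
            z = (z - z.mean(axis=0)) / (z.std(axis=0) + EPS)
        return z

    def active_latent_dims(self, threshold: float = 0.1) -> int:
        """Number of latent dimensions whose posterior mean varies across
        cells (std above ``threshold``); collapses under strong KL weight."""
        mu = self.get_latent()
        return int((mu.std(axis=0) > threshold).sum())

    def prior_component_assignment(self, dataset: ExpressionDataset | None = None) -> np.ndarray:
        """Per-cell index of the mixture component with the highest support
        (weight times component density at the cell's posterior mean)."""
        comp_mu, comp_logvar, logits = self.state.prior_component_params()
        mu = self.get_latent(dataset)
        return mixture_component_assignment(mu, comp_mu, comp_logvar, logits)

    def summary(self) -> str:
        cfg = self.model.config
        n_params = sum(p.data.size for p in self.state.main_parameters())
        lines = [
            "Cross-system conditional VAE results",
            "=" * 44,
            f"cells: {self.model.dataset.n_cells}   genes: {len(self.state.gene_ids)}",
            f"systems: {self.state.encoding.n_systems}   "
            f"samples: {len(self.state.encoding.sample_categories)}",
            f"prior: {cfg.prior} (L={cfg.n_prior_components})"
            if cfg.prior != "standard"
            else "prior: standard normal",
            f"n_latent: {cfg.n_latent}   n_hidden: {cfg.n_hidden}   n_layers: {cfg.n_layers}",
            f"kl_weight: {cfg.kl_weight}   cycle_weight: {cfg.cycle_weight}   "
            f"kappa: {cfg.adv_weight}",
            f"parameters: {n_params}   epochs: {len(self.history)}   "
            f"seed: {self.train_config.seed}",
            "-" * 44,
            f"final loss: {self.final_loss:.4f}",
            f"  reconstruction: {self.history['reconstruction'].iloc[-1]:.4f}",
            f"  kl: {self.history['kl'].iloc[-1]:.4f}",
            f"  cycle: {self.history['cycle'].iloc[-1]:.4f}",
            f"active latent dims (std > 0.1): {self.active_latent_dims()}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.state.save(path)


def _diag_normal_logpdf(x: np.ndarray, mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    var = np.exp(logvar)
    return -0.5 * (((x - mu) ** 2) / var + logvar + np.log(2 * np.pi)).sum(axis=1)


def mixture_component_assignment(
    points: np.ndarray, comp_mu: np.ndarray, comp_logvar: np.ndarray, weight_logits: np.ndarray
) -> np.ndarray:
    """Index of the mixture component with the highest weighted density at
    each point; ties break at the lowest index (argmax convention)."""
    points = np.atleast_2d(np.asarray(points, float))
    logits = np.asarray(weight_logits, float)
    log_w = logits - (np.log(np.exp(logits - logits.max()).sum()) + logits.max())
    support = np.stack(
        [
            log_w[l] + _diag_normal_logpdf(points, comp_mu[l], comp_logvar[l])
            for l in range(comp_mu.shape[0])
        ],
        axis=1,
    )
    return np.argmax(support, axis=1)
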