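"""Variational auto-encoder feature extraction for beta matrices.

The extractor compresses a samples x CpGs beta matrix through a ReLU
encoder into a Gaussian latent posterior N(mu, diag(sigma^2)); a mirrored
decoder with sigmoid output reconstructs betas from latent draws.  The
objective is Bernoulli cross-entropy reconstruction plus a beta_kl-weighted
KL divergence to the standard-normal prior; validation uses the same
objective (with z = mu, deterministically) for early stopping and model
selection, and the returned model is the parameter snapshot from the epoch
with minimum validation loss.

:class:`VAEEmbedder` is the scikit-learn style estimator (fit / transform /
inverse_transform); ``train_vae``, ``encode``, ``decode``, ``sample_latent``
are thin functional wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .arrays import MethylationArray
from .errors import ConfigError, ContractError
from .nn import VAENet, clamp01, run_training

CHECKPOINT_VERSION = "1"


@dataclass
class EncoderTopology:
    """Encoder shape: hidden layer widths (decoder mirrors them) + latent size."""

    hidden_widths: list[int]
    latent_dim: int

    def __post_init__(self):
        if not self.hidden_widths or any(w < 1 for w in self.hidden_widths):
            raise ConfigError(f"hidden_widths must be non-empty positive, got {self.hidden_widths}")
        if self.latent_dim < 1:
            raise ConfigError(f"latent_dim must be >= 1, got {self.latent_dim}")


@dataclass
class TrainConfig:
    """Optimisation settings shared by embedding and prediction training."""

    learning_rate: float = 1e-3
    beta_kl: float = 1.0
    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 32
    seed: int = 0
    scheduler: str = "none"  # none | cosine | step

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigError("learning_rate, batch_size and max_epochs must be positive")
        if self.beta_kl < 0:
            raise ConfigError(f"beta_kl must be >= 0, got {self.beta_kl}")
        if self.scheduler not in ("none", "cosine", "step"):
            raise ConfigError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class LatentStats:
    """Variational posterior parameters per sample: mu and log sigma^2."""

    mu: np.ndarray
    logvar: np.ndarray


def vae_loss(recon, target, latents: LatentStats, beta_kl: float):
    """(total, recon_term, kl_term), all as sums.

    recon_term = sum over cells of the Bernoulli cross-entropy
    -[t log p + (1-t) log(1-p)]; kl_term = sum over samples and latent dims
    of 0.5 (mu^2 + e^logvar - 1 - logvar); total = recon + beta_kl * kl.
    Targets and reconstructions are clamped to [1e-6, 1-1e-6] here only.
    """
    recon = np.asarray(recon, dtype=float)
    target = np.asarray(target, dtype=float)
    if recon.shape != target.shape:
        raise ContractError(f"shape mismatch: recon {recon.shape} vs target {target.shape}")
    p = clamp01(recon)
    t = clamp01(target)
    recon_term = float(-np.sum(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    mu, logvar = latents.mu, latents.logvar
    kl_term = float(0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar))
    return recon_term + beta_kl * kl_term, recon_term, kl_term


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, MethylationArray):
        return data.values
    return np.asarray(data, dtype=float)


class VAEEmbedder(TransformerMixin, BaseEstimator):
    """VAE feature extractor with a scikit-learn estimator surface.

    Parameters mirror :class:`EncoderTopology` and :class:`TrainConfig`.
    After :meth:`fit`, ``transform`` returns deterministic posterior means,
    ``inverse_transform`` decodes latents back to beta space, and
    ``training_log_`` / ``best_epoch_`` expose the per-epoch loss history
    and the snapshotted epoch.
    """

    def __init__(self, hidden_widths=(128, 64), latent_dim=16,
                 learning_rate=1e-3, beta_kl=1.0, max_epochs=50, patience=10,
                 batch_size=32, seed=0, scheduler="none", recon_loss="bce"):
        self.hidden_widths = hidden_widths
        self.latent_dim = latent_dim
        self.learning_rate = learning_rate
        self.beta_kl = beta_kl
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed
        self.scheduler = scheduler
        self.recon_loss = recon_loss

    # -- configuration helpers ------------------------------------------
    @property
    def topology(self) -> EncoderTopology:
        return EncoderTopology(list(self.hidden_widths), self.latent_dim)

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, beta_kl=self.beta_kl,
            max_epochs=self.max_epochs, patience=self.patience,
            batch_size=self.batch_size, seed=self.seed, scheduler=self.scheduler,
        )

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None, X_val=None):
        """Train on X (MethylationArray or matrix); X_val drives early
        stopping and the best-epoch snapshot (defaults to X)."""
        if isinstance(X, MethylationArray) and isinstance(X_val, MethylationArray):
            if X.cpg_ids != X_val.cpg_ids:
                raise ContractError("train/val CpG sets differ")
        if isinstance(X, MethylationArray):
            self.cpg_ids_ = X.cpg_ids
        Xtr = _as_matrix(X)
        Xva = Xtr if X_val is None else _as_matrix(X_val)
        if Xva.shape[1] != Xtr.shape[1]:
            raise ContractError(
                f"train/val CpG counts differ: {Xtr.shape[1]} vs {Xva.shape[1]}"
            )
        config = self._config()
        topo = self.topology
        rng_init = np.random.default_rng(config.seed)
        net = VAENet(Xtr.shape[1], topo.hidden_widths, topo.latent_dim,
                     rng_init, recon_loss=self.recon_loss)

        def train_step(idx, rng):
            batch = Xtr[idx]
            total, _, _, caches = net.loss_terms(batch, rng=rng, beta_kl=config.beta_kl)
            grads = net.backward(batch, caches, config.beta_kl)
            return total / len(idx), grads

        def val_metrics():
            total, recon, kl, _ = net.loss_terms(Xva, rng=None, beta_kl=config.beta_kl)
            n = Xva.shape[0]
            return {"val_loss": total / n, "recon_loss": recon / n, "kl_loss": kl / n}

        log, _, best_epoch = run_training(net, Xtr, train_step, val_metrics, config)
        self.net_ = net
        self.input_dim_ = Xtr.shape[1]
        self.training_log_ = log
        self.best_epoch_ = best_epoch
        return self

    def _check_input(self, X) -> np.ndarray:
        M = _as_matrix(X)
        if M.shape[1] != self.input_dim_:
            raise ContractError(
                f"input has {M.shape[1]} CpGs, model expects {self.input_dim_}"
            )
        return M

    def transform(self, X) -> np.ndarray:
        """Posterior-mean embedding (deterministic; no latent sampling)."""
        mu, _, _ = self.net_.encode(self._check_input(X))
        return mu

    def encode_stats(self, X) -> tuple[np.ndarray, LatentStats]:
        mu, logvar, _ = self.net_.encode(self._check_input(X))
        return mu, LatentStats(mu=mu, logvar=logvar)

    def inverse_transform(self, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != self.net_.latent_dim:
            raise ContractError(
                f"embedding width {Z.shape[-1] if Z.ndim == 2 else Z.shape} "
                f"!= latent_dim {self.net_.latent_dim}"
            )
        p, _, _ = self.net_.decode(Z)
        return p

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Decode n standard-normal latent draws into synthetic beta rows."""
        if n <= 0:
            raise ConfigError(f"n must be positive, got {n}")
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((n, self.net_.latent_dim))
        return self.inverse_transform(Z)

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """Single-file HDF5 checkpoint: topology, weights, cpg ids, config, log."""
        with h5py.File(path, "w") as f:
            f.attrs["checkpoint_version"] = CHECKPOINT_VERSION
            f.attrs["kind"] = "vae"
            f.attrs["hidden_widths"] = list(self.hidden_widths)
            f.attrs["latent_dim"] = self.latent_dim
            f.attrs["input_dim"] = self.input_dim_
            f.attrs["recon_loss"] = self.recon_loss
            f.attrs["best_epoch"] = self.best_epoch_
            for k in ("learning_rate", "beta_kl", "max_epochs", "patience",
                      "batch_size", "seed"):
                f.attrs[k] = getattr(self, k)
            f.attrs["scheduler"] = self.scheduler
            if hasattr(self, "cpg_ids_"):
                f.create_dataset("cpg_ids", data=np.array(self.cpg_ids_, dtype=object),
                                 dtype=h5py.string_dtype())
            g = f.create_group("weights")
            for i, p in enumerate(self.net_.parameters()):
                g.create_dataset(str(i), data=p)
            lg = f.create_group("log")
            if self.training_log_:
                for key in self.training_log_[0]:
                    lg.create_dataset(key, data=[e[key] for e in self.training_log_])
        return path

    @classmethod
    def load(cls, path) -> "VAEEmbedder":
        with h5py.File(path, "r") as f:
            est = cls(
                hidden_widths=[int(w) for w in f.attrs["hidden_widths"]],
                latent_dim=int(f.attrs["latent_dim"]),
                learning_rate=float(f.attrs["learning_rate"]),
                beta_kl=float(f.attrs["beta_kl"]),
                max_epochs=int(f.attrs["max_epochs"]),
                patience=int(f.attrs["patience"]),
                batch_size=int(f.attrs["batch_size"]),
                seed=int(f.attrs["seed"]),
                scheduler=str(f.attrs["scheduler"]),
                recon_loss=str(f.attrs["recon_loss"]),
            )
            input_dim = int(f.attrs["input_dim"])
            net = VAENet(input_dim, list(est.hidden_widths), est.latent_dim,
                         np.random.default_rng(0), recon_loss=est.recon_loss)
            state = [np.asarray(f["weights"][str(i)]) for i in range(len(net.parameters()))]
            net.set_state(state)
            est.net_ = net
            est.input_dim_ = input_dim
            est.best_epoch_ = int(f.attrs["best_epoch"])
            if "cpg_ids" in f:
                est.cpg_ids_ = [s.decode() if isinstance(s, bytes) else str(s)
                                for s in f["cpg_ids"]]
            lg = f["log"]
            keys = list(lg.keys())
            if keys:
                n = len(lg[keys[0]])
                est.training_log_ = [
                    {k: (int(lg[k][i]) if k == "epoch" else float(lg[k][i])) for k in keys}
                    for i in range(n)
                ]
            else:
                est.training_log_ = []
        return est


# Fitted VAEEmbedder doubles as the trained-model container.
VAEModel = VAEEmbedder


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train_vae(train: MethylationArray, val: MethylationArray,
              topology: EncoderTopology, config: TrainConfig,
              recon_loss: str = "bce") -> VAEEmbedder:
    """Train a VAE on train, snapshotting at minimum validation loss."""
    est = VAEEmbedder(
        hidden_widths=list(topology.hidden_widths), latent_dim=topology.latent_dim,
        learning_rate=config.learning_rate, beta_kl=config.beta_kl,
        max_epochs=config.max_epochs, patience=config.patience,
        batch_size=config.batch_size, seed=config.seed,
        scheduler=config.scheduler, recon_loss=recon_loss,
    )
    return est.fit(train, X_val=val)


def encode(model: VAEEmbedder, arr) -> tuple[np.ndarray, LatentStats]:
    """Posterior-mean embeddings plus full posterior stats."""
    return model.encode_stats(arr)


def decode(model: VAEEmbedder, embedding) -> np.ndarray:
    """Decode latent vectors to beta values in (0, 1)."""
    return model.inverse_transform(embedding)


def sample_latent(model: VAEEmbedder, n: int, seed: int = 0) -> MethylationArray:
    """Generate n synthetic samples from standard-normal latent draws."""
    beta = model.sample(n, seed=seed)
    cpgs = getattr(model, "cpg_ids_", [f"cg{i}" for i in range(model.input_dim_)])
    ids = [f"gen{i}" for i in range(n)]
    return MethylationArray(
        pd.DataFrame(beta, index=ids, columns=cpgs),
        pd.DataFrame(index=ids),
        validate=False,
    )
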