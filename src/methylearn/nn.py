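"""Minimal feed-forward network engine (numpy, manual backprop, Adam).

Implements exactly what the modelling stack needs and nothing more:
fully-connected ReLU stacks, a Gaussian-latent VAE head, softmax/linear
output heads, sum/mean Bernoulli and squared-error losses, input
gradients (needed by the expected-gradients attribution estimator), and
a shared early-stopping training loop with best-epoch snapshotting.
All randomness flows from a single ``numpy.random.Generator`` so runs
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingDivergedError

CLAMP = 1e-6  # numerical guard for Bernoulli-style losses


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def clamp01(x):
    return np.clip(x, CLAMP, 1.0 - CLAMP)


def he_init(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


def xavier_init(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(1.0 / fan_in)


# ---------------------------------------------------------------------------
# ReLU stacks
# ---------------------------------------------------------------------------

def stack_init(rng, dims):
    """Weights/biases for a ReLU stack with layer sizes ``dims``."""
    Ws = [he_init(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
    bs = [np.zeros(b) for b in dims[1:]]
    return Ws, bs


def stack_forward(Ws, bs, X):
    acts, pres = [X], []
    h = X
    for W, b in zip(Ws, bs):
        pre = h @ W + b
        h = np.maximum(pre, 0.0)
        pres.append(pre)
        acts.append(h)
    return h, (acts, pres)


def stack_backward(Ws, caches, dh):
    """Returns (d_input, grads_W, grads_b)."""
    acts, pres = caches
    gW, gb = [None] * len(Ws), [None] * len(Ws)
    for i in reversed(range(len(Ws))):
        dpre = dh * (pres[i] > 0)
        gW[i] = acts[i].T @ dpre
        gb[i] = dpre.sum(axis=0)
        dh = dpre @ Ws[i].T
    return dh, gW, gb


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def scheduled_lr(base_lr, scheduler, epoch, max_epochs):
    if scheduler == "cosine":
        return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(1, max_epochs)))
    if scheduler == "step":
        return base_lr * 0.5 ** (epoch // 10)
    return base_lr


# ---------------------------------------------------------------------------
# VAE network
# ---------------------------------------------------------------------------

class VAENet:
    """Encoder -> (mu, logvar) -> reparameterised z -> mirrored decoder.

    Hidden activations are ReLU; the output layer is a sigmoid so decoded
    values live strictly in (0, 1).  The reconstruction loss treats beta
    values as soft Bernoulli targets (cross-entropy on continuous targets);
    ``recon_loss="mse"`` switches to squared error.
    """

    def __init__(self, input_dim, hidden_widths, latent_dim, rng, recon_loss="bce"):
        self.input_dim = int(input_dim)
        self.hidden_widths = list(hidden_widths)
        self.latent_dim = int(latent_dim)
        self.recon_loss = recon_loss
        enc_dims = [self.input_dim] + self.hidden_widths
        dec_dims = [self.latent_dim] + self.hidden_widths[::-1]
        self.enc_Ws, self.enc_bs = stack_init(rng, enc_dims)
        h = enc_dims[-1]
        self.W_mu = xavier_init(rng, h, self.latent_dim)
        self.b_mu = np.zeros(self.latent_dim)
        self.W_lv = 0.1 * xavier_init(rng, h, self.latent_dim)
        self.b_lv = np.zeros(self.latent_dim)
        self.dec_Ws, self.dec_bs = stack_init(rng, dec_dims)
        self.W_out = xavier_init(rng, dec_dims[-1], self.input_dim)
        self.b_out = np.zeros(self.input_dim)

    # -- parameter plumbing ---------------------------------------------
    def parameters(self):
        return (
            self.enc_Ws + self.enc_bs
            + [self.W_mu, self.b_mu, self.W_lv, self.b_lv]
            + self.dec_Ws + self.dec_bs + [self.W_out, self.b_out]
        )

    def get_state(self):
        return [p.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward passes --------------------------------------------------
    def encode(self, X):
        h, cache = stack_forward(self.enc_Ws, self.enc_bs, X)
        mu = h @ self.W_mu + self.b_mu
        logvar = h @ self.W_lv + self.b_lv
        return mu, logvar, (h, cache)

    def decode(self, Z):
        h, cache = stack_forward(self.dec_Ws, self.dec_bs, Z)
        pre = h @ self.W_out + self.b_out
        return sigmoid(pre), pre, (h, cache)

    def loss_terms(self, X, rng=None, beta_kl=1.0):
        """(total, recon, kl) as sums, plus caches for backward.

        With ``rng`` given the latent is reparameterised (training);
        without, z = mu (deterministic validation/inference).
        """
        mu, logvar, enc_cache = self.encode(X)
        if rng is not None:
            eps = rng.standard_normal(mu.shape)
            z = mu + eps * np.exp(0.5 * logvar)
        else:
            eps = None
            z = mu
        p, pre, dec_cache = self.decode(z)
        t = clamp01(X)
        if self.recon_loss == "bce":
            # numerically stable BCE-with-logits, summed over all cells
            recon = float(np.sum(np.logaddexp(0.0, pre) - t * pre))
        else:
            recon = float(np.sum((p - t) ** 2))
        kl = float(0.5 * np.sum(mu ** 2 + np.exp(logvar) - 1.0 - logvar))
        total = recon + beta_kl * kl
        caches = (mu, logvar, enc_cache, eps, z, p, pre, dec_cache, t)
        return total, recon, kl, caches

    def backward(self, X, caches, beta_kl):
        """Gradients of (recon + beta_kl * kl) / n_batch w.r.t. parameters."""
        mu, logvar, (h_enc, enc_cache), eps, z, p, pre, (h_dec, dec_cache), t = caches
        n = X.shape[0]
        if self.recon_loss == "bce":
            dpre = (p - t) / n
        else:
            dpre = 2.0 * (p - t) * p * (1.0 - p) / n
        gW_out = h_dec.T @ dpre
        gb_out = dpre.sum(axis=0)
        dh_dec = dpre @ self.W_out.T
        dz, gdec_W, gdec_b = stack_backward(self.dec_Ws, dec_cache, dh_dec)

        dmu = dz.copy()
        dlogvar = np.zeros_like(logvar)
        if eps is not None:
            dlogvar += dz * eps * 0.5 * np.exp(0.5 * logvar)
        dmu += beta_kl * mu / n
        dlogvar += beta_kl * 0.5 * (np.exp(logvar) - 1.0) / n

        gW_mu = h_enc.T @ dmu
        gb_mu = dmu.sum(axis=0)
        gW_lv = h_enc.T @ dlogvar
        gb_lv = dlogvar.sum(axis=0)
        dh_enc = dmu @ self.W_mu.T + dlogvar @ self.W_lv.T
        _, genc_W, genc_b = stack_backward(self.enc_Ws, enc_cache, dh_enc)
        return (
            genc_W + genc_b
            + [gW_mu, gb_mu, gW_lv, gb_lv]
            + gdec_W + gdec_b + [gW_out, gb_out]
        )


# ---------------------------------------------------------------------------
# Fine-tune network (encoder + prediction head)
# ---------------------------------------------------------------------------

class FineTuneNet:
    """Encoder stack + mu projection, followed by a ReLU prediction head.

    The encoder half can be initialised from a trained :class:`VAENet`
    (weights copied, never shared) or randomly (the no-pretraining MLP
    baseline).  Output layer weights start small so a fresh classifier
    predicts near-uniform probabilities (initial cross-entropy ~= ln k).

    ``out_kind``: "softmax" (classification / simplex-constrained
    proportions) or "linear" (regression / unconstrained multi-output).
    """

    def __init__(self, input_dim, encoder_widths, latent_dim, head_widths,
                 n_outputs, out_kind, rng):
        self.input_dim = int(input_dim)
        self.encoder_widths = list(encoder_widths)
        self.latent_dim = int(latent_dim)
        self.head_widths = list(head_widths)
        self.n_outputs = int(n_outputs)
        self.out_kind = out_kind
        enc_dims = [self.input_dim] + self.encoder_widths
        self.enc_Ws, self.enc_bs = stack_init(rng, enc_dims)
        self.W_mu = xavier_init(rng, enc_dims[-1], self.latent_dim)
        self.b_mu = np.zeros(self.latent_dim)
        head_dims = [self.latent_dim] + self.head_widths
        self.head_Ws, self.head_bs = stack_init(rng, head_dims)
        self.W_out = 0.01 * rng.standard_normal((head_dims[-1], self.n_outputs))
        self.b_out = np.zeros(self.n_outputs)

    @classmethod
    def from_vae(cls, vae: VAENet, head_widths, n_outputs, out_kind, rng):
        net = cls(vae.input_dim, vae.hidden_widths, vae.latent_dim,
                  head_widths, n_outputs, out_kind, rng)
        net.enc_Ws = [W.copy() for W in vae.enc_Ws]
        net.enc_bs = [b.copy() for b in vae.enc_bs]
        net.W_mu = vae.W_mu.copy()
        net.b_mu = vae.b_mu.copy()
        return net

    def parameters(self):
        return (
            self.enc_Ws + self.enc_bs + [self.W_mu, self.b_mu]
            + self.head_Ws + self.head_bs + [self.W_out, self.b_out]
        )

    def get_state(self):
        return [p.copy() for p in self.parameters()]

    def set_state(self, state):
        for p, s in zip(self.parameters(), state):
            p[...] = s

    # -- forward ---------------------------------------------------------
    def embed(self, X):
        h, _ = stack_forward(self.enc_Ws, self.enc_bs, X)
        return h @ self.W_mu + self.b_mu

    def forward(self, X):
        h_enc, enc_cache = stack_forward(self.enc_Ws, self.enc_bs, X)
        z = h_enc @ self.W_mu + self.b_mu
        h_head, head_cache = stack_forward(self.head_Ws, self.head_bs, z)
        out = h_head @ self.W_out + self.b_out
        caches = (h_enc, enc_cache, z, h_head, head_cache)
        return out, caches

    def loss(self, X, Y):
        """Mean loss over the batch; Y is one-hot / proportion / standardized
        target matrix depending on the task."""
        out, caches = self.forward(X)
        n = X.shape[0]
        if self.out_kind == "softmax":
            p = softmax(out)
            if getattr(self, "loss_kind", "ce") == "mse":
                value = float(np.mean((p - Y) ** 2))
            else:
                logp = out - out.max(axis=1, keepdims=True)
                logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
                value = float(-np.sum(Y * logp) / n)
            return value, (out, p, caches)
        value = float(np.mean((out - Y) ** 2))
        return value, (out, None, caches)

    def backward(self, X, Y, fwd):
        out, p, (h_enc, enc_cache, z, h_head, head_cache) = fwd
        n = X.shape[0]
        if self.out_kind == "softmax":
            if getattr(self, "loss_kind", "ce") == "mse":
                dp = 2.0 * (p - Y) / (n * self.n_outputs)
                dout = p * (dp - (dp * p).sum(axis=1, keepdims=True))
            else:
                dout = (p - Y) / n
        else:
            dout = 2.0 * (out - Y) / (n * self.n_outputs)
        gW_out = h_head.T @ dout
        gb_out = dout.sum(axis=0)
        dh_head = dout @ self.W_out.T
        dz, ghead_W, ghead_b = stack_backward(self.head_Ws, head_cache, dh_head)
        gW_mu = h_enc.T @ dz
        gb_mu = dz.sum(axis=0)
        dh_enc = dz @ self.W_mu.T
        _, genc_W, genc_b = stack_backward(self.enc_Ws, enc_cache, dh_enc)
        return (
            genc_W + genc_b + [gW_mu, gb_mu]
            + ghead_W + ghead_b + [gW_out, gb_out]
        )

    def input_gradients(self, X, output_index):
        """d raw-output[i, output_index[i]] / d X[i, :] for each sample i.

        Used by the expected-gradients attribution estimator; gradients are
        of the pre-softmax logit for classifiers.
        """
        out, (h_enc, enc_cache, z, h_head, head_cache) = self.forward(X)
        dout = np.zeros_like(out)
        idx = np.broadcast_to(np.asarray(output_index), (X.shape[0],))
        dout[np.arange(X.shape[0]), idx] = 1.0
        dh_head = dout @ self.W_out.T
        dz, _, _ = stack_backward(self.head_Ws, head_cache, dh_head)
        dh_enc = dz @ self.W_mu.T
        dX, _, _ = stack_backward(self.enc_Ws, enc_cache, dh_enc)
        return dX


# ---------------------------------------------------------------------------
# Shared training loop
# ---------------------------------------------------------------------------

def run_training(net, X_train, train_loss_grad, val_loss, config):
    """Minibatch Adam loop with early stopping and best-epoch snapshot.

    ``train_loss_grad(batch_indices, rng)`` returns (loss, grads);
    ``val_loss()`` returns the scalar validation objective.  Returns
    (log, best_state, best_epoch); ``log`` is a list of per-epoch dicts
    and the snapshot is the epoch with minimum validation loss.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    n = X_train.shape[0]
    bs = min(config.batch_size, n)
    log = []
    best_val = np.inf
    best_state = net.get_state()
    best_epoch = -1
    no_improve = 0
    for epoch in range(config.max_epochs):
        lr = scheduled_lr(config.learning_rate, config.scheduler, epoch, config.max_epochs)
        perm = rng.permutation(n)
        epoch_train = 0.0
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            loss, grads = train_loss_grad(idx, rng)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.step(net.parameters(), grads, lr=lr)
            epoch_train += loss * len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_train / n}
        entry.update(val_loss())
        log.append(entry)
        vl = entry["val_loss"]
        if not np.isfinite(vl):
            raise TrainingDivergedError(epoch)
        if vl < best_val:
            best_val = vl
            best_state = net.get_state()
            best_epoch = epoch
            no_improve = 0
        else:
            no_improve += 1
            if no_improve > config.patience:
                break
    net.set_state(best_state)
    return log, best_state, best_epoch
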