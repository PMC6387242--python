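"""Gaussian variational autoencoder classifier for CNN features.

Architecture (defaults): input 900 -> encoder hidden 600 -> 300 -> a
100-dimensional diagonal-Gaussian latent (mean mu(x) and variance theta(x))
-> decoder hidden 300 -> 600 -> a diagonal-Gaussian reconstruction of the
input with learned per-dimension variance -> plus a two-way softmax head on
the latent mean.

Training follows the stacked-autoencoder recipe: each of the three
(input, latent) stages is first trained greedily as a one-latent-layer VAE
by stochastic gradient *ascent* on the single-sample reparameterized ELBO

    L(q) = E_eps[ log p(x | z = mu + sqrt(theta) * eps) ] - KL(q(z|x) || N(0, I)),

the deterministic hidden representation softplus(mu(.)) of each stage
feeding the next; afterwards the encoder and the classifier head are
fine-tuned with supervised cross-entropy using mu(x) deterministically (no
sampling at fine-tune or prediction time).

The closed-form KL between the diagonal posterior and the standard-normal
prior is 0.5 * sum(mu^2 + theta - 1 - ln theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Dense, minibatches, softmax, softmax_xent, softplus, softplus_grad
from .cnn import TrainingHistory

__all__ = [
    "VaeConfig",
    "GaussianVae",
    "VaeModel",
    "ElboReport",
    "init_vae",
    "encode",
    "reparameterize",
    "decode",
    "elbo",
    "pretrain_layerwise",
    "finetune",
    "predict",
]

_THETA_FLOOR = 1e-6
_LOGVAR_FLOOR = float(np.log(1e-6))


@dataclass(frozen=True)
class VaeConfig:
    input_dim: int = 900
    hidden_dims: tuple[int, ...] = (600, 300, 100, 300, 600)
    output_classes: int = 2
    pretrain_epochs: int = 200
    pretrain_batch: int = 20
    finetune_epochs: int = 200
    finetune_batch: int = 40
    learning_rate: float = 0.05
    seed: int = 0
    init_scale: float = 0.01
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if len(self.hidden_dims) != 5:
            raise ValueError(
                f"hidden_dims must list exactly 5 sizes, got {self.hidden_dims}"
            )
        h = self.hidden_dims
        if h[0] != h[4] or h[1] != h[3]:
            raise ValueError(
                f"hidden_dims {h} must be symmetric around the middle latent"
            )
        if min(h) < 1 or self.input_dim < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def latent_dim(self) -> int:
        return self.hidden_dims[2]


@dataclass(frozen=True)
class ElboReport:
    elbo: float
    reconstruction: float
    kl: float


class GaussianVae:
    """Diagonal-Gaussian VAE with arbitrary encoder/decoder hidden stacks.

    With empty hidden stacks this is a one-latent-layer (linear) VAE, the
    building block used during greedy layer-wise pretraining; the full model
    uses two softplus hidden layers on each side.
    """

    def __init__(
        self,
        enc_hidden: list[Dense],
        enc_mu: Dense,
        enc_s: Dense,
        dec_hidden: list[Dense],
        dec_mu: Dense,
        dec_logvar: np.ndarray,
    ) -> None:
        self.enc_hidden = enc_hidden
        self.enc_mu = enc_mu
        self.enc_s = enc_s
        self.dec_hidden = dec_hidden
        self.dec_mu = dec_mu
        self.dec_logvar = dec_logvar

    @property
    def input_dim(self) -> int:
        first = self.enc_hidden[0] if self.enc_hidden else self.enc_mu
        return first.n_in

    @property
    def latent_dim(self) -> int:
        return self.enc_mu.n_out

    # -- forward passes -------------------------------------------------
    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, theta); theta > 0 by construction."""
        x = np.atleast_2d(np.asarray(x))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"feature length {x.shape[1]} != input_dim {self.input_dim}"
            )
        h = x
        for layer in self.enc_hidden:
            h = softplus(layer.forward(h))
        mu = self.enc_mu.forward(h)
        theta = softplus(self.enc_s.forward(h)) + _THETA_FLOOR
        return mu, theta

    def decode(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Decoder Gaussian parameters (mean, variance) of p(x|z)."""
        h = np.atleast_2d(np.asarray(z))
        for layer in self.dec_hidden:
            h = softplus(layer.forward(h))
        x_mu = self.dec_mu.forward(h)
        x_var = np.exp(self.dec_logvar)
        return x_mu, x_var

    def params(self) -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for i, layer in enumerate(self.enc_hidden):
            out += [(f"enc{i}.W", layer.W), (f"enc{i}.b", layer.b)]
        out += [("enc_mu.W", self.enc_mu.W), ("enc_mu.b", self.enc_mu.b)]
        out += [("enc_s.W", self.enc_s.W), ("enc_s.b", self.enc_s.b)]
        for i, layer in enumerate(self.dec_hidden):
            out += [(f"dec{i}.W", layer.W), (f"dec{i}.b", layer.b)]
        out += [("dec_mu.W", self.dec_mu.W), ("dec_mu.b", self.dec_mu.b)]
        out.append(("dec_logvar", self.dec_logvar))
        return out


class VaeModel:
    """GaussianVae core plus the two-way classifier head on mu(x)."""

    def __init__(self, core: GaussianVae, head: Dense, config: VaeConfig) -> None:
        self.core = core
        self.head = head
        self.config = config


def init_vae(cfg: VaeConfig) -> VaeModel:
    """Seeded small-Gaussian initialization of all weight matrices."""
    rng = np.random.default_rng(cfg.seed)
    d = cfg.input_dim
    h1, h2, latent = cfg.hidden_dims[0], cfg.hidden_dims[1], cfg.latent_dim

    def dense(n_in: int, n_out: int) -> Dense:
        return Dense(n_in, n_out, rng=rng, scale=cfg.init_scale, dtype=cfg.dtype)

    core = GaussianVae(
        enc_hidden=[dense(d, h1), dense(h1, h2)],
        enc_mu=dense(h2, latent),
        enc_s=dense(h2, latent),
        dec_hidden=[dense(latent, h2), dense(h2, h1)],
        dec_mu=dense(h1, d),
        dec_logvar=np.zeros(d, dtype=cfg.dtype),
    )
    head = dense(latent, cfg.output_classes)
    return VaeModel(core, head, cfg)


def encode(m: VaeModel | GaussianVae, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    core = m.core if isinstance(m, VaeModel) else m
    return core.encode(x)


def decode(m: VaeModel | GaussianVae, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    core = m.core if isinstance(m, VaeModel) else m
    return core.decode(z)


def reparameterize(mu: np.ndarray, theta: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + sqrt(theta) * eps, elementwise."""
    mu, theta, eps = np.asarray(mu), np.asarray(theta), np.asarray(eps)
    if mu.shape != theta.shape or mu.shape != eps.shape:
        raise ValueError("mu, theta and eps must share a shape")
    if np.any(theta <= 0):
        raise ValueError("theta must be strictly positive")
    return mu + np.sqrt(theta) * eps


def gaussian_kl(mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """KL(N(mu, diag theta) || N(0, I)) per sample, closed form."""
    return 0.5 * np.sum(mu**2 + theta - 1.0 - np.log(theta), axis=-1)


def _gaussian_loglik(x: np.ndarray, x_mu: np.ndarray, x_var: np.ndarray) -> np.ndarray:
    return -0.5 * np.sum(
        np.log(2.0 * np.pi * x_var) + (x - x_mu) ** 2 / x_var, axis=-1
    )


def elbo(m: VaeModel | GaussianVae, x: np.ndarray, eps: np.ndarray) -> ElboReport:
    """Single-sample reparameterized ELBO estimate, averaged over the batch."""
    core = m.core if isinstance(m, VaeModel) else m
    x = np.atleast_2d(np.asarray(x))
    mu, theta = core.encode(x)
    eps = np.asarray(eps).reshape(mu.shape)
    z = reparameterize(mu, theta, eps)
    x_mu, x_var = core.decode(z)
    recon = float(np.mean(_gaussian_loglik(x, x_mu, x_var)))
    kl = float(np.mean(gaussian_kl(mu, theta)))
    if not np.isfinite(recon) or not np.isfinite(kl):
        raise FloatingPointError("non-finite ELBO term; check input scaling")
    return ElboReport(elbo=recon - kl, reconstruction=recon, kl=kl)


def elbo_and_grads(
    core: GaussianVae, x: np.ndarray, eps: np.ndarray
) -> tuple[ElboReport, dict[str, np.ndarray]]:
    """Mean single-sample ELBO and its analytic gradients w.r.t. all params."""
    x = np.atleast_2d(np.asarray(x))
    n = x.shape[0]

    # ---- forward with caches
    h = x
    enc_caches = []  # (input, pre-activation) per hidden layer
    for layer in core.enc_hidden:
        pre = layer.forward(h)
        enc_caches.append((h, pre))
        h = softplus(pre)
    h_enc = h
    mu = core.enc_mu.forward(h_enc)
    s_pre = core.enc_s.forward(h_enc)
    theta = softplus(s_pre) + _THETA_FLOOR
    eps = np.asarray(eps).reshape(mu.shape)
    sqrt_theta = np.sqrt(theta)
    z = mu + sqrt_theta * eps

    hd = z
    dec_caches = []
    for layer in core.dec_hidden:
        pre = layer.forward(hd)
        dec_caches.append((hd, pre))
        hd = softplus(pre)
    x_mu = core.dec_mu.forward(hd)
    x_var = np.exp(core.dec_logvar)

    recon = float(np.mean(_gaussian_loglik(x, x_mu, x_var)))
    kl = float(np.mean(gaussian_kl(mu, theta)))
    report = ElboReport(elbo=recon - kl, reconstruction=recon, kl=kl)

    grads: dict[str, np.ndarray] = {}

    # ---- backward (gradient of the mean ELBO; 1/n carried from the top)
    resid = (x - x_mu) / x_var
    g_xmu = resid / n
    grads["dec_logvar"] = np.mean(-0.5 * (1.0 - resid * (x - x_mu)), axis=0)
    dW, db, g_hd = core.dec_mu.backward(hd, g_xmu)
    grads["dec_mu.W"], grads["dec_mu.b"] = dW, db
    for i in range(len(core.dec_hidden) - 1, -1, -1):
        inp, pre = dec_caches[i]
        g_pre = g_hd * softplus_grad(pre)
        dW, db, g_hd = core.dec_hidden[i].backward(inp, g_pre)
        grads[f"dec{i}.W"], grads[f"dec{i}.b"] = dW, db
    g_z = g_hd

    g_mu = g_z - mu / n
    g_theta = g_z * eps / (2.0 * sqrt_theta) - 0.5 * (1.0 - 1.0 / theta) / n
    g_spre = g_theta * softplus_grad(s_pre)
    dW, db, g_h1 = core.enc_mu.backward(h_enc, g_mu)
    grads["enc_mu.W"], grads["enc_mu.b"] = dW, db
    dW, db, g_h2 = core.enc_s.backward(h_enc, g_spre)
    grads["enc_s.W"], grads["enc_s.b"] = dW, db
    g_h = g_h1 + g_h2
    for i in range(len(core.enc_hidden) - 1, -1, -1):
        inp, pre = enc_caches[i]
        g_pre = g_h * softplus_grad(pre)
        dW, db, g_h = core.enc_hidden[i].backward(inp, g_pre)
        grads[f"enc{i}.W"], grads[f"enc{i}.b"] = dW, db
    return report, grads


#: global cap on the ELBO gradient norm: near the reconstruction-variance
#: floor the decoder gradients scale like residual/variance, and a raw SGD
#: step would overshoot by orders of magnitude
_MAX_GRAD_NORM = 50.0
_LOGVAR_CEIL = 10.0


def _sgd_ascent(core: GaussianVae, grads: dict[str, np.ndarray], lr: float) -> None:
    sq = sum(float(np.vdot(g, g)) for g in grads.values())
    norm = float(np.sqrt(sq))
    scale = _MAX_GRAD_NORM / norm if norm > _MAX_GRAD_NORM else 1.0
    for name, param in core.params():
        g = grads[name]
        if g.dtype != param.dtype:
            g = g.astype(param.dtype)
        param += lr * scale * g
    np.clip(core.dec_logvar, _LOGVAR_FLOOR, _LOGVAR_CEIL, out=core.dec_logvar)


def train_stage(
    core: GaussianVae,
    data: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
) -> list[float]:
    """SGD ascent on the reparameterized ELBO.

    Returns the per-epoch ELBO (mean of the mini-batch estimates seen
    during the epoch, so no extra full-data passes are spent on logging).
    """
    history = []
    for _ in range(epochs):
        epoch_elbos = []
        for idx in minibatches(len(data), batch_size, rng):
            xb = data[idx]
            eps = rng.standard_normal((len(xb), core.latent_dim)).astype(xb.dtype)
            report, grads = elbo_and_grads(core, xb, eps)
            _sgd_ascent(core, grads, lr)
            epoch_elbos.append(report.elbo)
        history.append(float(np.mean(epoch_elbos)))
    return history


def pretrain_layerwise(
    m: VaeModel, features: np.ndarray, cfg: VaeConfig | None = None
) -> VaeModel:
    """Greedy stage-wise unsupervised pretraining of the full model.

    Stage k trains a one-latent-layer VAE whose mean map and decoder mean
    map are *shared* with the corresponding full-model layers (so training
    updates the model in place; zero epochs leaves it at initialization).
    The deterministic hidden output softplus(mu_k(.)) of each stage is the
    training input of the next.  Stage-local scratch parameters (the
    variance maps of the outer stages, the inner reconstruction variances)
    are discarded.
    """
    cfg = cfg or m.config
    features = np.atleast_2d(np.asarray(features, dtype=m.core.enc_mu.W.dtype))
    if features.shape[0] == 0:
        raise ValueError("empty feature set")
    if features.shape[1] != m.core.input_dim:
        raise ValueError(
            f"feature length {features.shape[1]} != input_dim {m.core.input_dim}"
        )
    core = m.core
    dtype = cfg.dtype
    stages = [
        # (mu map, decoder mean map, shared decoder logvar or None)
        (core.enc_hidden[0], core.dec_mu, core.dec_logvar),
        (core.enc_hidden[1], core.dec_hidden[1], None),
        (core.enc_mu, core.dec_hidden[0], None),
    ]
    data = features
    for k, (enc_mu, dec_mu, logvar) in enumerate(stages):
        rng = np.random.default_rng(cfg.seed + 101 * (k + 1))
        enc_s = (
            core.enc_s
            if enc_mu is core.enc_mu
            else Dense(enc_mu.n_in, enc_mu.n_out, rng=rng, scale=cfg.init_scale, dtype=dtype)
        )
        stage = GaussianVae(
            enc_hidden=[],
            enc_mu=enc_mu,
            enc_s=enc_s,
            dec_hidden=[],
            dec_mu=dec_mu,
            dec_logvar=logvar
            if logvar is not None
            else np.zeros(dec_mu.n_out, dtype=dtype),
        )
        train_stage(
            stage, data, cfg.pretrain_epochs, cfg.pretrain_batch, cfg.learning_rate, rng
        )
        if k < 2:
            data = softplus(enc_mu.forward(data))
    return m


def _classifier_forward(m: VaeModel, x: np.ndarray):
    """Deterministic classification path: hidden stack -> mu -> head."""
    core = m.core
    h = x
    caches = []
    for layer in core.enc_hidden:
        pre = layer.forward(h)
        caches.append((h, pre))
        h = softplus(pre)
    mu = core.enc_mu.forward(h)
    logits = m.head.forward(mu)
    return caches, h, mu, logits


def finetune(
    m: VaeModel,
    features: np.ndarray,
    labels: np.ndarray,
    cfg: VaeConfig | None = None,
) -> tuple[VaeModel, TrainingHistory]:
    """Supervised cross-entropy SGD through the encoder and the head.

    Uses mu(x) deterministically (no sampling); the decoder and the
    posterior-variance map are left untouched, so theta stays positive.
    """
    cfg = cfg or m.config
    x = np.atleast_2d(np.asarray(features, dtype=m.core.enc_mu.W.dtype))
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("fine-tuning requires both classes present")
    rng = np.random.default_rng(cfg.seed + 977)
    core = m.core
    history = TrainingHistory()
    for _ in range(cfg.finetune_epochs):
        batch_loss, batch_acc = [], []
        for idx in minibatches(len(x), cfg.finetune_batch, rng):
            caches, h_enc, mu, logits = _classifier_forward(m, x[idx])
            loss, _, dlogits = softmax_xent(logits, y[idx])
            dWh, dbh, g_mu = m.head.backward(mu, dlogits)
            dWm, dbm, g_h = core.enc_mu.backward(h_enc, g_mu)
            layer_grads = []
            for i in range(len(core.enc_hidden) - 1, -1, -1):
                inp, pre = caches[i]
                g_pre = g_h * softplus_grad(pre)
                dW, db, g_h = core.enc_hidden[i].backward(inp, g_pre)
                layer_grads.append((core.enc_hidden[i], dW, db))
            lr = cfg.learning_rate
            m.head.sgd_step(dWh, dbh, lr)
            core.enc_mu.sgd_step(dWm, dbm, lr)
            for layer, dW, db in layer_grads:
                layer.sgd_step(dW, db, lr)
            batch_loss.append(loss)
            batch_acc.append(float(np.mean(np.argmax(logits, axis=1) == y[idx])))
        history.loss.append(float(np.mean(batch_loss)))
        history.accuracy.append(float(np.mean(batch_acc)))
    return m, history


def predict(m: VaeModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities); argmax with ties resolving to class 0."""
    x = np.atleast_2d(np.asarray(features, dtype=m.core.enc_mu.W.dtype))
    if x.shape[1] != m.core.input_dim:
        raise ValueError(
            f"feature length {x.shape[1]} != input_dim {m.core.input_dim}"
        )
    _, _, _, logits = _classifier_forward(m, x)
    probs = softmax(logits)
    return np.argmax(probs, axis=1), probs
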