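"""Adversarial training of the split-latent obfuscation model.

Each minibatch alternates two updates:

1. *Discriminator step* — the privacy discriminator P is trained to predict
   the sensitive attribute s from the (frozen) encoder's nonsensitive codes
   z_ns by minimising cross-entropy.  In addition, at the start of every
   epoch P is *consolidated*: re-fitted for several hundred minibatch steps
   on freshly encoded latents of the whole training set, so the encoder
   always plays against a near-best-response adversary rather than a stale
   one (a single SGD-tracked adversary lets the game cycle without removing
   information).
2. *Autoencoder step* — encoder E, decoder D and an auxiliary head A on z_s
   are updated with P frozen.  The gradient combines

   * reconstruction:  MSE(x, D(E(x))),
   * routing:         lambda_s * CE(A(z_s), s)  — pulls sensitive
     information into the sensitive subspace,
   * privacy pressure on z_ns, scaled by gamma * privacy_pressure:
       - a non-saturating *confusion* term pushing P's prediction toward
         the uniform distribution (the naive "maximise CE(P, s)" gradient
         vanishes exactly when P is confidently correct, i.e. when leakage
         is worst), and
       - class-conditional batch-mean matching of z_ns, which directly
         aligns the first moments of the two sensitive groups.

Both optimisers decay their learning rate each epoch (``lr_decay``); the
cooling schedule freezes the adversarial game near its equilibrium instead
of letting it oscillate.  Loss functional forms, the Adam optimiser
(lr 1e-3), batch size 64 and the gradient-norm cap are this package's own
reconstruction of an adversarial-autoencoder recipe; see docs/methods.md
for why the non-saturating form and the consolidation schedule are load-
bearing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .datasets import LabeledDataset
from .networks import LSPModel, PrivacyDiscriminator

__all__ = [
    "TrainingConfig", "TrainingHistory", "reconstruction_loss", "privacy_loss",
    "train_lsp", "fit_latent_statistics",
]


@dataclass
class TrainingConfig:
    gamma: float = 0.2            # privacy weight on the adversarial term
    lambda_s: float = 1.0         # weight of the sensitive-routing auxiliary head
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    betas: tuple = (0.9, 0.999)
    disc_steps_per_enc_step: int = 1
    disc_refit_steps: int = 300   # per-epoch adversary consolidation steps (gamma>0)
    privacy_pressure: float = 25.0  # gain converting gamma into gradient units
    lr_decay: float = 0.90        # per-epoch multiplicative lr cooling
    grad_clip: float = 5.0        # global L2 cap on autoencoder gradients; 0 disables
    latent_bank_cap: int = 1024
    seed: int = 0

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lambda_s < 0:
            raise ValueError("lambda_s must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.disc_steps_per_enc_step < 1:
            raise ValueError("disc_steps_per_enc_step must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch mean losses of one training run."""

    reconstruction: list = field(default_factory=list)
    discriminator: list = field(default_factory=list)
    adversarial: list = field(default_factory=list)   # CE(P(z_ns), s) seen by the encoder
    routing: list = field(default_factory=list)        # CE(aux(z_s), s)
    final_reconstruction_error: float = float("nan")

    def n_epochs(self) -> int:
        return len(self.reconstruction)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs() + 1),
            "reconstruction": self.reconstruction,
            "discriminator": self.discriminator,
            "adversarial": self.adversarial,
            "routing": self.routing,
        })


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def reconstruction_loss(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Mean squared error over every element, averaged over the batch."""
    x = np.asarray(x, float)
    x_rec = np.asarray(x_rec, float)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    return float(((x - x_rec) ** 2).mean())


def privacy_loss(pred_probs: np.ndarray, s: np.ndarray) -> float:
    """Mean cross-entropy of sensitive-attribute predictions.

    ``pred_probs`` is either (n,) probabilities of class 1 (binary s) or
    (n, C) rows summing to 1.
    """
    p = np.asarray(pred_probs, float)
    s = np.asarray(s, int)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0,1]")
    eps = 1e-12
    if p.ndim == 1:
        return float(-(np.where(s == 1, np.log(p + eps), np.log(1 - p + eps))).mean())
    return float(-np.log(p[np.arange(len(s)), s] + eps).mean())


def _ce_grad_binary(logit: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy and its gradient w.r.t. a single-logit column."""
    p = nn.sigmoid(logit[:, 0])
    loss = privacy_loss(p, s)
    grad = ((p - s) / len(s))[:, None]
    return loss, grad


def _ce_grad_categorical(logits: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    p = nn.softmax(logits, axis=1)
    loss = privacy_loss(p, s)
    grad = p.copy()
    grad[np.arange(len(s)), s] -= 1.0
    return loss, grad / len(s)


def _ce_grad(logits: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray]:
    if logits.shape[1] == 1:
        return _ce_grad_binary(logits, s)
    return _ce_grad_categorical(logits, s)


def _probs_from_logits(logits: np.ndarray) -> np.ndarray:
    if logits.shape[1] == 1:
        return nn.sigmoid(logits[:, 0])
    return nn.softmax(logits, axis=1)


def _confusion_grad(logits: np.ndarray) -> np.ndarray:
    """Gradient (w.r.t. logits) of CE(P, uniform): pushes P toward maximal
    uncertainty.  Non-saturating: strongest exactly when P is confident."""
    n = len(logits)
    if logits.shape[1] == 1:
        return ((nn.sigmoid(logits[:, 0]) - 0.5) / n)[:, None]
    p = nn.softmax(logits, axis=1)
    return (p - 1.0 / logits.shape[1]) / n


def _mean_match_grad(zin: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Gradient of the squared gap between class-conditional means of the
    released code (pairwise for binary s; class-vs-global otherwise)."""
    g = np.zeros_like(zin)
    classes = np.unique(s)
    if len(classes) < 2:
        return g
    if len(classes) == 2:
        m0, m1 = s == classes[0], s == classes[1]
        dmu = zin[m0].mean(axis=0) - zin[m1].mean(axis=0)
        g[m0] = 2.0 * dmu / m0.sum()
        g[m1] = -2.0 * dmu / m1.sum()
        return g
    mu = zin.mean(axis=0)
    for c in classes:
        mc = s == c
        g[mc] = 2.0 * (zin[mc].mean(axis=0) - mu) / mc.sum()
    return g


# ---------------------------------------------------------------------------
# single-batch steps (exposed for the degenerate-limit and isolation tests)
# ---------------------------------------------------------------------------

def _zero_grads(*nets) -> None:
    for net in nets:
        for g in net.grads():
            g[...] = 0.0


def _disc_update(model: LSPModel, disc: PrivacyDiscriminator, z: np.ndarray,
                 s: np.ndarray, opt: nn.Adam) -> float:
    zin = z[:, model.spec.d_s:] if model.spec.discriminator_input == "z_ns" else z
    _zero_grads(disc.net)
    logits = disc.net.forward(zin, train=True)
    loss, glog = _ce_grad(logits, s)
    disc.net.backward(glog)
    opt.step(disc.net.grads())
    return loss


def discriminator_step(model: LSPModel, disc: PrivacyDiscriminator,
                       x: np.ndarray, s: np.ndarray, opt: nn.Adam) -> float:
    """One adversary update on frozen encoder codes; returns the CE loss."""
    z = model.encode(x, train=True).z  # constant w.r.t. this step
    return _disc_update(model, disc, z, s, opt)


def autoencoder_step(model: LSPModel, disc: PrivacyDiscriminator,
                     aux: nn.Sequential, x: np.ndarray, s: np.ndarray,
                     opt: nn.Adam, config: TrainingConfig,
                     _precomputed: tuple | None = None) -> tuple[float, float, float]:
    """One encoder/decoder/aux update with the discriminator frozen.

    Returns (reconstruction loss, adversarial CE, routing CE); the latter two
    are NaN when their weight is zero (the terms are then never evaluated, so
    the gamma=0, lambda_s=0 case is exactly plain autoencoder training).
    ``_precomputed`` lets the training loop pass an already-run encoder
    forward (the caches stay valid because the adversary step never touches
    encoder parameters).
    """
    d_s = model.spec.d_s
    if _precomputed is None:
        xi = model._to_internal(x)
        z = model.encoder.forward(xi, train=True)
    else:
        xi, z = _precomputed
    _zero_grads(model.encoder, model.decoder, aux)
    x_dec = model.decoder.forward(z, train=True)
    # reconstruction measured in the data domain ([0,1] for images)
    if model.spec.modality == "image":
        x_rec01 = (x_dec + 1.0) / 2.0
        x01 = (xi + 1.0) / 2.0
        diff = x_rec01 - x01
        rec = float((diff ** 2).mean())
        gdec = diff * (2.0 / diff.size) * 0.5  # d x_rec01 / d x_dec = 1/2
    else:
        diff = x_dec - xi
        rec = float((diff ** 2).mean())
        gdec = diff * (2.0 / diff.size)
    gz = model.decoder.backward(gdec)

    adv_loss = float("nan")
    if config.gamma > 0:
        sl = slice(d_s, None) if model.spec.discriminator_input == "z_ns" else slice(None)
        zin = z[:, sl]
        logits = disc.net.forward(zin, train=True)  # frozen params, live statistics
        _zero_grads(disc.net)
        adv_loss = privacy_loss(_probs_from_logits(logits), s)  # reported CE vs s
        glog = _confusion_grad(logits)
        gz_adv = disc.net.backward(glog)
        _zero_grads(disc.net)
        gain = config.gamma * config.privacy_pressure
        gz[:, sl] += gain * gz_adv
        gz[:, sl] += gain * _mean_match_grad(z[:, sl], s)

    route_loss = float("nan")
    if config.lambda_s > 0 and d_s > 0:
        logits = aux.forward(z[:, :d_s], train=True)
        route_loss, glog = _ce_grad(logits, s)
        gz_aux = aux.backward(glog)
        gz[:, :d_s] += config.lambda_s * gz_aux
        for g in aux.grads():
            g *= config.lambda_s

    model.encoder.backward(gz)
    grads = model.encoder.grads() + model.decoder.grads() + aux.grads()
    if config.grad_clip > 0:
        nn.clip_gradients(grads, config.grad_clip)
    opt.step(grads)
    return rec, adv_loss, route_loss


def build_aux_head(spec, seed: int) -> nn.Sequential:
    """Linear sensitive-prediction head on z_s (the routing head)."""
    rng = np.random.default_rng(seed)
    n_out = 1 if spec.sensitive_cardinality == 2 else spec.sensitive_cardinality
    return nn.Sequential([nn.Dense(max(spec.d_s, 1), n_out, rng)])


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_lsp(model: LSPModel, disc: PrivacyDiscriminator, data: LabeledDataset,
              config: TrainingConfig) -> tuple[LSPModel, PrivacyDiscriminator, TrainingHistory]:
    """Alternating adversarial optimisation; fully seeded and reproducible."""
    config.validate()
    if data.modality != model.spec.modality:
        raise ValueError(f"data modality {data.modality!r} does not match "
                         f"model spec {model.spec.modality!r}")
    rng = np.random.default_rng(config.seed)
    aux = build_aux_head(model.spec, config.seed + 1)
    opt_ae = nn.Adam(model.encoder.params() + model.decoder.params() + aux.params(),
                     lr=config.learning_rate, betas=config.betas)
    opt_disc = nn.Adam(disc.net.params(), lr=config.learning_rate, betas=config.betas)

    n = len(data)
    history = TrainingHistory()
    for epoch in range(1, config.epochs + 1):
        decay = config.lr_decay ** (epoch - 1)
        opt_ae.lr = config.learning_rate * decay
        opt_disc.lr = config.learning_rate * decay
        if config.gamma > 0 and config.disc_refit_steps > 0:
            _consolidate_discriminator(model, disc, data, opt_disc, rng,
                                       config.disc_refit_steps)
        perm = rng.permutation(n)
        rec_sum, disc_sum, adv_sum, route_sum, n_batches = 0.0, 0.0, 0.0, 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            if len(idx) < 2:   # batch norm needs >= 2 samples
                continue
            xb, sb = data.X[idx], data.s[idx]
            xi = model._to_internal(xb)
            z = model.encoder.forward(xi, train=True)
            d_loss = 0.0
            for _ in range(config.disc_steps_per_enc_step):
                d_loss = _disc_update(model, disc, z, sb, opt_disc)
            rec, adv, route = autoencoder_step(model, disc, aux, xb, sb, opt_ae,
                                               config, _precomputed=(xi, z))
            if not np.isfinite(rec) or not np.isfinite(d_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches + 1} "
                    f"(reconstruction={rec}, discriminator={d_loss})")
            rec_sum += rec
            disc_sum += d_loss
            adv_sum += 0.0 if np.isnan(adv) else adv
            route_sum += 0.0 if np.isnan(route) else route
            n_batches += 1
        history.reconstruction.append(rec_sum / n_batches)
        history.discriminator.append(disc_sum / n_batches)
        history.adversarial.append(adv_sum / n_batches)
        history.routing.append(route_sum / n_batches)
    history.final_reconstruction_error = reconstruction_loss(
        data.X, _reconstruct_batched(model, data.X))
    fit_latent_statistics(model, data, cap=config.latent_bank_cap, seed=config.seed)
    return model, disc, history


def _consolidate_discriminator(model: LSPModel, disc: PrivacyDiscriminator,
                               data: LabeledDataset, opt: nn.Adam,
                               rng: np.random.Generator, steps: int) -> None:
    """Re-fit the adversary on freshly encoded latents of the full dataset.

    Keeps the discriminator near its best response to the current encoder,
    which is what makes the encoder's confusion gradient informative.
    """
    sl = slice(model.spec.d_s, None) if model.spec.discriminator_input == "z_ns" \
        else slice(None)
    Z = np.concatenate([model.encode(data.X[i:i + 256]).z[:, sl]
                        for i in range(0, len(data), 256)])
    n = len(Z)
    for _ in range(steps):
        idx = rng.integers(0, n, size=min(64, n))
        _zero_grads(disc.net)
        logits = disc.net.forward(Z[idx], train=True)
        _, glog = _ce_grad(logits, data.s[idx])
        disc.net.backward(glog)
        opt.step(disc.net.grads())


def _reconstruct_batched(model: LSPModel, X: np.ndarray, batch: int = 256) -> np.ndarray:
    out = [model.reconstruct(X[i:i + batch]) for i in range(0, len(X), batch)]
    return np.concatenate(out, axis=0)


def fit_latent_statistics(model: LSPModel, data: LabeledDataset,
                          cap: int = 1024, seed: int = 0) -> LSPModel:
    """Store the mean and a seeded reservoir of z_s over a dataset.

    Enables the "mean" and "resample" obfuscation modes.
    """
    if len(data) == 0:
        raise ValueError("cannot fit latent statistics on an empty dataset")
    zs = []
    for i in range(0, len(data), 256):
        zs.append(model.encode(data.X[i:i + 256]).z_s)
    zs = np.concatenate(zs, axis=0)
    model.zs_mean = zs.mean(axis=0)
    if len(zs) > cap:
        idx = np.sort(np.random.default_rng(seed).choice(len(zs), size=cap, replace=False))
        model.zs_bank = zs[idx].copy()
    else:
        model.zs_bank = zs.copy()
    return model
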