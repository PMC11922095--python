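"""Post-hoc privacy evaluation: attribute-inference and model-inversion attacks.

The attribute-inference attacker is a freshly initialised privacy
discriminator (same architecture family as the training-time adversary but
independently seeded) trained on an attack split of released codes; its
held-out accuracy, compared against the majority-class chance rate, yields
the protection score

    protection_pct = 100 * (1 - max(0, (a - c) / (1 - c)))

so a chance-level attack scores 100 (no leakage) and a perfect attack 0.

The model-inversion attacker trains an inverse decoder-family network from
released codes back to images on a public split, applies it to private
codes, and counts reconstructions whose SSIM to the true image exceeds a
threshold (default 0.8) as successes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .networks import NetworkSpec, LSPModel, PrivacyDiscriminator
from .training import _ce_grad

__all__ = [
    "PrivacyReport", "InversionReport", "AttackConfig",
    "protection_score", "attribute_inference_attack", "model_inversion_attack",
]


@dataclass
class PrivacyReport:
    attack_accuracy: float
    chance_rate: float
    protection_pct: float
    attack: str
    n_eval: int

    def to_dict(self) -> dict:
        return {"attack_accuracy": self.attack_accuracy, "chance_rate": self.chance_rate,
                "protection_pct": self.protection_pct, "attack": self.attack,
                "n_eval": self.n_eval}


@dataclass
class InversionReport:
    similarities: np.ndarray
    threshold: float
    success_rate: float

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "success_rate": self.success_rate,
                "n": int(len(self.similarities))}


@dataclass
class AttackConfig:
    train_fraction: float = 0.5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    widths: tuple = (512, 256, 128)
    dropout: float = 0.3


def protection_score(a: float, c: float) -> float:
    """100 * (1 - normalised attacker advantage over chance), in [0, 100]."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("attack accuracy must be in [0,1]")
    if not 0.0 <= c < 1.0:
        raise ValueError("chance rate must be in [0,1)")
    return float(np.clip(100.0 * (1.0 - max(0.0, (a - c) / (1.0 - c))), 0.0, 100.0))


def _train_classifier(net: PrivacyDiscriminator, Z: np.ndarray, s: np.ndarray,
                      config: AttackConfig, rng: np.random.Generator) -> None:
    opt = nn.Adam(net.net.params(), lr=config.learning_rate)
    n = len(Z)
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            for g in net.net.grads():
                g[...] = 0.0
            logits = net.net.forward(Z[idx], train=True)
            _, glog = _ce_grad(logits, s[idx])
            net.net.backward(glog)
            opt.step(net.net.grads())


def attribute_inference_attack(latents: np.ndarray, s: np.ndarray,
                               attack_config: AttackConfig | None = None,
                               seed: int = 0) -> tuple[PrivacyDiscriminator, PrivacyReport]:
    """Train a fresh adversary on (latents, s); report held-out leakage.

    ``latents`` is whatever representation is released (typically z_ns).
    The attack-train and attack-test splits are disjoint; chance rate is the
    majority-class rate of s on the evaluation split.
    """
    config = attack_config or AttackConfig()
    Z = np.atleast_2d(np.asarray(latents, float))
    s = np.asarray(s, int)
    if len(Z) != len(s):
        raise ValueError("latents and sensitive attributes must align")
    classes = np.unique(s)
    if len(classes) < 2:
        raise ValueError("sensitive attribute has a single class; chance rate would be 1")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(Z))
    n_train = int(np.floor(len(Z) * config.train_fraction))
    if n_train == 0 or n_train == len(Z):
        raise ValueError("attack split leaves an empty partition")
    tr, te = perm[:n_train], perm[n_train:]

    spec = NetworkSpec(modality="tabular", input_shape=(Z.shape[1],),
                       latent_dim=max(2, Z.shape[1]), d_s=0,
                       discriminator_widths=config.widths, dropout=config.dropout,
                       sensitive_cardinality=max(2, int(classes.max()) + 1),
                       discriminator_input="z")
    attacker = PrivacyDiscriminator(spec, seed=seed + 1)
    _train_classifier(attacker, Z[tr], s[tr], config, rng)

    pred = attacker.predict(Z[te])
    a = float((pred == s[te]).mean())
    counts = np.bincount(s[te], minlength=int(classes.max()) + 1)
    c = float(counts.max() / counts.sum())
    if c >= 1.0:
        raise ValueError("evaluation split has a single sensitive class")
    report = PrivacyReport(attack_accuracy=a, chance_rate=c,
                           protection_pct=protection_score(a, c),
                           attack="attribute_inference", n_eval=len(te))
    return attacker, report


# ---------------------------------------------------------------------------
# model inversion
# ---------------------------------------------------------------------------

def _build_inverter(d_in: int, image_shape: tuple, seed: int) -> nn.Sequential:
    """Small dense inverse network z_ns -> image (values in [0,1] via tanh)."""
    rng = np.random.default_rng(seed)
    n_out = int(np.prod(image_shape))
    return nn.Sequential([
        nn.Dense(d_in, 256, rng), nn.BatchNorm(256), nn.ReLU(),
        nn.Dense(256, 512, rng), nn.BatchNorm(512), nn.ReLU(),
        nn.Dense(512, n_out, rng), nn.Tanh(),
    ])


def _released_codes(model, X: np.ndarray) -> np.ndarray:
    if callable(model) and not isinstance(model, LSPModel):
        return np.atleast_2d(np.asarray(model(X), float))
    return np.concatenate([model.encode(X[i:i + 256]).z_ns
                           for i in range(0, len(X), 256)], axis=0)


def model_inversion_attack(model, public_images: np.ndarray,
                           private_images: np.ndarray, tau: float = 0.8,
                           seed: int = 0, epochs: int = 60,
                           batch_size: int = 64) -> InversionReport:
    """Invert released codes back to images; count SSIM > tau as success.

    ``model`` is an :class:`LSPModel` (its z_ns is the released code) or any
    callable mapping an image batch to released codes.  The attacker only
    ever sees (image, code) pairs for ``public_images``; the report is
    computed on ``private_images``.
    """
    from .metrics import ssim

    public_images = np.asarray(public_images, float)
    private_images = np.asarray(private_images, float)
    if public_images.ndim < 3:
        raise ValueError("model inversion is defined for image data only")
    img_shape = public_images.shape[1:]

    Zpub = _released_codes(model, public_images)
    rng = np.random.default_rng(seed)
    net = _build_inverter(Zpub.shape[1], img_shape, seed + 1)
    opt = nn.Adam(net.params(), lr=1e-3)
    target = public_images.reshape(len(public_images), -1) * 2.0 - 1.0
    n = len(Zpub)
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            if len(idx) < 2:
                continue
            for g in net.grads():
                g[...] = 0.0
            out = net.forward(Zpub[idx], train=True)
            diff = out - target[idx]
            net.backward(diff * (2.0 / diff.size))
            opt.step(net.grads())

    Zpriv = _released_codes(model, private_images)
    inv = (net.forward(Zpriv, train=False) + 1.0) / 2.0
    inv = np.clip(inv, 0.0, 1.0).reshape((len(Zpriv),) + img_shape)
    sims = np.array([ssim(private_images[i], inv[i]) for i in range(len(inv))])
    return InversionReport(similarities=sims, threshold=tau,
                           success_rate=float((sims > tau).mean()))
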