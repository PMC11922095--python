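"""Scikit-learn style estimator facade for the obfuscation model.

``LatentSpaceProjector`` is a transformer: ``fit(X, y=None, sensitive=s)``
adversarially trains the split-latent autoencoder against a privacy
discriminator, and ``transform(X)`` returns obfuscated reconstructions with
the sensitive subspace neutralised.  It composes with sklearn pipelines and
``clone``/``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import LabeledDataset
from .networks import NetworkSpec, LSPModel, build_encoder, build_decoder, build_discriminator
from .training import TrainingConfig, train_lsp

__all__ = ["LatentSpaceProjector"]


class LatentSpaceProjector(TransformerMixin, BaseEstimator):
    """Privacy-preserving obfuscator with an adversarially purged latent space.

    Parameters
    ----------
    gamma : float, default 0.2
        Privacy weight of the adversarial term.  0 trains a plain
        autoencoder with a routing head; larger values purge more sensitive
        information from the released subspace at some utility cost.
    lambda_s : float, default 1.0
        Weight of the auxiliary head routing sensitive information into z_s.
    latent_dim, d_s : int or None
        Latent size and sensitive-subspace size.  Defaults: 128 (image) /
        64 (tabular) and latent_dim // 8.
    obfuscation_mode : {"zero", "mean", "resample"}
        How z_s is neutralised in :meth:`transform`.
    epochs, batch_size, learning_rate, disc_steps, random_state
        Training-loop controls; every source of randomness derives from
        ``random_state``.

    Attributes
    ----------
    model_ : LSPModel
        Trained encoder/decoder with latent statistics.
    discriminator_ : PrivacyDiscriminator
        The training-time adversary.
    history_ : TrainingHistory
        Per-epoch loss traces.
    """

    def __init__(self, gamma: float = 0.2, lambda_s: float = 1.0,
                 latent_dim: int | None = None, d_s: int | None = None,
                 epochs: int = 50, batch_size: int = 64,
                 learning_rate: float = 1e-3, disc_steps: int = 1,
                 dropout: float = 0.3, obfuscation_mode: str = "zero",
                 grad_clip: float = 5.0, random_state: int = 0):
        self.gamma = gamma
        self.lambda_s = lambda_s
        self.latent_dim = latent_dim
        self.d_s = d_s
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.disc_steps = disc_steps
        self.dropout = dropout
        self.obfuscation_mode = obfuscation_mode
        self.grad_clip = grad_clip
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _as_dataset(self, X, y, sensitive) -> LabeledDataset:
        X = np.asarray(X, dtype=float)
        if sensitive is None:
            raise ValueError("LatentSpaceProjector.fit requires the sensitive attribute "
                             "(pass sensitive=...)")
        modality = "image" if X.ndim >= 3 else "tabular"
        y = np.zeros(len(X), dtype=int) if y is None else np.asarray(y)
        return LabeledDataset(X, y, np.asarray(sensitive), modality)

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y=None, sensitive=None):
        data = self._as_dataset(X, y, sensitive)
        shape = data.X.shape[1:] if data.modality == "image" else (data.X.shape[1],)
        spec = NetworkSpec(modality=data.modality, input_shape=shape,
                           latent_dim=self.latent_dim, d_s=self.d_s,
                           dropout=self.dropout,
                           sensitive_cardinality=max(2, int(data.s.max()) + 1))
        seed = int(self.random_state)
        model = LSPModel(build_encoder(spec, seed), build_decoder(spec, seed + 1),
                         spec, seed=seed)
        disc = build_discriminator(spec, seed + 2)
        config = TrainingConfig(gamma=self.gamma, lambda_s=self.lambda_s,
                                epochs=self.epochs, batch_size=self.batch_size,
                                learning_rate=self.learning_rate,
                                disc_steps_per_enc_step=self.disc_steps,
                                grad_clip=self.grad_clip, seed=seed)
        self.model_, self.discriminator_, self.history_ = train_lsp(model, disc, data, config)
        self.spec_ = spec
        self.n_features_in_ = int(np.prod(shape))
        return self

    def transform(self, X) -> np.ndarray:
        """Obfuscated reconstruction of X (same shape as the input)."""
        self._check_fitted()
        out = []
        X = np.asarray(X, dtype=float)
        for i in range(0, len(X), 256):
            out.append(self.model_.obfuscate(X[i:i + 256], mode=self.obfuscation_mode,
                                             seed=int(self.random_state) + i))
        return np.concatenate(out, axis=0)

    def encode(self, X) -> np.ndarray:
        """Full latent codes z = [z_s, z_ns]."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return np.concatenate([self.model_.encode(X[i:i + 256]).z
                               for i in range(0, len(X), 256)], axis=0)

    def encode_released(self, X) -> np.ndarray:
        """The released representation z_ns (what an attacker would see)."""
        return self.encode(X)[:, self.spec_.d_s:]

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("LatentSpaceProjector is not fitted yet")
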