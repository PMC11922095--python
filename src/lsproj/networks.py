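"""Split-latent autoencoder architectures and the privacy discriminator.

The obfuscation model is an encoder/decoder pair whose latent space Z is the
direct sum of a sensitive subspace Z_s (the first ``d_s`` coordinates) and a
nonsensitive subspace Z_ns.  The privacy discriminator is a fully connected
adversary that tries to predict the sensitive attribute from latent codes.

Image encoders stack four stride-2 convolution blocks (32, 64, 128, 256
filters, each followed by batch norm and leaky ReLU) and a final dense layer
into the latent vector — five weight layers in total.  The decoder mirrors
this with a dense layer into a spatial seed tensor and four transposed
convolutions (256, 128, 64, 32 filters), the last one squashed through tanh.
Tabular encoders/decoders are three-layer fully connected networks.  The
discriminator has three hidden layers (512, 256, 128) with dropout 0.3.

Pixels are handled in [0, 1] at the interface and mapped to [-1, 1]
internally to match the tanh output; this mapping is part of the model
contract.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "NetworkSpec", "LatentCode", "LSPModel", "PrivacyDiscriminator",
    "build_encoder", "build_decoder", "build_discriminator", "split_latent",
    "encoder_parameter_count", "decoder_parameter_count",
    "discriminator_parameter_count", "save_checkpoint", "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class NetworkSpec:
    """Architecture hyperparameters for one obfuscation model.

    ``latent_dim`` defaults to 128 for images and 64 for tabular data;
    ``d_s`` (size of the sensitive subspace) defaults to ``latent_dim // 8``.
    """

    modality: str                      # "image" | "tabular"
    input_shape: tuple                 # (H, W) or (H, W, C) for image, (n_features,) for tabular
    latent_dim: int | None = None
    d_s: int | None = None
    conv_filters: tuple = (32, 64, 128, 256)
    fc_widths: tuple = (256, 128)
    discriminator_widths: tuple = (512, 256, 128)
    dropout: float = 0.3
    sensitive_cardinality: int = 2
    discriminator_input: str = "z_ns"  # "z_ns" (released info) or "z" (stricter)

    def __post_init__(self):
        if self.modality not in ("image", "tabular"):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.input_shape = tuple(int(v) for v in self.input_shape)
        if self.modality == "image" and len(self.input_shape) == 2:
            self.input_shape = self.input_shape + (1,)
        if self.latent_dim is None:
            self.latent_dim = 128 if self.modality == "image" else 64
        if self.d_s is None:
            self.d_s = max(1, self.latent_dim // 8)
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if not 0 <= self.d_s < self.latent_dim:
            raise ValueError("d_s must satisfy 0 <= d_s < latent_dim")
        if self.sensitive_cardinality < 2:
            raise ValueError("sensitive_cardinality must be >= 2")
        if any(w <= 0 for w in self.conv_filters + self.fc_widths + self.discriminator_widths):
            raise ValueError("layer widths must be positive")
        if self.modality == "image":
            h, w = self.input_shape[:2]
            div = 2 ** len(self.conv_filters)
            if h % div or w % div:
                raise ValueError(
                    f"image size {h}x{w} must be divisible by {div} "
                    f"(one halving per conv block); pad or resize the input"
                )

    @property
    def d_ns(self) -> int:
        return self.latent_dim - self.d_s

    @property
    def disc_input_dim(self) -> int:
        return self.d_ns if self.discriminator_input == "z_ns" else self.latent_dim

    def to_dict(self) -> dict:
        return {
            "modality": self.modality, "input_shape": list(self.input_shape),
            "latent_dim": self.latent_dim, "d_s": self.d_s,
            "conv_filters": list(self.conv_filters), "fc_widths": list(self.fc_widths),
            "discriminator_widths": list(self.discriminator_widths),
            "dropout": self.dropout, "sensitive_cardinality": self.sensitive_cardinality,
            "discriminator_input": self.discriminator_input,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        for k in ("input_shape", "conv_filters", "fc_widths", "discriminator_widths"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class LatentCode:
    """A batch of latent vectors with the sensitive/nonsensitive split sizes."""

    z: np.ndarray   # (n, d)
    d_s: int

    @property
    def d(self) -> int:
        return self.z.shape[1]

    @property
    def d_ns(self) -> int:
        return self.d - self.d_s

    @property
    def z_s(self) -> np.ndarray:
        return self.z[:, :self.d_s]

    @property
    def z_ns(self) -> np.ndarray:
        return self.z[:, self.d_s:]


def split_latent(code: LatentCode) -> tuple[np.ndarray, np.ndarray]:
    """Split a latent code into (z_s, z_ns); concatenation inverts exactly."""
    return code.z_s, code.z_ns


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_encoder(spec: NetworkSpec, seed: int) -> nn.Sequential:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if spec.modality == "image":
        h, w, c = spec.input_shape
        c_in = c
        for f in spec.conv_filters:
            layers += [nn.Conv2d(c_in, f, rng), nn.BatchNorm(f), nn.LeakyReLU(0.2)]
            c_in = f
        hs = h // 2 ** len(spec.conv_filters)
        ws = w // 2 ** len(spec.conv_filters)
        layers += [nn.Flatten(), nn.Dense(c_in * hs * ws, spec.latent_dim, rng)]
    else:
        n_in = spec.input_shape[0]
        for width in spec.fc_widths:
            layers += [nn.Dense(n_in, width, rng), nn.BatchNorm(width), nn.LeakyReLU(0.2)]
            n_in = width
        layers += [nn.Dense(n_in, spec.latent_dim, rng)]
    return nn.Sequential(layers)


def build_decoder(spec: NetworkSpec, seed: int) -> nn.Sequential:
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    if spec.modality == "image":
        h, w, c = spec.input_shape
        filters = tuple(reversed(spec.conv_filters))  # e.g. 256,128,64,32
        hs, ws = h // 2 ** len(filters), w // 2 ** len(filters)
        layers += [nn.Dense(spec.latent_dim, filters[0] * hs * ws, rng),
                   nn.Reshape((filters[0], hs, ws)),
                   nn.BatchNorm(filters[0]), nn.ReLU()]
        for f_in, f_out in zip(filters[:-1], filters[1:]):
            layers += [nn.ConvTranspose2d(f_in, f_out, rng), nn.BatchNorm(f_out), nn.ReLU()]
        layers += [nn.ConvTranspose2d(filters[-1], c, rng), nn.Tanh()]
    else:
        n_out = spec.input_shape[0]
        widths = tuple(reversed(spec.fc_widths))  # e.g. 128,256
        n_in = spec.latent_dim
        for width in widths:
            layers += [nn.Dense(n_in, width, rng), nn.BatchNorm(width), nn.LeakyReLU(0.2)]
            n_in = width
        layers += [nn.Dense(n_in, n_out, rng)]
    return nn.Sequential(layers)


class PrivacyDiscriminator:
    """Adversary predicting the sensitive attribute from latent codes.

    Holds a 512-256-128 fully connected trunk with batch norm, ReLU and
    dropout 0.3, plus a logit head sized for the sensitive attribute:
    one logit (sigmoid) for binary attributes, ``cardinality`` logits
    (softmax) otherwise.
    """

    def __init__(self, spec: NetworkSpec, seed: int):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.cardinality = spec.sensitive_cardinality
        n_in = spec.disc_input_dim
        layers: list[nn.Layer] = []
        for width in spec.discriminator_widths:
            layers += [nn.Dense(n_in, width, rng), nn.BatchNorm(width),
                       nn.ReLU(), nn.Dropout(spec.dropout)]
            n_in = width
        n_out = 1 if self.cardinality == 2 else self.cardinality
        layers += [nn.Dense(n_in, n_out, rng)]
        self.net = nn.Sequential(layers).attach_rng(rng)

    def logits(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(z, train=train)

    def predict_proba(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability of each sensitive class; (n,) for binary, (n,C) else."""
        logit = self.logits(z, train=train)
        if self.cardinality == 2:
            return nn.sigmoid(logit[:, 0])
        return nn.softmax(logit, axis=1)

    def predict(self, z: np.ndarray) -> np.ndarray:
        p = self.predict_proba(z)
        return (p >= 0.5).astype(int) if p.ndim == 1 else p.argmax(axis=1)

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_discriminator(spec: NetworkSpec, seed: int) -> PrivacyDiscriminator:
    return PrivacyDiscriminator(spec, seed)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class LSPModel:
    """Encoder/decoder pair with the latent split and optional latent stats."""

    encoder: nn.Sequential
    decoder: nn.Sequential
    spec: NetworkSpec
    seed: int = 0
    zs_mean: np.ndarray | None = field(default=None, repr=False)
    zs_bank: np.ndarray | None = field(default=None, repr=False)

    def _to_internal(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.encoder.dtype)
        if self.spec.modality == "image":
            if x.ndim == 2:
                x = x[None]
            if x.ndim == 3:  # (n, H, W) -> NCHW
                x = x[:, None, :, :]
            elif x.ndim == 4 and x.shape[-1] == self.spec.input_shape[2]:
                x = x.transpose(0, 3, 1, 2)
            return 2.0 * x - 1.0
        return np.atleast_2d(x)

    def _from_internal(self, x: np.ndarray) -> np.ndarray:
        if self.spec.modality == "image":
            x = (x + 1.0) / 2.0
            return np.clip(x[:, 0] if x.shape[1] == 1 else x.transpose(0, 2, 3, 1), 0.0, 1.0)
        return x

    def encode(self, x: np.ndarray, train: bool = False) -> LatentCode:
        xi = self._to_internal(x)
        expect = ((xi.shape[3], xi.shape[2], xi.shape[1]) if self.spec.modality == "image"
                  else (xi.shape[1],))
        want = ((self.spec.input_shape[1], self.spec.input_shape[0], self.spec.input_shape[2])
                if self.spec.modality == "image" else tuple(self.spec.input_shape))
        if expect != want:
            raise ValueError(f"input shape {x.shape} does not match spec {self.spec.input_shape}")
        return LatentCode(self.encoder.forward(xi, train=train), self.spec.d_s)

    def decode(self, z: np.ndarray | LatentCode, train: bool = False) -> np.ndarray:
        if isinstance(z, LatentCode):
            z = z.z
        return self._from_internal(self.decoder.forward(np.atleast_2d(z), train=train))

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(x))

    def obfuscate(self, x: np.ndarray, mode: str = "zero",
                  seed: int | None = None) -> np.ndarray:
        """Encode, neutralise the sensitive subspace, decode.

        ``mode``: "zero" writes zeros into z_s; "mean" the training-set mean
        of z_s; "resample" a seeded draw from the stored empirical bank of
        z_s vectors.  "mean"/"resample" require fitted latent statistics.
        """
        code = self.encode(x)
        z = code.z.copy()
        if self.spec.d_s > 0:
            if mode == "zero":
                z[:, :self.spec.d_s] = 0.0
            elif mode == "mean":
                if self.zs_mean is None:
                    raise RuntimeError("latent statistics not fitted; call fit_latent_statistics")
                z[:, :self.spec.d_s] = self.zs_mean
            elif mode == "resample":
                if self.zs_bank is None or len(self.zs_bank) == 0:
                    raise RuntimeError("latent statistics not fitted; call fit_latent_statistics")
                rng = np.random.default_rng(seed)
                idx = rng.integers(0, len(self.zs_bank), size=z.shape[0])
                z[:, :self.spec.d_s] = self.zs_bank[idx]
            else:
                raise ValueError(f"unknown obfuscation mode {mode!r}")
        return self.decode(z)

    def n_parameters(self) -> int:
        return self.encoder.n_parameters() + self.decoder.n_parameters()


# ---------------------------------------------------------------------------
# parameter-count closed forms (used as structural oracles)
# ---------------------------------------------------------------------------

def _conv_params(c_in, c_out, k=4):
    return c_out * c_in * k * k + c_out


def _bn_params(c):
    return 2 * c


def _dense_params(n_in, n_out):
    return n_in * n_out + n_out


def encoder_parameter_count(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count of :func:`build_encoder`."""
    if spec.modality == "image":
        h, w, c = spec.input_shape
        total, c_in = 0, c
        for f in spec.conv_filters:
            total += _conv_params(c_in, f) + _bn_params(f)
            c_in = f
        hs = h // 2 ** len(spec.conv_filters)
        ws = w // 2 ** len(spec.conv_filters)
        return total + _dense_params(c_in * hs * ws, spec.latent_dim)
    total, n_in = 0, spec.input_shape[0]
    for width in spec.fc_widths:
        total += _dense_params(n_in, width) + _bn_params(width)
        n_in = width
    return total + _dense_params(n_in, spec.latent_dim)


def decoder_parameter_count(spec: NetworkSpec) -> int:
    if spec.modality == "image":
        h, w, c = spec.input_shape
        filters = tuple(reversed(spec.conv_filters))
        hs, ws = h // 2 ** len(filters), w // 2 ** len(filters)
        total = _dense_params(spec.latent_dim, filters[0] * hs * ws) + _bn_params(filters[0])
        for f_in, f_out in zip(filters[:-1], filters[1:]):
            total += _conv_params(f_in, f_out) + _bn_params(f_out)
        return total + _conv_params(filters[-1], c)
    total, n_in = 0, spec.latent_dim
    for width in reversed(spec.fc_widths):
        total += _dense_params(n_in, width) + _bn_params(width)
        n_in = width
    return total + _dense_params(n_in, spec.input_shape[0])


def discriminator_parameter_count(spec: NetworkSpec) -> int:
    total, n_in = 0, spec.disc_input_dim
    for width in spec.discriminator_widths:
        total += _dense_params(n_in, width) + _bn_params(width)
        n_in = width
    n_out = 1 if spec.sensitive_cardinality == 2 else spec.sensitive_cardinality
    return total + _dense_params(n_in, n_out)


# ---------------------------------------------------------------------------
# checkpoint serialisation (single text archive; deterministic bytes)
# ---------------------------------------------------------------------------

def _encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a)
    return {"dtype": str(a.dtype), "shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _decode_array(d: dict) -> np.ndarray:
    return np.frombuffer(base64.b64decode(d["data"]), dtype=d["dtype"]).reshape(d["shape"]).copy()


def _collect_state(net: nn.Sequential) -> list[np.ndarray]:
    state = list(net.params())
    for layer in net.layers:
        if isinstance(layer, nn.BatchNorm):
            state += [layer.running_mean, layer.running_var]
    return state


def save_checkpoint(model: LSPModel, path) -> None:
    """Serialise spec + all parameter/statistic arrays to one JSON file.

    The byte stream is deterministic: write -> read -> write reproduces the
    file exactly.
    """
    arrays = {}
    for name, net in (("encoder", model.encoder), ("decoder", model.decoder)):
        for i, a in enumerate(_collect_state(net)):
            arrays[f"{name}.{i}"] = _encode_array(a)
    if model.zs_mean is not None:
        arrays["zs_mean"] = _encode_array(model.zs_mean)
    if model.zs_bank is not None:
        arrays["zs_bank"] = _encode_array(model.zs_bank)
    doc = {"format": "lsproj-checkpoint", "version": CHECKPOINT_VERSION,
           "spec": model.spec.to_dict(), "seed": model.seed, "arrays": arrays}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def load_checkpoint(path) -> LSPModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "lsproj-checkpoint":
        raise ValueError(f"{path} is not a model checkpoint")
    spec = NetworkSpec.from_dict(doc["spec"])
    model = LSPModel(build_encoder(spec, doc["seed"]), build_decoder(spec, doc["seed"]),
                     spec, seed=doc["seed"])
    for name, net in (("encoder", model.encoder), ("decoder", model.decoder)):
        state = _collect_state(net)
        for i, a in enumerate(state):
            a[...] = _decode_array(doc["arrays"][f"{name}.{i}"])
    if "zs_mean" in doc["arrays"]:
        model.zs_mean = _decode_array(doc["arrays"]["zs_mean"])
    if "zs_bank" in doc["arrays"]:
        model.zs_bank = _decode_array(doc["arrays"]["zs_bank"])
    return model
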