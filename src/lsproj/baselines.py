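"""Comparison obfuscators: k-anonymity, k-Same averaging, Gaussian mechanism.

* ``MondrianKAnonymizer`` — greedy multidimensional (Mondrian-style)
  recursive partitioning of numeric quasi-identifiers; each leaf holds at
  least k records and its quasi-identifier values are replaced by the leaf
  interval midpoints, so every equivalence class has >= k rows.
* ``KSameAveraging`` — image de-identification: greedy nearest-neighbour
  grouping in pixel space into clusters of >= k images, each image replaced
  by its cluster mean.
* ``GaussianMechanism`` — classical (epsilon, delta) input perturbation:
  values clipped to the sensitivity bound, then independent Gaussian noise
  with sigma = clip * sqrt(2 ln(1.25/delta)) / epsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "KAnonConfig", "DPConfig", "MondrianKAnonymizer", "KSameAveraging",
    "GaussianMechanism", "k_anonymize_table", "k_same_images",
    "dp_gaussian_mechanism", "gaussian_sigma",
]


@dataclass
class KAnonConfig:
    k: int = 5
    quasi_identifiers: tuple = ()

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.quasi_identifiers:
            raise ValueError("quasi_identifiers must be non-empty")


@dataclass
class DPConfig:
    epsilon: float = 1.0
    delta: float = 1e-5
    clip: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0,1)")
        if self.clip <= 0:
            raise ValueError("clip (sensitivity bound) must be positive")


# ---------------------------------------------------------------------------
# Mondrian k-anonymity
# ---------------------------------------------------------------------------

def _mondrian_partition(values: np.ndarray, idx: np.ndarray, k: int,
                        leaves: list) -> None:
    """Recursively median-split on the widest-range dimension."""
    if len(idx) < 2 * k:
        leaves.append(idx)
        return
    sub = values[idx]
    spans = sub.max(axis=0) - sub.min(axis=0)
    order = np.argsort(-spans, kind="stable")  # widest first, stable tie-break
    for dim in order:
        if spans[dim] == 0:
            break
        col = sub[:, dim]
        median = np.median(col)
        left = idx[col <= median]   # lower median goes left
        right = idx[col > median]
        if len(left) >= k and len(right) >= k:
            _mondrian_partition(values, left, k, leaves)
            _mondrian_partition(values, right, k, leaves)
            return
    leaves.append(idx)


class MondrianKAnonymizer(TransformerMixin, BaseEstimator):
    """Generalise quasi-identifiers so each equivalence class has >= k rows.

    Transductive: ``fit_transform`` anonymises the table it is given.
    """

    def __init__(self, k: int = 5, quasi_identifiers: tuple = ()):
        self.k = k
        self.quasi_identifiers = quasi_identifiers

    def fit(self, X, y=None):
        KAnonConfig(self.k, tuple(self.quasi_identifiers)).validate()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        df = X.copy()
        qi = list(self.quasi_identifiers)
        values = df[qi].to_numpy(dtype=float)
        n = len(df)
        if n < self.k:
            warnings.warn(f"table has {n} < k={self.k} rows; fully suppressing "
                          "quasi-identifiers into one class")
            leaves = [np.arange(n)]
        elif self.k == 1:
            return df
        else:
            leaves = []
            _mondrian_partition(values, np.arange(n), self.k, leaves)
        out = values.copy()
        for leaf in leaves:
            mid = (values[leaf].min(axis=0) + values[leaf].max(axis=0)) / 2.0
            out[leaf] = mid
        df[qi] = out
        return df


def k_anonymize_table(table: pd.DataFrame, config: KAnonConfig) -> pd.DataFrame:
    config.validate()
    return MondrianKAnonymizer(config.k, tuple(config.quasi_identifiers)).transform(table)


# ---------------------------------------------------------------------------
# k-Same image averaging
# ---------------------------------------------------------------------------

class KSameAveraging(TransformerMixin, BaseEstimator):
    """Replace each image by the mean of a nearest-neighbour group of >= k."""

    def __init__(self, k: int = 5, random_state: int = 0):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X, float)
        n = len(X)
        if self.k == 1:
            return X.copy()
        if n < self.k:
            warnings.warn(f"{n} images < k={self.k}; returning the global mean")
            return np.broadcast_to(X.mean(axis=0), X.shape).copy()
        flat = X.reshape(n, -1)
        order = np.random.default_rng(self.random_state).permutation(n)
        unassigned = list(order)
        groups: list[np.ndarray] = []
        n_groups = n // self.k
        for _ in range(n_groups):
            seed_idx = unassigned.pop(0)
            rest = np.array(unassigned)
            if len(rest) >= self.k - 1:
                d = ((flat[rest] - flat[seed_idx]) ** 2).sum(axis=1)
                near = rest[np.argsort(d, kind="stable")[:self.k - 1]]
            else:
                near = rest
            group = np.concatenate([[seed_idx], near]).astype(int)
            unassigned = [i for i in unassigned if i not in set(near.tolist())]
            groups.append(group)
        if unassigned:  # n mod k leftovers join their nearest group centroid
            centroids = np.stack([flat[g].mean(axis=0) for g in groups])
            for i in unassigned:
                j = int(((centroids - flat[i]) ** 2).sum(axis=1).argmin())
                groups[j] = np.append(groups[j], i)
        out = np.empty_like(X)
        for g in groups:
            out[g] = X[g].mean(axis=0)
        return out


def k_same_images(images: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    return KSameAveraging(k=k, random_state=seed).transform(images)


# ---------------------------------------------------------------------------
# Gaussian mechanism
# ---------------------------------------------------------------------------

def gaussian_sigma(epsilon: float, delta: float, clip: float) -> float:
    """Noise scale of the classical Gaussian mechanism."""
    return clip * np.sqrt(2.0 * np.log(1.25 / delta)) / epsilon


class GaussianMechanism(TransformerMixin, BaseEstimator):
    """(epsilon, delta) input perturbation with calibrated Gaussian noise.

    Values are clipped to the sensitivity bound before noising; image data
    (detected by a [0, 1] clip bound with ``image=True``) is re-clipped to
    [0, 1] afterwards.
    """

    def __init__(self, epsilon: float = 1.0, delta: float = 1e-5,
                 clip: float = 1.0, image: bool = False, random_state: int = 0):
        self.epsilon = epsilon
        self.delta = delta
        self.clip = clip
        self.image = image
        self.random_state = random_state

    @property
    def sigma_(self) -> float:
        return gaussian_sigma(self.epsilon, self.delta, self.clip)

    def fit(self, X, y=None):
        DPConfig(self.epsilon, self.delta, self.clip, self.random_state).validate()
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X, float)
        lo, hi = (0.0, self.clip) if self.image else (-self.clip, self.clip)
        out = np.clip(X, lo, hi)
        rng = np.random.default_rng(self.random_state)
        out = out + rng.normal(0.0, self.sigma_, size=out.shape)
        if self.image:
            out = np.clip(out, 0.0, 1.0)
        return out


def dp_gaussian_mechanism(x: np.ndarray, config: DPConfig,
                          image: bool = False) -> np.ndarray:
    config.validate()
    return GaussianMechanism(config.epsilon, config.delta, config.clip,
                             image=image, random_state=config.seed).transform(x)
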