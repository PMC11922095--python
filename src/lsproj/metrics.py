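"""Utility, fidelity and fairness metrics for obfuscated data.

Downstream task quality is measured by training a configurable classifier
(gradient-boosted trees for tabular data, a linear probe for latent codes /
flattened images) on possibly-obfuscated training features and scoring it on
an untouched test set.  Image fidelity uses PSNR and SSIM; fairness gaps are
demographic parity and equal opportunity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (accuracy_score, average_precision_score, f1_score,
                             roc_auc_score)

__all__ = [
    "UtilityReport", "FidelityReport", "FairnessReport",
    "psnr", "ssim", "downstream_utility", "fairness_metrics", "fidelity_report",
]


@dataclass
class UtilityReport:
    accuracy: float
    f1: float           # positive class; 0 (flagged) when undefined
    auc_roc: float
    average_precision: float
    n_eval: int
    f1_degenerate: bool = False   # no positive predictions and no true positives

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "f1": self.f1, "auc_roc": self.auc_roc,
                "average_precision": self.average_precision, "n_eval": self.n_eval,
                "f1_degenerate": self.f1_degenerate}


@dataclass
class FidelityReport:
    psnr: float   # decibels; inf for identical inputs
    ssim: float

    def to_dict(self) -> dict:
        return {"psnr": self.psnr, "ssim": self.ssim}


@dataclass
class FairnessReport:
    demographic_parity_gap: float
    equal_opportunity_gap: float

    def to_dict(self) -> dict:
        return {"demographic_parity_gap": self.demographic_parity_gap,
                "equal_opportunity_gap": self.equal_opportunity_gap}


def psnr(x: np.ndarray, y: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(max_val^2 / MSE) in dB.

    Identical inputs return the ``inf`` sentinel (zero error) rather than
    raising.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(((x - y) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / mse))


def ssim(x: np.ndarray, y: np.ndarray, window: int = 11, sigma: float = 1.5,
         K1: float = 0.01, K2: float = 0.03, L: float = 1.0) -> float:
    """Mean structural similarity with a Gaussian window (standard constants)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape[:2]) < window:
        raise ValueError(f"image smaller than the {window}x{window} window")
    return float(structural_similarity(
        x, y, win_size=window, gaussian_weights=True, sigma=sigma,
        K1=K1, K2=K2, data_range=L, use_sample_covariance=False))


def fidelity_report(x: np.ndarray, y: np.ndarray) -> FidelityReport:
    """Mean per-image PSNR/SSIM over an image batch (or a single pair)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim == 2:
        return FidelityReport(psnr=psnr(x, y), ssim=ssim(x, y))
    p = [psnr(a, b) for a, b in zip(x, y)]
    s = [ssim(a, b) for a, b in zip(x, y)]
    return FidelityReport(psnr=float(np.mean(p)), ssim=float(np.mean(s)))


def _make_classifier(kind: str, seed: int):
    if kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if kind == "linear":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def downstream_utility(train_features: np.ndarray, train_y: np.ndarray,
                       test_features: np.ndarray, test_y: np.ndarray,
                       classifier: str = "linear", seed: int = 0) -> UtilityReport:
    """Fit a task classifier on (possibly obfuscated) training data.

    Scores accuracy, positive-class F1, ROC AUC and average precision on the
    untouched test set.  ``classifier``: "linear" (probe; default, suits
    latent codes and flattened images) or "gradient_boosting" (tabular).
    """
    Xtr = np.asarray(train_features, float).reshape(len(train_features), -1)
    Xte = np.asarray(test_features, float).reshape(len(test_features), -1)
    ytr = np.asarray(train_y, int)
    yte = np.asarray(test_y, int)
    if len(Xte) == 0:
        raise ValueError("test set is empty")
    if len(np.unique(ytr)) < 2:
        raise ValueError("training labels contain a single class")

    clf = _make_classifier(classifier, seed)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    score = clf.predict_proba(Xte)
    score = score[:, 1] if score.shape[1] == 2 else score

    degenerate = bool((pred == 1).sum() == 0 and (yte == 1).sum() == 0)
    multi = score.ndim > 1
    return UtilityReport(
        accuracy=float(accuracy_score(yte, pred)),
        f1=float(f1_score(yte, pred, zero_division=0.0,
                          average="binary" if not multi else "macro")),
        auc_roc=float(roc_auc_score(yte, score, multi_class="ovr" if multi else "raise")),
        average_precision=float(average_precision_score(yte, score) if not multi else
                                average_precision_score(np.eye(score.shape[1])[yte], score)),
        n_eval=len(yte), f1_degenerate=degenerate)


def fairness_metrics(pred_y: np.ndarray, true_y: np.ndarray,
                     group: np.ndarray) -> FairnessReport:
    """Demographic-parity and equal-opportunity gaps between two groups."""
    pred_y = np.asarray(pred_y, int)
    true_y = np.asarray(true_y, int)
    group = np.asarray(group, int)
    g0, g1 = group == 0, group == 1
    if g0.sum() == 0 or g1.sum() == 0:
        raise ValueError("both groups must be present")
    dp = abs(float(pred_y[g0].mean()) - float(pred_y[g1].mean()))
    pos0, pos1 = g0 & (true_y == 1), g1 & (true_y == 1)
    if pos0.sum() == 0 or pos1.sum() == 0:
        raise ValueError("equal opportunity undefined: a group has no positives")
    eo = abs(float(pred_y[pos0].mean()) - float(pred_y[pos1].mean()))
    return FairnessReport(demographic_parity_gap=dp, equal_opportunity_gap=eo)
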