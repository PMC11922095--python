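"""Privacy-utility benchmark: raw data vs obfuscators, Table-style report.

For every (method, parameter, seed) combination the harness obfuscates the
training split (or trains the projector), trains a downstream classifier on
the obfuscated features, scores it on the untouched test split, runs an
attribute-inference attack on the released representation, and (for images)
measures reconstruction fidelity.  Test data is never transformed by any
obfuscator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import GaussianMechanism, KSameAveraging, MondrianKAnonymizer
from .datasets import ImageGenConfig, TabularGenConfig, LabeledDataset, \
    generate_images, generate_transactions, train_test_split
from .estimator import LatentSpaceProjector
from .metrics import downstream_utility, fidelity_report
from .privacy import AttackConfig, attribute_inference_attack

__all__ = ["BenchmarkConfig", "run_benchmark", "privacy_utility_curve",
           "report_to_csv", "report_to_json"]


@dataclass
class BenchmarkConfig:
    """What to run: dataset source, methods with parameter grids, seeds."""

    dataset: ImageGenConfig | TabularGenConfig | LabeledDataset = field(
        default_factory=lambda: ImageGenConfig(n_samples=1200, image_size=16))
    methods: dict = field(default_factory=lambda: {"raw": [{}]})
    train_fraction: float = 0.8
    seeds: tuple = (0, 1, 2)
    classifier: str = "linear"
    epochs: int = 10           # projector training epochs
    attack: AttackConfig = field(default_factory=lambda: AttackConfig(epochs=20))
    compute_fidelity: bool = True

    def validate(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        if not self.seeds:
            raise ValueError("at least one seed is required")


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


def _materialise(config, seed: int) -> LabeledDataset:
    if isinstance(config, LabeledDataset):
        return config
    import copy
    cfg = copy.deepcopy(config)
    cfg.seed = seed
    if isinstance(cfg, ImageGenConfig):
        return generate_images(cfg)
    return generate_transactions(cfg)


def _run_one(method: str, params: dict, train: LabeledDataset,
             test: LabeledDataset, config: BenchmarkConfig, seed: int) -> dict:
    """One benchmark row; released features + obfuscated training features."""
    is_image = train.modality == "image"
    fid = None
    if method == "raw":
        feat_tr, feat_te = train.X, test.X
        released = test.X.reshape(len(test.X), -1)
        if is_image:
            fid = fidelity_report(test.X, test.X)
    elif method == "lsp":
        proj = LatentSpaceProjector(epochs=config.epochs, random_state=seed, **params)
        proj.fit(train.X, train.y, sensitive=train.s)
        feat_tr = proj.encode_released(train.X)
        feat_te = proj.encode_released(test.X)
        released = feat_te
        if is_image:
            fid = fidelity_report(test.X, proj.transform(test.X))
    elif method == "k_anonymity":
        qi = params.get("quasi_identifiers")
        cols = [f"f{j+1}" for j in range(train.X.shape[1])]
        df = pd.DataFrame(train.X, columns=cols)
        anon = MondrianKAnonymizer(k=params.get("k", 5),
                                   quasi_identifiers=tuple(qi or cols)).transform(df)
        feat_tr = anon[cols].to_numpy()
        feat_te = test.X
        released = feat_tr
    elif method == "k_same":
        feat_tr = KSameAveraging(k=params.get("k", 5), random_state=seed).transform(train.X)
        feat_te = test.X
        released = feat_tr.reshape(len(feat_tr), -1)
        if is_image:
            fid = fidelity_report(train.X, feat_tr)
    elif method == "dp_gaussian":
        mech = GaussianMechanism(epsilon=params.get("epsilon", 1.0),
                                 delta=params.get("delta", 1e-5),
                                 clip=params.get("clip", 1.0),
                                 image=is_image, random_state=seed)
        feat_tr = mech.transform(train.X)
        feat_te = test.X
        released = feat_tr.reshape(len(feat_tr), -1)
        if is_image:
            fid = fidelity_report(train.X, feat_tr)
    else:
        raise ValueError(f"unknown method {method!r}")

    utility = downstream_utility(feat_tr, train.y, feat_te, test.y,
                                 classifier=config.classifier, seed=seed)
    s_for_attack = test.s if method in ("raw", "lsp") else train.s
    _, privacy = attribute_inference_attack(released, s_for_attack,
                                            config.attack, seed=seed)
    row = {"method": method, "params": json.dumps(params, sort_keys=True), "seed": seed,
           **{f"utility_{k}": v for k, v in utility.to_dict().items()},
           **{f"privacy_{k}": v for k, v in privacy.to_dict().items()}}
    if fid is not None:
        row.update({f"fidelity_{k}": v for k, v in fid.to_dict().items()})
    return row


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """One row per (method, params, seed); failures are recorded, not fatal."""
    config.validate()
    methods = dict(config.methods)
    methods.setdefault("raw", [{}])   # reference row always present
    rows = []
    for seed in config.seeds:
        data = _materialise(config.dataset, seed)
        train, test = train_test_split(data, config.train_fraction, seed=seed)
        test_hash = _hash_array(test.X)
        for method, param_grid in methods.items():
            for params in param_grid:
                try:
                    rows.append(_run_one(method, params, train, test, config, seed))
                except Exception as exc:   # noqa: BLE001 - row-level isolation
                    rows.append({"method": method, "params": json.dumps(params, sort_keys=True),
                                 "seed": seed, "failed": str(exc)})
        assert _hash_array(test.X) == test_hash, "test data was mutated by an obfuscator"
    return pd.DataFrame(rows)


def privacy_utility_curve(report: pd.DataFrame, method: str = "lsp",
                          utility_col: str = "utility_accuracy") -> tuple[pd.DataFrame, float]:
    """Utility-vs-protection curve for one method and its trapezoidal area.

    Points are the per-parameter means over seeds, sorted by protection;
    both axes are normalised to [0, 1] (protection /100).  Needs >= 2
    parameter points.
    """
    sub = report[(report["method"] == method) & report.get("failed", pd.Series(dtype=object)).isna()] \
        if "failed" in report.columns else report[report["method"] == method]
    pts = (sub.groupby("params", as_index=False)
              .agg(protection=("privacy_protection_pct", "mean"),
                   utility=(utility_col, "mean")))
    if len(pts) < 2:
        raise ValueError("privacy-utility curve needs at least 2 parameter points")
    pts = pts.sort_values("protection", kind="stable").reset_index(drop=True)
    x = pts["protection"].to_numpy() / 100.0
    y = pts["utility"].to_numpy()
    area = float(np.trapezoid(y, x)) if hasattr(np, "trapezoid") else float(np.trapz(y, x))
    return pts, area


def report_to_csv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)


def report_to_json(report: pd.DataFrame, path) -> None:
    """Aggregate mean +/- sd over seeds per (method, params)."""
    num_cols = [c for c in report.columns
                if c.startswith(("utility_", "privacy_", "fidelity_"))
                and report[c].dtype != object]
    agg = report.groupby(["method", "params"])[num_cols].agg(["mean", "std"])
    out = {f"{m}|{p}": {f"{c[0]}_{c[1]}": (None if pd.isna(v) else float(v))
                        for c, v in row.items()}
           for (m, p), row in agg.iterrows()}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))
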