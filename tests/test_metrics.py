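"""Fidelity, utility and fairness metrics against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from lsproj import (downstream_utility, fairness_metrics, fidelity_report,
                    psnr, ssim)


class TestPSNR:
    def test_identical_inputs_infinite_sentinel(self, rng):
        x = rng.random((16, 16))
        assert psnr(x, x) == float("inf")

    def test_uniform_offset_is_20db(self, rng):
        x = rng.random((16, 16)) * 0.8
        assert psnr(x, x + 0.1) == pytest.approx(20.0, abs=1e-9)

    def test_matches_brute_force_formula(self, rng):
        x, y = rng.random((8, 8)), rng.random((8, 8))
        mse = np.mean([(float(x[i, j]) - float(y[i, j])) ** 2
                       for i in range(8) for j in range(8)])
        assert psnr(x, y) == pytest.approx(10 * np.log10(1.0 / mse), abs=1e-9)

    def test_decreases_with_noise_variance(self, rng):
        x = rng.random((32, 32))
        vals = [psnr(x, np.clip(x + rng.normal(0, sd, x.shape), 0, 1))
                for sd in (0.01, 0.05, 0.2)]
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            psnr(rng.random((4, 4)), rng.random((5, 5)))


def _reference_ssim(x, y, sigma=1.5, K1=0.01, K2=0.03, L=1.0, truncate=3.5):
    """Direct Gaussian-window SSIM (independent of scikit-image)."""
    C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
    f = lambda a: gaussian_filter(a, sigma, truncate=truncate, mode="reflect")
    mx, my = f(x), f(y)
    vx = f(x * x) - mx * mx
    vy = f(y * y) - my * my
    cxy = f(x * y) - mx * my
    s = ((2 * mx * my + C1) * (2 * cxy + C2)) / ((mx ** 2 + my ** 2 + C1) * (vx + vy + C2))
    pad = (11 - 1) // 2   # crop the filter-radius border, as the metric does
    return float(s[pad:-pad, pad:-pad].mean())


class TestSSIM:
    def test_identity_is_one(self, rng):
        x = rng.random((24, 24))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.random((24, 24)), rng.random((24, 24))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_matches_independent_gaussian_window_implementation(self, rng):
        x = rng.random((32, 32))
        y = np.clip(x + rng.normal(0, 0.1, x.shape), 0, 1)
        assert ssim(x, y) == pytest.approx(_reference_ssim(x, y), abs=1e-6)

    def test_bounded_and_below_one_for_different_inputs(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        v = ssim(x, y)
        assert -1.0 <= v < 1.0

    def test_image_smaller_than_window_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((8, 8)), rng.random((8, 8)))


class TestFidelityReport:
    def test_raw_row_is_perfect(self, rng):
        x = rng.random((3, 16, 16))
        rep = fidelity_report(x, x)
        assert rep.psnr == float("inf")
        assert rep.ssim == pytest.approx(1.0, abs=1e-9)


class TestDownstreamUtility:
    def test_perfectly_separable_data(self, rng):
        X = np.concatenate([rng.normal(-5, 0.1, (50, 3)), rng.normal(5, 0.1, (50, 3))])
        y = np.repeat([0, 1], 50)
        rep = downstream_utility(X, y, X, y, classifier="linear")
        assert rep.accuracy == 1.0 and rep.auc_roc == 1.0

    def test_all_negative_predictions_give_zero_f1(self, rng):
        """The degenerate-imbalance failure mode: no positives predicted."""
        Xtr = rng.normal(0, 1, (200, 4))
        ytr = (rng.random(200) < 0.02).astype(int)
        ytr[:2] = 1   # keep both classes present
        Xte = rng.normal(0, 1, (100, 4))
        yte = (rng.random(100) < 0.02).astype(int)
        rep = downstream_utility(Xtr, ytr, Xte, yte, classifier="linear")
        if (rep.n_eval and (yte == 1).sum() == 0):
            assert rep.f1 == 0.0

    def test_metrics_match_brute_force_confusion_matrix(self, small_table, rng):
        from sklearn.linear_model import LogisticRegression
        X, y = small_table.X, small_table.y
        rep = downstream_utility(X[:4000], y[:4000], X[4000:], y[4000:],
                                 classifier="linear", seed=0)
        clf = LogisticRegression(max_iter=2000, random_state=0).fit(X[:4000], y[:4000])
        pred = clf.predict(X[4000:])
        yte = y[4000:]
        tp = int(((pred == 1) & (yte == 1)).sum())
        fp = int(((pred == 1) & (yte == 0)).sum())
        fn = int(((pred == 0) & (yte == 1)).sum())
        acc = float((pred == yte).mean())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        assert rep.accuracy == pytest.approx(acc, abs=1e-12)
        assert rep.f1 == pytest.approx(f1, abs=1e-12)

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(0, 1, (20, 3))
        with pytest.raises(ValueError):
            downstream_utility(X, np.zeros(20), X, np.zeros(20))

    def test_majority_class_floor(self, small_table):
        """Any sane classifier beats or matches the majority-class rate."""
        X, y = small_table.X, small_table.y
        rep = downstream_utility(X[:4000], y[:4000], X[4000:], y[4000:],
                                 classifier="gradient_boosting", seed=0)
        prevalence = y[4000:].mean()
        assert rep.accuracy >= max(prevalence, 1 - prevalence) - 0.02


class TestFairness:
    def test_equal_rates_give_zero_gaps(self):
        pred = np.array([1, 0, 1, 0])
        true = np.array([1, 1, 1, 1])
        group = np.array([0, 0, 1, 1])
        rep = fairness_metrics(pred, true, group)
        assert rep.demographic_parity_gap == 0.0
        assert rep.equal_opportunity_gap == 0.0

    def test_toy_gap_arithmetic(self):
        # group 0: positive rate 0.6 over 5; group 1: 0.2 over 5
        pred = np.array([1, 1, 1, 0, 0, 1, 0, 0, 0, 0])
        true = np.ones(10, dtype=int)
        group = np.repeat([0, 1], 5)
        rep = fairness_metrics(pred, true, group)
        assert rep.demographic_parity_gap == pytest.approx(0.4)

    def test_matches_brute_force_group_rates(self, rng):
        pred = rng.integers(0, 2, 200)
        true = rng.integers(0, 2, 200)
        group = rng.integers(0, 2, 200)
        if true[group == 0].sum() == 0 or true[group == 1].sum() == 0:
            pytest.skip("no positives in a group for this draw")
        rep = fairness_metrics(pred, true, group)
        dp = abs(pred[group == 0].mean() - pred[group == 1].mean())
        tpr0 = pred[(group == 0) & (true == 1)].mean()
        tpr1 = pred[(group == 1) & (true == 1)].mean()
        assert rep.demographic_parity_gap == pytest.approx(dp, abs=1e-12)
        assert rep.equal_opportunity_gap == pytest.approx(abs(tpr0 - tpr1), abs=1e-12)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError):
            fairness_metrics(np.ones(4), np.ones(4), np.zeros(4))

    def test_group_without_positives_rejected(self):
        pred = np.array([1, 0, 1, 0])
        true = np.array([1, 1, 0, 0])
        group = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="equal opportunity"):
            fairness_metrics(pred, true, group)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 0.3))
def test_psnr_ssim_degrade_together_property(seed, sd):
    """Noisier copies never look *more* similar: PSNR finite and SSIM < 1
    whenever noise is actually added."""
    r = np.random.default_rng(seed)
    x = r.random((16, 16))
    y = np.clip(x + r.normal(0, sd, x.shape), 0, 1)
    if np.array_equal(x, y):
        assert psnr(x, y) == float("inf")
    else:
        assert np.isfinite(psnr(x, y))
        assert ssim(x, y) < 1.0
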