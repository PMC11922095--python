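"""Synthetic generators: determinism, marginal rates, separability, splits."""

import numpy as np
import pytest
from scipy import stats

from lsproj import (ImageGenConfig, TabularGenConfig, generate_images,
                    generate_transactions, train_test_split)
from lsproj.datasets import joint_bernoulli_table, phi_coefficient


def binomial_99_interval(n, p):
    """Central 99% interval of Binomial(n, p) counts (exact)."""
    return stats.binom.ppf(0.005, n, p), stats.binom.ppf(0.995, n, p)


class TestImageGenerator:
    def test_fixed_seed_is_bit_identical(self):
        cfg = dict(n_samples=200, image_size=16, sensitive_rate=0.5, seed=7)
        a = generate_images(ImageGenConfig(**cfg))
        b = generate_images(ImageGenConfig(**cfg))
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.s, b.s)

    def test_pixels_in_unit_interval(self, small_images):
        assert small_images.X.min() >= 0.0
        assert small_images.X.max() <= 1.0

    def test_sensitive_rate_within_binomial_interval(self):
        n = 10_000
        d = generate_images(ImageGenConfig(n_samples=n, image_size=16,
                                           sensitive_rate=0.3, seed=1))
        lo, hi = binomial_99_interval(n, 0.3)
        assert lo <= d.s.sum() <= hi

    def test_zero_correlation_gives_small_phi(self):
        n = 4000
        d = generate_images(ImageGenConfig(n_samples=n, image_size=16,
                                           label_attr_correlation=0.0, seed=2))
        assert abs(phi_coefficient(d.y, d.s)) <= 3.0 / np.sqrt(n)

    def test_requested_correlation_is_realised(self):
        n = 20_000
        d = generate_images(ImageGenConfig(n_samples=n, image_size=16,
                                           label_attr_correlation=0.5, seed=3))
        assert phi_coefficient(d.y, d.s) == pytest.approx(0.5, abs=3.0 / np.sqrt(n))

    def test_infeasible_correlation_names_interval(self):
        with pytest.raises(ValueError, match="feasible interval"):
            generate_images(ImageGenConfig(n_samples=10, class_rate=0.9,
                                           sensitive_rate=0.1,
                                           label_attr_correlation=0.9))

    def test_linear_probe_recovers_label_and_attribute(self):
        """Raw-pixel linear probes reach >= 0.90 held-out accuracy for both
        the morphological label and the texture attribute."""
        from sklearn.linear_model import LogisticRegression
        d = generate_images(ImageGenConfig(n_samples=2000, image_size=32,
                                           label_attr_correlation=0.0,
                                           noise_sd=0.05, seed=4))
        tr, te = train_test_split(d, 0.5, seed=0)
        Xtr = tr.X.reshape(len(tr.X), -1)
        Xte = te.X.reshape(len(te.X), -1)
        for target_tr, target_te in ((tr.y, te.y), (tr.s, te.s)):
            probe = LogisticRegression(max_iter=2000).fit(Xtr, target_tr)
            assert probe.score(Xte, target_te) >= 0.90


class TestJointBernoulli:
    def test_table_matches_marginals_and_phi(self):
        t = joint_bernoulli_table(0.4, 0.6, 0.3)
        assert t.sum() == pytest.approx(1.0)
        assert t[1].sum() == pytest.approx(0.4)    # P(y=1)
        assert t[:, 1].sum() == pytest.approx(0.6)  # P(s=1)
        sd = np.sqrt(0.4 * 0.6 * 0.6 * 0.4)
        assert t[1, 1] == pytest.approx(0.4 * 0.6 + 0.3 * sd)

    def test_independence_at_zero_phi(self):
        t = joint_bernoulli_table(0.3, 0.7, 0.0)
        assert t[1, 1] == pytest.approx(0.21)

    def test_degenerate_marginal_requires_zero_phi(self):
        joint_bernoulli_table(1.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            joint_bernoulli_table(1.0, 0.5, 0.1)


class TestTabularGenerator:
    def test_fixed_seed_is_bit_identical(self):
        a = generate_transactions(TabularGenConfig(n_samples=5000, seed=9))
        b = generate_transactions(TabularGenConfig(n_samples=5000, seed=9))
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)

    def test_fraud_prevalence_calibrated(self):
        """At the default 0.172% rate, the positive count over 100k rows
        stays inside the exact central 99% binomial interval around 172."""
        n = 100_000
        d = generate_transactions(TabularGenConfig(n_samples=n, seed=0))
        lo, hi = binomial_99_interval(n, 0.00172)
        assert lo <= d.y.sum() <= hi

    def test_zero_coefficients_decouple_label_from_features(self):
        n = 50_000
        d = generate_transactions(TabularGenConfig(
            n_samples=n, n_features=5, fraud_rate=0.3,
            fraud_coefs=np.zeros(5), seed=1))
        for j in range(5):
            r = np.corrcoef(d.X[:, j], d.y)[0, 1]
            assert abs(r) <= 0.02

    def test_coefficient_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            generate_transactions(TabularGenConfig(
                n_samples=10, n_features=5, fraud_coefs=np.ones(3)))

    def test_features_are_standardized(self, small_table):
        assert np.abs(small_table.X.mean(axis=0)).max() < 0.1
        assert np.abs(small_table.X.std(axis=0) - 1.0).max() < 0.1


class TestTrainTestSplit:
    @pytest.mark.parametrize("n,fraction,expected", [
        (2637, 0.8, (2109, 528)),
        (10, 0.5, (5, 5)),
        (101, 0.8, (80, 21)),
    ])
    def test_floor_rule_sizes(self, n, fraction, expected):
        d = generate_transactions(TabularGenConfig(n_samples=n, n_features=3,
                                                   fraud_rate=0.3, seed=0))
        tr, te = train_test_split(d, fraction, seed=0)
        assert (len(tr), len(te)) == expected

    def test_partition_is_disjoint_and_exhaustive(self):
        d = generate_transactions(TabularGenConfig(n_samples=50, n_features=3,
                                                   fraud_rate=0.3, seed=0))
        d.X[:, 0] = np.arange(50)  # unique marker per row
        tr, te = train_test_split(d, 0.5, seed=1)
        seen = np.concatenate([tr.X[:, 0], te.X[:, 0]])
        assert sorted(seen.astype(int).tolist()) == list(range(50))

    def test_alignment_preserved(self, small_images):
        tr, _ = train_test_split(small_images, 0.8, seed=2)
        # blob brightness area grows with the label: check y still matches X
        area = (tr.X > 0.7).mean(axis=(1, 2))
        assert area[tr.y == 1].mean() > area[tr.y == 0].mean()

    def test_invalid_fraction_rejected(self, small_images):
        with pytest.raises(ValueError):
            train_test_split(small_images, 1.0)
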