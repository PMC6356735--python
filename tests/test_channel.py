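"""Unimodal channel: attenuation, noise, DCT features, density propagation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msifusion.channel import (
    FeatureTransform,
    add_noise,
    attenuate,
    build_dct_basis,
    dct_rows,
    extract_features,
    fit_feature_transform,
    fit_normalizer,
    propagate_density,
    rank_coefficients,
)


class TestAttenuate:
    def test_identity_zero_and_scaling(self):
        np.testing.assert_array_equal(attenuate([2.0, 4.0], 1.0), [2.0, 4.0])
        np.testing.assert_array_equal(attenuate([2.0, 4.0], 0.0), [0.0, 0.0])
        np.testing.assert_array_equal(attenuate([2.0, 4.0], 0.5), [1.0, 2.0])

    @pytest.mark.parametrize("alpha", [-0.1, 1.1])
    def test_out_of_range_raises(self, alpha):
        with pytest.raises(ValueError):
            attenuate([1.0], alpha)


class TestAddNoise:
    def test_zero_covariance_is_identity(self):
        x = np.arange(5.0)
        np.testing.assert_array_equal(add_noise(x, 0.0, rng_seed=0), x)

    def test_seeded_reproducibility(self):
        x = np.ones(8)
        np.testing.assert_array_equal(
            add_noise(x, 2.0, rng_seed=11), add_noise(x, 2.0, rng_seed=11)
        )

    def test_monte_carlo_covariance(self):
        # 1e4 draws, isotropic: sample covariance within 3 SE of sigma^2 I
        var, d, n = 1.5, 5, 10_000
        draws = add_noise(np.zeros((n, d)), var, rng_seed=3)
        cov = np.cov(draws, rowvar=False)
        se_diag = var * np.sqrt(2.0 / (n - 1))
        se_off = var / np.sqrt(n - 1)
        assert np.all(np.abs(np.diag(cov) - var) < 3 * se_diag)
        off = cov - np.diag(np.diag(cov))
        assert np.all(np.abs(off) < 3 * se_off)

    def test_full_covariance_matrix(self):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        draws = add_noise(np.zeros((20_000, 2)), cov, rng_seed=5)
        emp = np.cov(draws, rowvar=False)
        assert np.allclose(emp, cov, atol=0.05)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(3), np.eye(2), rng_seed=0)


class TestDCTBasis:
    def test_d1_is_unity(self):
        np.testing.assert_allclose(build_dct_basis(1), [[1.0]])

    @pytest.mark.parametrize("d", [2, 4, 16, 33])
    def test_orthonormality(self, d):
        b = build_dct_basis(d)
        assert np.max(np.abs(b @ b.T - np.eye(d))) < 1e-10

    def test_constant_input_closed_form(self):
        # DCT-II of [1,1,1,1] concentrates in the DC coefficient: [2,0,0,0]
        b = build_dct_basis(4)
        np.testing.assert_allclose(b @ np.ones(4), [2.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_direct_summation_oracle(self, rng):
        # X_k = s_k sum_n x_n cos(pi k (2n+1) / (2d)), s_0 = sqrt(1/d), else sqrt(2/d)
        d = 12
        x = rng.normal(size=d)
        expected = np.empty(d)
        for k in range(d):
            s = np.sqrt(1.0 / d) if k == 0 else np.sqrt(2.0 / d)
            expected[k] = s * sum(
                x[n] * np.cos(np.pi * k * (2 * n + 1) / (2 * d)) for n in range(d)
            )
        np.testing.assert_allclose(build_dct_basis(d) @ x, expected, atol=1e-10)
        np.testing.assert_allclose(
            dct_rows(d, np.arange(d)) @ x, expected, atol=1e-10
        )

    def test_invalid_dimension_raises(self):
        with pytest.raises(ValueError):
            build_dct_basis(0)


def _fisher_scores(groups: dict, eps: float = 1e-12) -> np.ndarray:
    """Brute-force separability oracle: between-class / pooled within-class."""
    means = np.stack([np.mean(v, axis=0) for v in groups.values()])
    between = means.var(axis=0)
    d = means.shape[1]
    num, dof = np.zeros(d), 0
    for v in groups.values():
        v = np.asarray(v)
        if v.shape[0] > 1:
            num += (v.shape[0] - 1) * v.var(axis=0, ddof=1)
        dof += v.shape[0]
    within = num / max(dof - len(groups), 1)
    return between / (within + eps)


class TestRankCoefficients:
    def test_exhaustive_selection(self, rng):
        x = {0: rng.normal(size=(4, 6)), 1: rng.normal(size=(4, 6))}
        assert sorted(rank_coefficients(x, 6)) == list(range(6))

    def test_single_informative_coefficient_ranked_first(self, rng):
        # classes differ only in coefficient 5; noise everywhere else
        a = rng.normal(0, 1, size=(50, 8))
        b = rng.normal(0, 1, size=(50, 8))
        b[:, 5] += 10.0
        groups = {0: a, 1: b}
        idx = rank_coefficients(groups, 8)
        assert idx[0] == 5
        scores = _fisher_scores(groups)
        np.testing.assert_array_equal(idx, np.lexsort((np.arange(8), -scores)))

    def test_zero_within_class_variance_guard(self):
        # degenerate within-class variance: ranking by between-class variance
        groups = {0: np.tile([1.0, 0.0, 3.0], (3, 1)), 1: np.tile([2.0, 0.0, 9.0], (3, 1))}
        idx = rank_coefficients(groups, 3)
        np.testing.assert_array_equal(idx, [2, 0, 1])

    def test_too_many_requested_raises(self, rng):
        with pytest.raises(ValueError):
            rank_coefficients({0: rng.normal(size=(3, 4))}, 5)


class TestExtractAndNormalize:
    def test_selection_equals_full_dct_subset(self, rng):
        d = 40
        idx = np.array([0, 3, 17, 39])
        tf = FeatureTransform(raw_dim=d, selected_indices=idx)
        x = rng.normal(size=d)
        full = build_dct_basis(d) @ x
        np.testing.assert_allclose(extract_features(x, tf), full[idx], atol=1e-10)
        np.testing.assert_allclose(tf.selection_matrix @ x, full[idx], atol=1e-10)

    def test_zero_signal_gives_zero_features(self):
        tf = FeatureTransform(raw_dim=6, selected_indices=np.array([1, 4]))
        np.testing.assert_array_equal(extract_features(np.zeros(6), tf), [0.0, 0.0])

    def test_linearity_of_noise_free_channel(self, rng):
        tf = FeatureTransform(raw_dim=10, selected_indices=np.array([0, 2, 5]))
        x = rng.normal(size=10)
        np.testing.assert_allclose(
            extract_features(0.37 * x, tf), 0.37 * extract_features(x, tf)
        )

    def test_dimension_mismatch_raises(self):
        tf = FeatureTransform(raw_dim=6, selected_indices=np.array([0]))
        with pytest.raises(ValueError):
            extract_features(np.zeros(5), tf)

    @pytest.mark.parametrize(
        "span,interval,expected",
        [((0.0, 10.0), (0.0, 1.0), (0.1, 0.0)), ((2.0, 12.0), (0.0, 1.0), (0.1, -0.2))],
    )
    def test_normalizer_slope_intercept(self, span, interval, expected):
        feats = np.linspace(*span, 7)
        m, c = fit_normalizer(feats, *interval)
        assert (m, c) == pytest.approx(expected)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30, unique=True))
    def test_normalizer_endpoint_exactness(self, values):
        feats = np.array(values)
        m, c = fit_normalizer(feats, -1.0, 2.0)
        mapped = m * feats + c
        assert mapped.min() == pytest.approx(-1.0, abs=1e-12)
        assert mapped.max() == pytest.approx(2.0, abs=1e-12)

    def test_degenerate_range_raises(self):
        with pytest.raises(ValueError):
            fit_normalizer(np.full(4, 3.0), 0.0, 1.0)


class TestPropagateDensity:
    def test_isotropic_noise_collapses_to_scaled_identity(self, rng):
        # orthonormal rows: Phi Psi Phi^T = sigma^2 I
        tf = FeatureTransform(
            raw_dim=16, selected_indices=np.array([1, 5, 9]), slope=2.0, intercept=0.3
        )
        dens = propagate_density(rng.normal(size=16), 0.5, tf)
        np.testing.assert_allclose(dens.covariance, 2.0**2 * 0.5 * np.eye(3), atol=1e-10)

    def test_full_covariance_form(self, rng):
        d = 8
        a = rng.normal(size=(d, d))
        psi = a @ a.T
        tf = FeatureTransform(
            raw_dim=d, selected_indices=np.array([0, 3]), slope=1.5, intercept=-0.2
        )
        dens = propagate_density(rng.normal(size=d), psi, tf)
        phi = tf.selection_matrix
        np.testing.assert_allclose(
            dens.covariance, 1.5**2 * phi @ psi @ phi.T, atol=1e-10
        )

    def test_monte_carlo_agreement_with_simulated_channel(self, rng):
        # core correctness: analytic density vs 1e4 simulated channel outputs
        d, n_draws, var = 32, 10_000, 0.4
        proto = rng.normal(size=d)
        labels = np.repeat([0, 1], 20)
        train = np.concatenate(
            [proto + rng.normal(0, 0.6, size=(20, d)),
             -proto + rng.normal(0, 0.6, size=(20, d))]
        )
        tf = fit_feature_transform(train, labels, feature_dim=8)
        dens = propagate_density(proto, var, tf)

        noisy = proto + rng.normal(0, np.sqrt(var), size=(n_draws, d))
        feats = tf.transform(noisy)
        se_mean = np.sqrt(np.diag(dens.covariance) / n_draws)
        assert np.all(np.abs(feats.mean(axis=0) - dens.mean) < 3 * se_mean)
        emp_cov = np.cov(feats, rowvar=False)
        frob_rel = np.linalg.norm(emp_cov - dens.covariance) / np.linalg.norm(
            dens.covariance
        )
        assert frob_rel < 0.1

    def test_negative_variance_raises(self):
        tf = FeatureTransform(raw_dim=4, selected_indices=np.array([0]))
        with pytest.raises(ValueError):
            propagate_density(np.ones(4), -1.0, tf)


class TestFitFeatureTransform:
    def test_fitted_range_maps_to_interval(self, rng):
        x = rng.normal(size=(30, 20))
        labels = np.repeat([0, 1, 2], 10)
        tf = fit_feature_transform(x, labels, feature_dim=5, interval=(0.0, 1.0))
        feats = tf.transform(x)
        assert feats.min() == pytest.approx(0.0, abs=1e-12)
        assert feats.max() == pytest.approx(1.0, abs=1e-12)
        assert tf.feature_dim == 5
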