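"""Feature-integrating and decision-integrating fusion."""

import itertools

import numpy as np
import pytest

from msifusion.classifiers import (
    GaussianClassConditional,
    TrainingConfig,
    decide,
    fit_gaussian_map,
    map_posterior,
    mlp_forward,
)
from msifusion.fusion import (
    ConfusionModel,
    di_concat_posteriors,
    di_map_likelihood,
    di_map_posterior,
    estimate_confusion,
    fi_classify,
    fi_concat,
    fit_fi_map,
    train_di_mlp,
)


class TestFIConcat:
    def test_concatenation_and_offsets(self):
        fused = fi_concat([np.array([1.0, 2.0]), np.array([3.0])])
        np.testing.assert_array_equal(fused.values, [1.0, 2.0, 3.0])
        assert fused.modality_offsets == (0, 2)
        np.testing.assert_array_equal(fused.slice_of(1), [3.0])

    def test_two_64_feature_modalities_fuse_to_128(self, rng):
        fused = fi_concat([rng.normal(size=64), rng.normal(size=64)])
        assert fused.values.shape == (128,)

    def test_single_modality_identity(self, rng):
        x = rng.normal(size=5)
        np.testing.assert_array_equal(fi_concat([x]).values, x)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fi_concat([])


class TestFitFIMap:
    def test_independent_noise_off_diagonal_vanishes(self, rng):
        # large-n fused covariance: cross-modality blocks -> 0 within 3 SE
        n, var = 4000, 1.0
        a = rng.normal(0, np.sqrt(var), size=(n, 3))
        b = rng.normal(0, np.sqrt(var), size=(n, 2))
        fused = np.concatenate([a, b], axis=1)
        models = fit_fi_map(fused, np.zeros(n, dtype=int), priors=[1.0], shrinkage=0.0)
        cross = models[0].covariance[:3, 3:]
        assert np.all(np.abs(cross) < 3 * var / np.sqrt(n - 1))

    def test_shared_noise_appears_in_cross_block(self, rng):
        n = 4000
        shared = rng.normal(0, 1.0, size=(n, 1))
        a = shared + rng.normal(0, 0.3, size=(n, 1))
        b = shared + rng.normal(0, 0.3, size=(n, 1))
        fused = np.concatenate([a, b], axis=1)
        models = fit_fi_map(fused, np.zeros(n, dtype=int), priors=[1.0], shrinkage=0.0)
        # closed form: cov(a, b) = var(shared) = 1
        assert models[0].covariance[0, 1] == pytest.approx(1.0, abs=0.1)

    def test_single_modality_reduces_to_unimodal_fit(self, rng):
        x = rng.normal(size=(40, 4))
        y = np.repeat([0, 1], 20)
        a = fit_fi_map(x, y)
        b = fit_gaussian_map(x, y)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.mean, mb.mean)
            np.testing.assert_array_equal(ma.covariance, mb.covariance)


class TestFIClassify:
    def test_map_backend_delegates_to_map_posterior(self, rng):
        x = rng.normal(size=(30, 4))
        y = np.repeat([0, 1], 15)
        models = fit_gaussian_map(x, y)
        fused = fi_concat([x[0, :2], x[0, 2:]])
        np.testing.assert_array_equal(
            fi_classify(fused, models), map_posterior(x[0], models)
        )

    def test_identical_class_models_give_uniform(self):
        models = [
            GaussianClassConditional(k, np.zeros(3), np.eye(3), 0.25)
            for k in range(4)
        ]
        post = fi_classify(np.zeros(3), models)
        np.testing.assert_allclose(post, np.full(4, 0.25))


class TestDIConcat:
    def test_dimension_k_times_j(self, rng):
        blocks = [np.full(10, 0.1), np.full(10, 0.1)]
        z = di_concat_posteriors(blocks)
        assert z.shape == (20,)
        assert z[:10].sum() == pytest.approx(1.0)
        assert z[10:].sum() == pytest.approx(1.0)

    def test_single_modality_identity(self):
        p = np.array([0.2, 0.8])
        np.testing.assert_array_equal(di_concat_posteriors([p]), p)

    def test_inconsistent_classes_raise(self):
        with pytest.raises(ValueError):
            di_concat_posteriors([np.array([0.5, 0.5]), np.array([1 / 3] * 3)])

    def test_invalid_posterior_raises(self):
        with pytest.raises(ValueError):
            di_concat_posteriors([np.array([0.9, 0.3])])


class TestTrainDIMLP:
    def test_one_hot_copy_task_converges(self):
        eye = np.eye(4)
        z = np.concatenate([eye, eye], axis=1)[np.repeat(np.arange(4), 8)]
        y = np.repeat(np.arange(4), 8)
        res = train_di_mlp([(z, y)], TrainingConfig(hidden_sizes=(8,), seed=0))
        assert res.converged

    def test_learns_to_weight_reliable_modality(self, rng):
        # modality 1 one-hot correct, modality 2 random noise posteriors
        k, n = 4, 80
        y = rng.integers(0, k, size=n)
        reliable = np.eye(k)[y]
        junk = rng.dirichlet(np.ones(k), size=n)
        z = np.concatenate([reliable, junk], axis=1)
        res = train_di_mlp([(z, y)], TrainingConfig(hidden_sizes=(8,), seed=1))
        acc = np.mean(decide(mlp_forward(z, res.model)) == y)
        junk_acc = np.mean(decide(junk) == y)
        assert acc > max(junk_acc, 0.9)


class TestEstimateConfusion:
    def test_perfect_classifier_unsmoothed_identity(self):
        y = np.repeat(np.arange(3), 4)
        cm = estimate_confusion(y, y, 3, smoothing=0.0)
        np.testing.assert_array_equal(cm.matrix, np.eye(3))

    def test_smoothing_positivity_and_column_sums(self, rng):
        y = rng.integers(0, 4, size=50)
        dec = rng.integers(0, 4, size=50)
        cm = estimate_confusion(dec, y, 4, smoothing=1.0)
        assert np.all(cm.matrix > 0)
        np.testing.assert_allclose(cm.matrix.sum(axis=0), np.ones(4), atol=1e-9)

    def test_random_decisions_approach_uniform(self, rng):
        n = 40_000
        k = 4
        y = rng.integers(0, k, size=n)
        dec = rng.integers(0, k, size=n)
        cm = estimate_confusion(dec, y, k, smoothing=0.0)
        se = np.sqrt((1 / k) * (1 - 1 / k) / (n / k))
        assert np.all(np.abs(cm.matrix - 1 / k) < 3 * se)

    def test_absent_class_raises(self):
        with pytest.raises(ValueError):
            estimate_confusion(np.array([0, 1]), np.array([0, 1]), 3)


class TestDIMapPosterior:
    def test_identity_confusions_certain_evidence(self):
        confs = [
            ConfusionModel(j, np.eye(3) * 0.99 + 0.005, 0.0) for j in (1, 2)
        ]
        for m in confs:
            m.matrix /= m.matrix.sum(axis=0)
        post = di_map_posterior(np.array([2, 2]), confs)
        assert decide(post) == 2
        assert post[2] > 0.99

    def test_two_class_product_arithmetic(self):
        # both confusions: correct 0.9, wrong 0.1 -> posterior 0.81/(0.81+0.01)
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        confs = [ConfusionModel(1, m, 0.0), ConfusionModel(2, m, 0.0)]
        post = di_map_posterior(np.array([0, 0]), confs)
        np.testing.assert_allclose(post, [0.81 / 0.82, 0.01 / 0.82])

    def test_exhaustive_enumeration_oracle(self, rng):
        # K=3, J=2: compare every decision pair against the product formula
        k = 3
        confs = []
        for j in (1, 2):
            m = rng.dirichlet(np.ones(k) * 2, size=k).T  # columns sum to 1
            confs.append(ConfusionModel(j, m, 0.0))
        priors = np.array([0.5, 0.25, 0.25])
        for z in itertools.product(range(k), repeat=2):
            post = di_map_posterior(np.array(z), confs, priors)
            raw = np.array(
                [
                    confs[0].matrix[z[0], kk] * confs[1].matrix[z[1], kk] * priors[kk]
                    for kk in range(k)
                ]
            )
            np.testing.assert_allclose(post, raw / raw.sum(), atol=1e-12)

    def test_joint_likelihood_normalizes_over_all_decisions(self, rng):
        # sum over all K^J decision vectors of P(Z | class) = 1 for each class
        for k, j in [(3, 2), (2, 3), (4, 2)]:
            confs = [
                ConfusionModel(jj, rng.dirichlet(np.ones(k), size=k).T, 0.0)
                for jj in range(j)
            ]
            for kk in range(k):
                total = sum(
                    di_map_likelihood(np.array(z), confs)[0, kk]
                    for z in itertools.product(range(k), repeat=j)
                )
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_likelihood_raises(self):
        m = np.array([[1.0, 1.0], [0.0, 0.0]])  # decision 1 never produced
        confs = [ConfusionModel(1, m, 0.0), ConfusionModel(2, m, 0.0)]
        with pytest.raises(ValueError, match="smoothing"):
            di_map_posterior(np.array([1, 1]), confs)

    def test_single_modality_reproduces_unimodal_decision(self, rng):
        # J = 1 with a diagonally dominant confusion: fused decision = input
        k = 5
        m = np.full((k, k), 0.05)
        np.fill_diagonal(m, 0.8)
        m /= m.sum(axis=0)
        conf = ConfusionModel(1, m, 0.0)
        for y in range(k):
            assert decide(di_map_posterior(np.array([y]), [conf])) == y
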