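"""GMM vocabulary, Fisher-vector and bag-of-words encodings, normalization."""

import numpy as np
import pytest

from oracles import fisher_vector_numerical, random_gmm_instance
from tumorcbir import (
    GmmModel,
    PatchSet,
    build_signature,
    encode_bow,
    encode_fv,
    fit_gmm,
    normalize_signature,
    posterior,
    posteriors,
)


class TestGmmFit:
    def test_recovers_two_well_separated_components(self, rng):
        n = 5000
        X = np.concatenate(
            [rng.normal(-5, 1, n // 2), rng.normal(5, 1, n // 2)]
        ).reshape(-1, 1)
        model = fit_gmm(X, K=2, seed=0)
        means = np.sort(model.means.ravel())
        assert abs(means[0] + 5) < 0.2 and abs(means[1] - 5) < 0.2
        assert np.allclose(np.sort(model.weights), [0.5, 0.5], atol=0.05)

    def test_single_component_is_sample_moments(self, rng):
        X = rng.normal(3, 2, size=(400, 2))
        model = fit_gmm(X, K=1, seed=0)
        assert np.allclose(model.means[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(model.variances[0], X.var(axis=0), rtol=1e-4)

    def test_fixed_seed_reproduces_model(self, rng):
        X = rng.normal(size=(300, 3))
        m1, m2 = fit_gmm(X, K=4, seed=9), fit_gmm(X, K=4, seed=9)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.weights, m2.weights)

    def test_more_components_than_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gmm(rng.normal(size=(5, 2)), K=10, seed=0)


class TestPosterior:
    def test_single_component_posterior_is_one(self):
        model = GmmModel(weights=[1.0], means=[[0.0]], variances=[[1.0]])
        assert posterior(model, np.array([3.0])) == pytest.approx(1.0)

    def test_descriptor_at_far_component_mean(self):
        model = GmmModel(
            weights=[0.5, 0.5], means=[[0.0], [50.0]], variances=[[1.0], [1.0]]
        )
        gamma = posterior(model, np.array([0.0]))
        assert gamma[0] > 0.99

    def test_rows_sum_to_one_even_in_far_tails(self, rng):
        weights, means, variances, _ = random_gmm_instance(rng, 3, 2, 1)
        model = GmmModel(weights=weights, means=means, variances=variances)
        X = rng.normal(0, 100, size=(50, 2))  # far tails: underflow territory
        gamma = posteriors(model, X)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
        assert (gamma >= 0).all()


class TestFisherVector:
    def test_zero_gradient_at_maximum_likelihood(self, rng):
        # K=1: the FV vanishes when the model equals the sample moments
        x = rng.normal(2, 3, size=(50, 1))
        model = GmmModel(
            weights=[1.0], means=[[x.mean()]], variances=[[x.var()]]
        )
        fv = encode_fv(model, PatchSet(descriptors=x))
        assert np.allclose(fv.values, 0, atol=1e-12)

    def test_matches_numerical_gradient_oracle(self, rng):
        for _ in range(5):
            K, d, T = rng.integers(1, 4), rng.integers(1, 3), rng.integers(2, 21)
            weights, means, variances, X = random_gmm_instance(rng, K, d, T)
            model = GmmModel(weights=weights, means=means, variances=variances)
            got = encode_fv(model, PatchSet(descriptors=X)).values
            want = fisher_vector_numerical(X, weights, means.copy(), variances)
            assert np.abs(got - want).max() <= 1e-4 * max(np.abs(want).max(), 1e-12)

    def test_duplicating_patches_leaves_fv_unchanged(self, rng):
        weights, means, variances, X = random_gmm_instance(rng, 2, 2, 10)
        model = GmmModel(weights=weights, means=means, variances=variances)
        fv1 = encode_fv(model, PatchSet(descriptors=X)).values
        fv2 = encode_fv(model, PatchSet(descriptors=np.vstack([X, X]))).values
        assert np.allclose(fv1, fv2, atol=1e-12)

    def test_empty_patch_set_gives_zero_vector_with_warning(self):
        model = GmmModel(weights=[1.0], means=[[0.0, 0.0]], variances=[[1.0, 1.0]])
        with pytest.warns(UserWarning, match="empty"):
            fv = encode_fv(model, PatchSet(descriptors=np.empty((0, 2))))
        assert fv.values.shape == (4,) and (fv.values == 0).all()


class TestBow:
    def test_single_centroid_collects_everything(self, rng):
        hist = encode_bow(
            np.zeros((1, 3)), PatchSet(descriptors=rng.normal(size=(17, 3)))
        )
        assert hist.counts.tolist() == [17.0]

    def test_descriptors_at_centroids_count_multiplicities(self):
        vocab = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.array([vocab[0], vocab[1], vocab[1], vocab[2], vocab[2], vocab[2]])
        hist = encode_bow(vocab, PatchSet(descriptors=X))
        assert hist.counts.tolist() == [1.0, 2.0, 3.0]

    def test_matches_exhaustive_nearest_centroid(self, rng):
        vocab = rng.normal(size=(6, 4))
        X = rng.normal(size=(40, 4))
        hist = encode_bow(vocab, PatchSet(descriptors=X))
        counts = np.zeros(6)
        for x in X:
            counts[np.argmin([((x - c) ** 2).sum() for c in vocab])] += 1
        assert np.array_equal(hist.counts, counts)
        assert hist.counts.sum() == 40

    def test_distance_tie_goes_to_lowest_index(self):
        vocab = np.array([[1.0], [-1.0]])
        hist = encode_bow(vocab, PatchSet(descriptors=np.array([[0.0]])))
        assert hist.counts.tolist() == [1.0, 0.0]


class TestNormalization:
    def test_power_step_arithmetic(self):
        v = np.array([4.0, -0.25])
        powered = np.sign(v) * np.abs(v) ** 0.5
        assert powered[0] == pytest.approx(2.0)
        assert powered[1] == pytest.approx(-0.5)
        out = normalize_signature(v, 0.5)
        assert np.allclose(out, powered / np.linalg.norm(powered))

    def test_output_is_unit_norm(self, rng):
        for _ in range(5):
            out = normalize_signature(rng.normal(size=20), 0.5)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_maps_to_itself(self):
        assert (normalize_signature(np.zeros(4), 0.5) == 0).all()


class TestBuildSignature:
    def test_signature_length_and_unit_norm(self, small_cohort, small_config):
        from tumorcbir import fit_feature_models

        models = fit_feature_models(small_cohort.cases[:8], small_config)
        sig = build_signature(
            small_cohort.cases[0], small_config, models.pca, models.vocabulary
        )
        d = models.pca.d
        assert sig.values.shape == (2 * d * small_config.K * small_config.N,)
        assert np.linalg.norm(sig.values) == pytest.approx(1.0)

    def test_identical_cases_identical_signatures(self, small_cohort, small_config):
        from tumorcbir import fit_feature_models

        models = fit_feature_models(small_cohort.cases[:8], small_config)
        s1 = build_signature(
            small_cohort.cases[3], small_config, models.pca, models.vocabulary
        )
        s2 = build_signature(
            small_cohort.cases[3], small_config, models.pca, models.vocabulary
        )
        assert np.array_equal(s1.values, s2.values)

    def test_bow_signature_length_is_K_times_N(self, small_cohort, small_config):
        from tumorcbir import fit_feature_models

        cfg = small_config.replace(encoder="bow")
        models = fit_feature_models(small_cohort.cases[:8], cfg)
        sig = build_signature(small_cohort.cases[0], cfg, models.pca, models.vocabulary)
        assert sig.values.shape == (cfg.K * cfg.N,)
        assert np.linalg.norm(sig.values) == pytest.approx(1.0)
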