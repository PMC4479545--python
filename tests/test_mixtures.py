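"""The Gaussian-mixture engine: EM, BIC, model selection, classification."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from delimix.mixtures import (
    FAMILIES,
    MixtureFit,
    bic,
    classify,
    cov_param_count,
    em_fit,
    model_select,
    select_best,
)


def blobs(rng, centers, n_per=40, sd=1.0):
    return np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])


class TestEmFit:
    def test_separated_point_masses(self):
        X = np.vstack([np.zeros((50, 2)), np.full((50, 2), 100.0)])
        fit = em_fit(X, 2, "VVV", seed=0)
        means = fit.means[np.argsort(fit.means[:, 0])]
        np.testing.assert_allclose(means, [[0, 0], [100, 100]], atol=1e-6)
        part = classify(fit, X)
        assert part.posterior.max(axis=1).min() >= 1 - 1e-10

    def test_k1_matches_closed_form_mvn_loglik(self, rng):
        X = rng.normal(size=(60, 3))
        fit = em_fit(X, 1, "VVV", seed=0)
        mle = multivariate_normal.logpdf(X, X.mean(0), np.cov(X.T, bias=True)).sum()
        assert abs(fit.loglik - mle) < 1e-8

    def test_k1_all_families_same_loglik_for_isotropic_equivalents(self, rng):
        # spherical data: at K=1 each family fits its own constrained MLE;
        # VVV/EEE coincide, as do VII/EII and VVI/EEI
        X = rng.normal(size=(50, 2))
        logliks = {fam: em_fit(X, 1, fam, seed=0).loglik for fam in FAMILIES}
        assert abs(logliks["VVV"] - logliks["EEE"]) < 1e-10
        assert abs(logliks["VII"] - logliks["EII"]) < 1e-10
        assert abs(logliks["VVI"] - logliks["EEI"]) < 1e-10

    @pytest.mark.parametrize("family", FAMILIES)
    def test_loglik_sequence_monotone(self, family):
        rng = np.random.default_rng(99)
        for trial in range(50):
            X = rng.normal(size=(30, 2)) * rng.uniform(0.5, 2)
            fit = em_fit(X, 3, family, seed=trial)
            assert np.all(np.diff(fit.loglik_path) >= -1e-7)

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            em_fit(rng.normal(size=(5, 2)), 6, "EII", seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 2))
        f1 = em_fit(X, 3, "VVI", seed=7)
        f2 = em_fit(X, 3, "VVI", seed=7)
        np.testing.assert_array_equal(f1.means, f2.means)
        assert f1.loglik == f2.loglik

    def test_loglik_agrees_with_sklearn_scoring_of_same_params(self, rng):
        # independent check of the likelihood computation: hand our fitted
        # parameters to sklearn and compare total log-likelihood
        X = blobs(rng, [(0, 0), (6, 6)])
        fit = em_fit(X, 2, "VVV", seed=1)
        gm = GaussianMixture(n_components=2, covariance_type="full")
        gm.weights_ = fit.weights
        gm.means_ = fit.means
        gm.precisions_cholesky_ = np.stack([
            np.linalg.inv(np.linalg.cholesky(c)).T for c in fit.covariances
        ])
        assert abs(gm.score(X) * len(X) - fit.loglik) < 1e-6


class TestBic:
    def test_hand_formula_k1_eii_d1(self):
        X = np.array([[0.0], [1.0], [2.0]])
        fit = em_fit(X, 1, "EII", seed=0)
        var = np.mean((X - 1.0) ** 2)
        loglik = sum(
            -0.5 * (np.log(2 * np.pi * var) + (x - 1.0) ** 2 / var) for x in X[:, 0]
        )
        assert abs(fit.loglik - loglik) < 1e-10
        # n_params = (K-1) + K*d + 1 = 2
        assert abs(fit.bic - (2 * loglik - 2 * np.log(3))) < 1e-10

    def test_extra_component_never_lowers_loglik(self, rng):
        X = blobs(rng, [(0, 0), (4, 4)], n_per=30)
        best = {
            K: max(em_fit(X, K, "VVV", seed=s).loglik for s in range(5))
            for K in (1, 2, 3)
        }
        assert best[2] >= best[1] - 1e-6
        assert best[3] >= best[2] - 1e-6

    def test_n_equal_one_has_zero_penalty(self):
        fit = MixtureFit(
            family="EII", K=1, weights=np.ones(1), means=np.zeros((1, 1)),
            covariances=np.ones((1, 1, 1)), loglik=-3.5, n_iter=1,
            converged=True, n=1,
        )
        assert bic(fit, 1) == -7.0

    def test_param_counts_increase_with_dimension(self):
        for fam in FAMILIES:
            counts = [cov_param_count(fam, 3, d) for d in (1, 2, 5)]
            assert counts == sorted(counts)
            assert counts[0] > 0


class TestModelSelect:
    def test_three_separated_blobs_select_k3(self, rng):
        X = blobs(rng, [(0, 0), (10, 0), (0, 10)], n_per=40)
        fit, table = model_select(X, K_max=6, restarts=4, seed=2)
        assert fit.K == 3
        assert set(table.columns) == {"K", "family", "bic", "converged"}
        assert len(table) == 6 * 6

    def test_single_cloud_selects_k1(self):
        X = np.random.default_rng(5).normal(size=(200, 2))
        fit, _ = model_select(X, K_max=4, restarts=3, seed=5, max_iter=300)
        assert fit.K == 1

    def test_bic_tie_goes_to_smaller_k_then_fewer_params(self):
        def dummy(K, family, bic_value):
            f = MixtureFit(
                family=family, K=K, weights=np.ones(K) / K, means=np.zeros((K, 2)),
                covariances=np.stack([np.eye(2)] * K), loglik=0.0, n_iter=1,
                converged=True, n=10,
            )
            f.bic = bic_value
            return f

        assert select_best([dummy(3, "EII", -50.0), dummy(2, "VVV", -50.0)]).K == 2
        assert select_best([dummy(2, "VVV", -50.0), dummy(2, "EII", -50.0)]).family == "EII"
        assert select_best([dummy(2, "EII", -50.0), dummy(1, "EII", -60.0)]).K == 2


class TestClassify:
    def test_separated_blobs_have_negligible_uncertainty(self, rng):
        X = blobs(rng, [(0, 0), (20, 20)])
        fit = em_fit(X, 2, "EII", seed=0)
        part = classify(fit, X)
        assert part.uncertainty.max() < 1e-6

    def test_equidistant_point_has_half_uncertainty(self):
        fit = MixtureFit(
            family="EII", K=2, weights=np.array([0.5, 0.5]),
            means=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            covariances=np.stack([np.eye(2)] * 2), loglik=0.0, n_iter=1,
            converged=True, n=2,
        )
        part = classify(fit, np.array([[0.0, 0.0]]))
        assert abs(part.uncertainty[0] - 0.5) < 1e-12

    def test_labels_renumbered_by_descending_size(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(8, 0.5, (50, 2))])
        fit = em_fit(X, 2, "EII", seed=0)
        part = classify(fit, X)
        sizes = np.bincount(part.labels)[1:]
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_mean_uncertainty_grows_as_clusters_approach(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(60, 2))
        mean_unc = []
        for delta in (8, 4, 2, 1):
            X = base.copy()
            X[30:, 0] += delta
            fit = em_fit(X, 2, "EEI", seed=1)
            mean_unc.append(classify(fit, X).uncertainty.mean())
        assert mean_unc == sorted(mean_unc)

    def test_posterior_rows_on_simplex_and_uncertainty_bounded(self, rng):
        X = rng.normal(size=(50, 2))
        for K in (2, 3, 4):
            fit = em_fit(X, K, "VVI", seed=3)
            part = classify(fit, X)
            np.testing.assert_allclose(part.posterior.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(part.uncertainty <= 1 - 1 / K + 1e-9)
            assert np.all(part.uncertainty >= -1e-12)

    def test_label_permutation_invariance(self, rng):
        # unequal blob sizes so the size-based renumbering has no ties
        X = np.vstack([
            rng.normal((0, 0), 1, (15, 2)),
            rng.normal((6, 0), 1, (20, 2)),
            rng.normal((0, 6), 1, (25, 2)),
        ])
        fit = em_fit(X, 3, "VVV", seed=4)
        perm = [2, 0, 1]
        permuted = MixtureFit(
            family=fit.family, K=fit.K, weights=fit.weights[perm],
            means=fit.means[perm], covariances=fit.covariances[perm],
            loglik=fit.loglik, n_iter=fit.n_iter, converged=True, n=fit.n,
        )
        permuted.bic = bic(permuted, fit.n)
        assert permuted.bic == fit.bic
        p1, p2 = classify(fit, X), classify(permuted, X)
        np.testing.assert_allclose(p1.uncertainty, p2.uncertainty, atol=1e-12)
        np.testing.assert_array_equal(p1.labels, p2.labels)
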