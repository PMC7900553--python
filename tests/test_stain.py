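import itertools

import numpy as np
import pytest

from histomut.stain import (ColorMixtureEM, NotSPDError, StainGMM,
                            StainNormalizer, fit_gmm_em, gaussian_pdf,
                            log_likelihood, match_components, mixture_density,
                            normalize_colors, responsibilities)
from histomut.synthetic import default_color_model, generate_pixel_mixture

INV_2PI_32 = (2 * np.pi) ** -1.5


def _permute(model, perm):
    return StainGMM(model.weights[perm], model.means[perm],
                    model.covariances[perm])


def _best_permutation_rms(est_means, true_means):
    best = np.inf
    for perm in itertools.permutations(range(len(true_means))):
        rms = np.sqrt(((est_means[list(perm)] - true_means) ** 2).mean())
        best = min(best, rms)
    return best


class TestGaussianPdf:
    def test_closed_form_at_mean_identity_covariance(self):
        v = np.array([0.2, 0.5, 0.8])
        assert gaussian_pdf(v, v, np.eye(3)) == pytest.approx(
            INV_2PI_32, abs=1e-9)

    def test_determinant_scaling(self):
        v = np.zeros(3)
        assert gaussian_pdf(v, v, 4 * np.eye(3)) == pytest.approx(
            INV_2PI_32 / 8, abs=1e-9)

    def test_integrates_to_one_on_grid(self):
        # numerical integration oracle over [-5, 5]^3
        step = 0.25
        axis = np.arange(-5, 5 + step / 2, step)
        grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"),
                        axis=-1).reshape(-1, 3)
        total = gaussian_pdf(grid, np.zeros(3), np.eye(3)).sum() * step ** 3
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_non_spd_covariance_names_smallest_eigenvalue(self):
        C = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(NotSPDError, match="-5"):
            gaussian_pdf(np.zeros(3), np.zeros(3), C)


class TestMixtureDensity:
    def test_single_component_equals_gaussian(self):
        m = StainGMM(np.array([1.0]), np.array([[0.5, 0.5, 0.5]]),
                     np.array([np.eye(3) * 0.01]))
        x = np.array([0.4, 0.5, 0.6])
        assert mixture_density(x, m) == pytest.approx(
            gaussian_pdf(x, m.means[0], m.covariances[0]), rel=1e-12)

    def test_identical_components_convexity(self):
        mean, cov = np.array([0.3, 0.3, 0.3]), np.eye(3) * 0.02
        m = StainGMM(np.array([0.5, 0.5]), np.stack([mean, mean]),
                     np.stack([cov, cov]))
        x = np.array([0.25, 0.35, 0.3])
        assert mixture_density(x, m) == pytest.approx(
            gaussian_pdf(x, mean, cov), rel=1e-12)

    def test_matches_term_by_term_summation(self, color_model):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(10, 3))
        oracle = sum(
            w * gaussian_pdf(X, v, c) for w, v, c in
            zip(color_model.weights, color_model.means,
                color_model.covariances))
        np.testing.assert_allclose(mixture_density(X, color_model), oracle,
                                   rtol=1e-10)


class TestResponsibilities:
    def test_identical_components_return_priors(self):
        mean, cov = np.zeros(3), np.eye(3)
        for w in ([0.5, 0.5], [0.9, 0.1]):
            m = StainGMM(np.array(w), np.stack([mean, mean]),
                         np.stack([cov, cov]))
            np.testing.assert_allclose(
                responsibilities(np.array([0.1, 0.0, -0.2]), m), w,
                atol=1e-12)

    def test_matches_direct_formula(self, color_model):
        x = color_model.means[0]
        num = np.array([
            w * gaussian_pdf(x, v, c) for w, v, c in
            zip(color_model.weights, color_model.means,
                color_model.covariances)])
        np.testing.assert_allclose(responsibilities(x, color_model),
                                   num / num.sum(), rtol=1e-10)

    def test_rows_sum_to_one(self, color_model):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(200, 3))
        r = responsibilities(X, color_model)
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)

    def test_extreme_outlier_falls_back_to_nearest_mean(self, color_model,
                                                        caplog):
        x = np.array([1e200, 1e200, 1e200])  # all densities underflow
        with caplog.at_level("WARNING", logger="histomut"):
            r = responsibilities(x, color_model)
        assert "hard-assigning" in caplog.text
        assert r.sum() == pytest.approx(1.0)
        assert set(np.unique(r)) <= {0.0, 1.0}


class TestLogLikelihood:
    def test_single_pixel_closed_form(self):
        v = np.array([0.1, 0.2, 0.3])
        m = StainGMM(np.array([1.0]), v[None], np.eye(3)[None])
        assert log_likelihood(v[None], m) == pytest.approx(
            np.log(INV_2PI_32), abs=1e-9)

    def test_additivity_under_duplication(self, color_model):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, size=(50, 3))
        ll = log_likelihood(X, color_model)
        ll2 = log_likelihood(np.vstack([X, X]), color_model)
        assert ll2 == pytest.approx(2 * ll, abs=1e-9)

    def test_matches_naive_per_point_summation(self, color_model):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, size=(30, 3))
        naive = sum(np.log(mixture_density(x, color_model)) for x in X)
        assert log_likelihood(X, color_model) == pytest.approx(naive,
                                                               abs=1e-9)


class TestEMFit:
    def test_single_component_closed_form_mle(self):
        rng = np.random.default_rng(4)
        X = rng.normal([0.4, 0.5, 0.6], 0.05, size=(500, 3))
        res = fit_gmm_em(X, n_components=1, seed=0)
        np.testing.assert_allclose(res.model.weights, [1.0], atol=1e-12)
        np.testing.assert_allclose(res.model.means[0], X.mean(0), atol=1e-8)
        biased_cov = np.cov(X.T, ddof=0)
        np.testing.assert_allclose(res.model.covariances[0], biased_cov,
                                   atol=1e-6)

    def test_parameter_recovery_well_separated(self, color_model):
        X, _ = generate_pixel_mixture(color_model, 50_000, seed=123)
        res = fit_gmm_em(X, n_components=3, seed=0)
        assert _best_permutation_rms(res.model.means,
                                     color_model.means) < 0.02
        w = np.sort(res.model.weights)
        np.testing.assert_allclose(w, np.sort(color_model.weights),
                                   atol=0.03)

    def test_log_likelihood_trace_non_decreasing(self, color_model):
        X, _ = generate_pixel_mixture(color_model, 5_000, seed=77)
        res = fit_gmm_em(X, n_components=3, seed=0)
        tr = res.log_likelihood_trace
        assert res.iterations >= 1
        assert np.all(np.diff(tr) >= -1e-9 * np.maximum(np.abs(tr[:-1]), 1))

    def test_too_few_pixels_is_error(self):
        with pytest.raises(ValueError, match="at least 30"):
            fit_gmm_em(np.zeros((10, 3)), n_components=3)

    def test_weights_sum_to_one_and_covariances_floored(self, color_model):
        X, _ = generate_pixel_mixture(color_model, 3_000, seed=5)
        res = fit_gmm_em(X, n_components=3, seed=1)
        assert res.model.weights.sum() == pytest.approx(1.0, abs=1e-12)
        for C in res.model.covariances:
            assert np.linalg.eigvalsh(C)[0] >= 1e-6 * (1 - 1e-9)

    def test_agrees_with_reference_em_implementation(self, color_model):
        # independent oracle: sklearn's GaussianMixture on the same pixels
        from sklearn.mixture import GaussianMixture
        X, _ = generate_pixel_mixture(color_model, 20_000, seed=42)
        ours = ColorMixtureEM(n_components=3, random_state=0).fit(X)
        ref = GaussianMixture(3, covariance_type="full", random_state=0,
                              n_init=3).fit(X)
        ours_sorted = ours.means_[np.argsort(ours.means_[:, 0])]
        ref_sorted = ref.means_[np.argsort(ref.means_[:, 0])]
        np.testing.assert_allclose(ours_sorted, ref_sorted, atol=0.01)


class TestMatchComponents:
    def test_identity_when_source_equals_reference(self, color_model):
        np.testing.assert_array_equal(
            match_components(color_model, color_model), [0, 1, 2])

    def test_reversed_reference_gives_reversing_permutation(self, color_model):
        rev = _permute(color_model, [2, 1, 0])
        np.testing.assert_array_equal(match_components(color_model, rev),
                                      [2, 1, 0])

    def test_matches_min_luminance_distance_assignment(self):
        luma = np.array([0.299, 0.587, 0.114])
        rng = np.random.default_rng(6)
        for _ in range(10):
            means_s = rng.uniform(0, 1, size=(3, 3))
            means_r = rng.uniform(0, 1, size=(3, 3))
            covs = np.stack([np.eye(3) * 0.01] * 3)
            w = np.full(3, 1 / 3)
            src = StainGMM(w, means_s, covs)
            ref = StainGMM(w, means_r, covs)
            perm = match_components(src, ref)
            # exhaustive assignment oracle over all 6 permutations:
            # luminance-rank pairing must achieve the minimum total
            # luminance distance (ties may admit several optimal pairings)
            ls, lr = means_s @ luma, means_r @ luma
            cost = lambda p: sum(abs(ls[i] - lr[p[i]]) for i in range(3))
            best_cost = min(cost(p)
                            for p in itertools.permutations(range(3)))
            assert cost(tuple(perm)) == pytest.approx(best_cost, abs=1e-12)


class TestNormalizeColors:
    def test_identity_transform(self, color_model):
        X, _ = generate_pixel_mixture(color_model, 4_096, seed=3)
        img = np.round(X * 255).astype(np.uint8).reshape(64, 64, 3)
        out = normalize_colors(img, color_model, color_model)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 2

    def test_idempotent_once_source_equals_reference(self, color_model):
        X, _ = generate_pixel_mixture(color_model, 4_096, seed=3)
        img = np.round(X * 255).astype(np.uint8).reshape(64, 64, 3)
        once = normalize_colors(img, color_model, color_model)
        twice = normalize_colors(once, color_model, color_model)
        assert np.abs(twice.astype(int) - once.astype(int)).max() <= 1

    def test_pure_translation(self):
        delta = np.array([0.1, -0.05, 0.08])
        cov = np.eye(3) * 4e-4
        src = StainGMM(np.array([1.0]), np.array([[0.4, 0.5, 0.5]]),
                       cov[None])
        ref = StainGMM(np.array([1.0]), src.means + delta, cov[None])
        rng = np.random.default_rng(0)
        img = rng.normal(src.means[0], 0.02, size=(32, 32, 3)).clip(0, 1)
        out = normalize_colors(img, src, ref)
        np.testing.assert_allclose(out - img, np.broadcast_to(delta,
                                                              img.shape),
                                   atol=1e-9)

    def test_class_means_transferred_to_reference(self, color_model):
        reference = StainGMM(
            color_model.weights.copy(),
            np.array([[0.20, 0.15, 0.45],
                      [0.90, 0.60, 0.75],
                      [0.95, 0.95, 0.95]]),
            color_model.covariances.copy(),
        )
        X, assign = generate_pixel_mixture(color_model, 30_000, seed=21)
        out = normalize_colors(X.reshape(-1, 1, 3), color_model,
                               reference).reshape(-1, 3)
        for c in range(3):
            np.testing.assert_allclose(out[assign == c].mean(axis=0),
                                       reference.means[c], atol=0.03)


class TestStainNormalizer:
    def test_estimator_fits_and_transforms(self, color_model):
        X, _ = generate_pixel_mixture(color_model, 6_400, seed=10)
        ref_img = np.round(X * 255).astype(np.uint8).reshape(80, 80, 3)
        Y, _ = generate_pixel_mixture(color_model, 6_400, seed=11)
        src_img = np.round(Y * 255).astype(np.uint8).reshape(80, 80, 3)
        norm = StainNormalizer(random_state=0).fit(ref_img)
        out = norm.transform(src_img)
        assert out.shape == src_img.shape
        assert out.dtype == np.uint8
        # same underlying mixture: transform is close to the identity
        assert np.abs(out.astype(int) - src_img.astype(int)).mean() < 10

    def test_sklearn_get_set_params(self):
        norm = StainNormalizer()
        assert norm.get_params()["n_components"] == 3
        norm.set_params(n_components=2)
        assert norm.n_components == 2
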