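"""Gaussian fitting, density thresholds and confidence-region geometry."""

import numpy as np
import pytest
from scipy import stats

from posturekit import (
    CalibrationPoseSet,
    calibrate,
    compute_threshold,
    confidence_offsets,
    fit_gaussian,
    gaussian_density,
    mahalanobis_sq,
)
from posturekit.errors import (
    CalibrationDataError,
    InvalidDataError,
    InvalidParameterError,
    NumericalDegeneracyError,
)

from conftest import brute_force_density, chi2_quantile_oracle, random_spd

OCTAHEDRON = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=float
)


class TestFitGaussian:
    def test_symmetric_cloud_has_zero_mean(self):
        mu, _, _ = fit_gaussian(OCTAHEDRON)
        np.testing.assert_allclose(mu, np.zeros(3), atol=1e-15)

    def test_unbiased_covariance_of_octahedron(self):
        # hand computation with N=6, divisor 5: each axis sums to 2, so 2/5
        _, sigma, _ = fit_gaussian(OCTAHEDRON)
        np.testing.assert_allclose(sigma, np.diag([0.4, 0.4, 0.4]), atol=1e-15)

    def test_monte_carlo_parameter_recovery(self, rng):
        mu_true = np.array([1.0, -2.0, 3.0])
        sigma_true = random_spd(rng)
        n = 10_000
        X = rng.multivariate_normal(mu_true, sigma_true, size=n)
        mu, sigma, ridged = fit_gaussian(X)
        se = np.sqrt(np.diag(sigma_true) / n)
        assert np.all(np.abs(mu - mu_true) < 3 * se)
        rel = np.linalg.norm(sigma - sigma_true) / np.linalg.norm(sigma_true)
        assert rel < 0.05
        assert not ridged

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_too_few_samples_rejected(self, n):
        with pytest.raises(CalibrationDataError):
            fit_gaussian(OCTAHEDRON[:n])

    def test_non_finite_samples_rejected(self):
        bad = OCTAHEDRON.copy()
        bad[2, 1] = np.nan
        with pytest.raises(InvalidDataError):
            fit_gaussian(bad)

    def test_constant_samples_get_ridge_not_failure(self):
        X = np.tile([1.0, 2.0, 3.0], (10, 1))
        mu, sigma, ridged = fit_gaussian(X)
        assert ridged
        assert np.all(np.linalg.eigvalsh(sigma) > 0)
        # and the regularized covariance still yields a usable threshold
        assert compute_threshold(mu, sigma, 0.95) > 0

    def test_rank_deficient_planar_cloud_is_regularized(self, rng):
        X = rng.normal(size=(50, 3))
        X[:, 2] = 2.0 * X[:, 0] - X[:, 1]  # exactly coplanar
        _, sigma, ridged = fit_gaussian(X)
        assert ridged
        assert np.all(np.linalg.eigvalsh(sigma) > 0)


class TestGaussianDensity:
    def test_standard_normal_at_mean(self):
        val = gaussian_density(np.zeros(3), np.zeros(3), np.eye(3))
        assert val == pytest.approx((2 * np.pi) ** -1.5, rel=1e-12)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.7])
    def test_isotropic_closed_form(self, d):
        x = np.array([d, 0.0, 0.0])
        val = gaussian_density(x, np.zeros(3), np.eye(3))
        assert val == pytest.approx((2 * np.pi) ** -1.5 * np.exp(-0.5 * d * d), rel=1e-12)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(25):
            mu = rng.normal(size=3)
            sigma = random_spd(rng)
            x = rng.normal(size=3)
            assert gaussian_density(x, mu, sigma) == pytest.approx(
                brute_force_density(x, mu, sigma), rel=1e-10
            )

    def test_maximal_at_mean(self, rng):
        mu = rng.normal(size=3)
        sigma = random_spd(rng)
        at_mean = gaussian_density(mu, mu, sigma)
        for _ in range(20):
            assert gaussian_density(mu + rng.normal(size=3), mu, sigma) <= at_mean

    def test_singular_covariance_raises(self):
        singular = np.diag([1.0, 1.0, 0.0])
        with pytest.raises(NumericalDegeneracyError):
            gaussian_density(np.zeros(3), np.zeros(3), singular)


class TestConfidenceOffsets:
    def test_unit_isotropic_offsets(self):
        # pick c so that the chi-squared quantile is exactly 1
        c = stats.chi2.cdf(1.0, 3)
        delta, eigvals, eigvecs = confidence_offsets(np.eye(3), c)
        np.testing.assert_allclose(np.linalg.norm(delta, axis=1), 1.0, rtol=1e-12)
        np.testing.assert_allclose(eigvecs @ eigvecs.T, np.eye(3), atol=1e-12)

    def test_eigenvalue_scaling(self):
        delta, _, _ = confidence_offsets(np.diag([4.0, 1.0, 1.0]), 0.95)
        lengths = np.sort(np.linalg.norm(delta, axis=1))
        assert lengths[2] == pytest.approx(2 * lengths[0], rel=1e-12)
        assert lengths[2] == pytest.approx(2 * lengths[1], rel=1e-12)

    def test_offsets_reach_the_quantile_surface(self, rng):
        """mu + delta_j must sit at Mahalanobis^2 = chi2_3(c), all three axes."""
        q95 = chi2_quantile_oracle(0.95)
        for _ in range(10):
            mu = rng.normal(size=3)
            sigma = random_spd(rng)
            delta, _, _ = confidence_offsets(sigma, 0.95)
            for j in range(3):
                d2 = mahalanobis_sq(mu + delta[j], mu, sigma)
                assert d2 == pytest.approx(q95, rel=1e-9)

    @pytest.mark.parametrize("c", [0.0, 1.0, -0.2, 1.5])
    def test_confidence_out_of_range(self, c):
        with pytest.raises(InvalidParameterError):
            confidence_offsets(np.eye(3), c)


class TestComputeThreshold:
    def test_closed_form_vs_construction(self, rng):
        """tau equals the density evaluated at any ellipsoid semi-axis endpoint."""
        for _ in range(20):
            mu = rng.normal(size=3)
            sigma = random_spd(rng)
            tau = compute_threshold(mu, sigma, 0.95)
            delta, _, _ = confidence_offsets(sigma, 0.95)
            for j in range(3):
                assert gaussian_density(mu + delta[j], mu, sigma) == pytest.approx(
                    tau, rel=1e-10
                )

    def test_unit_covariance_value(self):
        q = chi2_quantile_oracle(0.95)
        tau = compute_threshold(np.zeros(3), np.eye(3), 0.95)
        assert tau == pytest.approx((2 * np.pi) ** -1.5 * np.exp(-0.5 * q), rel=1e-10)

    def test_shrinking_region_limit(self, rng):
        """As c -> 0+ the threshold climbs to the density at the mean."""
        mu = rng.normal(size=3)
        sigma = random_spd(rng)
        at_mean = gaussian_density(mu, mu, sigma)
        taus = [compute_threshold(mu, sigma, c) for c in (0.5, 0.1, 1e-3, 1e-8)]
        assert np.all(np.diff(taus) > 0)
        assert taus[-1] == pytest.approx(at_mean, rel=1e-3)

    def test_coverage_matches_confidence(self, rng):
        """P(density >= tau) under the fitted Gaussian is c (binomial band)."""
        mu = np.array([2.0, -1.0, 0.5])
        sigma = random_spd(rng)
        tau = compute_threshold(mu, sigma, 0.95)
        n = 20_000
        X = rng.multivariate_normal(mu, sigma, size=n)
        frac = np.mean(gaussian_density(X, mu, sigma) >= tau)
        band = 5 * np.sqrt(0.95 * 0.05 / n)
        assert abs(frac - 0.95) < band

    def test_affine_consistency(self, rng):
        """Refitting on linearly mapped samples maps the acceptance set exactly."""
        X = rng.multivariate_normal([1.0, 0.0, -1.0], random_spd(rng), size=500)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        mu1, s1, _ = fit_gaussian(X)
        mu2, s2, _ = fit_gaussian(X @ A.T)
        q = chi2_quantile_oracle(0.95)
        pts = rng.multivariate_normal(mu1, 4 * s1, size=200)
        before = mahalanobis_sq(pts, mu1, s1)
        after = mahalanobis_sq(pts @ A.T, mu2, s2)
        np.testing.assert_allclose(after, before, rtol=1e-8)
        assert np.array_equal(before <= q, after <= q)


class TestCalibrate:
    def test_eight_pose_model_structure(self, default_model):
        assert len(default_model.regions) == 16
        assert set(default_model.sensors) == {"accelerometer", "magnetometer"}
        assert all(r.tau > 0 for r in default_model.regions.values())
        assert all(abs(r.c - 0.95) < 1e-15 for r in default_model.regions.values())

    def test_recovers_generating_gaussians(self, rng):
        mu_true = np.array([5.0, 1.0, -3.0])
        sigma_true = np.diag([0.5, 1.0, 2.0])
        n = 5000
        ps = CalibrationPoseSet(
            "standing_arms_down", "accelerometer",
            rng.multivariate_normal(mu_true, sigma_true, size=n),
        )
        model = calibrate([ps])
        region = model.regions[("accelerometer", "standing_arms_down")]
        se = np.sqrt(np.diag(sigma_true) / n)
        assert np.all(np.abs(region.mu - mu_true) < 3 * se)
        rel = np.linalg.norm(region.sigma - sigma_true) / np.linalg.norm(sigma_true)
        assert rel < 0.1

    def test_single_pose_single_sensor_degenerates_to_one_ellipsoid(self, rng):
        X = rng.normal(size=(100, 3))
        model = calibrate([CalibrationPoseSet("only", "accelerometer", X)])
        assert len(model.regions) == 1
        clf = model.classifier_for("accelerometer")
        assert clf.predict([X.mean(axis=0)])[0] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(CalibrationDataError):
            calibrate([])

    def test_mixed_units_rejected(self, rng):
        a = CalibrationPoseSet("p1", "accelerometer", rng.normal(size=(10, 3)), units="m/s^2")
        b = CalibrationPoseSet("p2", "accelerometer", rng.normal(size=(10, 3)), units="g")
        with pytest.raises(InvalidDataError):
            calibrate([a, b])
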