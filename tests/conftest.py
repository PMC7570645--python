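"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import gammainc

from posturekit import CalibrationModel, GaussianRegion, calibrate, simulate_calibration


def random_spd(rng, scale: float = 1.0) -> np.ndarray:
    """A random well-conditioned 3x3 SPD matrix."""
    A = rng.normal(size=(3, 3))
    return scale * (A @ A.T + 0.25 * np.eye(3))


def brute_force_density(x, mu, sigma) -> float:
    """Trivariate normal density built directly from inv/det primitives."""
    x = np.asarray(x, float)
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    diff = x - mu
    quad = diff @ np.linalg.inv(sigma) @ diff
    return (2 * np.pi) ** -1.5 * np.linalg.det(sigma) ** -0.5 * np.exp(-0.5 * quad)


def chi2_quantile_oracle(c: float, df: int = 3) -> float:
    """chi-squared quantile via bisection on the regularized incomplete gamma.

    Independent of scipy.stats.chi2.ppf: the chi2(df) CDF at x is
    P(df/2, x/2) and we root-find it directly.
    """
    return brentq(lambda x: gammainc(df / 2.0, x / 2.0) - c, 1e-12, 200.0, xtol=1e-13)


def random_model(rng, n_regions: int = 3, c: float = 0.95) -> CalibrationModel:
    """A calibration model with random Gaussian regions for oracle tests."""
    regions = {}
    for i in range(n_regions):
        region = GaussianRegion(
            pose_label=f"pose_{i}",
            sensor="accelerometer",
            mu=rng.uniform(-10, 10, size=3),
            sigma=random_spd(rng),
            c=c,
        )
        regions[("accelerometer", region.pose_label)] = region
    return CalibrationModel(regions=regions, c=c)


@pytest.fixture(scope="session")
def default_model() -> CalibrationModel:
    """A model calibrated on the simulator's default eight-pose protocol."""
    return calibrate(simulate_calibration(n_per_pose=200, seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
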