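"""Per-pose trivariate Gaussian calibration and confidence-region thresholds.

During calibration the wearer holds each of a small set of reference poses
while keeping a correct posture.  For every (sensor, pose) pair the recorded
3-axis samples are fitted to a trivariate Gaussian N(mu, Sigma).  A confidence
level ``c`` (default 0.95) defines an equiprobability ellipsoid

    (x - mu)^T Sigma^-1 (x - mu) = chi2_3(c)

whose surface density

    tau = (2 pi)^{-3/2} |Sigma|^{-1/2} exp(-chi2_3(c) / 2)

is the acceptance threshold: a later reading is compatible with the pose iff
its density under the fitted Gaussian is >= tau, equivalently iff its squared
Mahalanobis distance is <= the chi-squared quantile.  The ellipsoid semi-axes
are sqrt(chi2_3(c) * lambda_j) along the covariance eigenvectors v_j; the
density is identical at all six semi-axis endpoints, which is what makes a
single scalar threshold well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import chi2, multivariate_normal

from .data import (
    DEFAULT_UNITS,
    MIN_CALIBRATION_SAMPLES,
    SENSORS,
    CalibrationPoseSet,
)
from .errors import (
    CalibrationDataError,
    InvalidDataError,
    InvalidParameterError,
    NumericalDegeneracyError,
)

DEFAULT_CONFIDENCE = 0.95
_DIM = 3
_LOG_NORM = -0.5 * _DIM * np.log(2.0 * np.pi)


def _check_confidence(c: float) -> float:
    c = float(c)
    if not 0.0 < c < 1.0:
        raise InvalidParameterError(f"confidence must lie strictly in (0, 1), got {c}")
    return c


def chi2_quantile(c: float, df: int = _DIM) -> float:
    """Quantile of the chi-squared distribution, ``s = chi2_df(c)``."""
    return float(chi2.ppf(_check_confidence(c), df))


def fit_gaussian(samples, *, ridge: float = 1e-6, max_condition: float = 1e12):
    """Fit a trivariate Gaussian to (n, 3) samples.

    Returns ``(mu, sigma, ridged)`` where ``mu`` is the arithmetic mean,
    ``sigma`` the unbiased (N-1 divisor) sample covariance, symmetrized, and
    ``ridged`` records whether a diagonal ridge ``ridge * trace(sigma) / 3``
    was applied to repair a singular or ill-conditioned covariance.

    Raises
    ------
    CalibrationDataError
        Fewer than 4 samples.
    InvalidDataError
        Non-finite input or wrong shape.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.ndim != 2 or X.shape[1] != _DIM:
        raise InvalidDataError(f"samples must be (n, 3), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise InvalidDataError("samples contain non-finite values")
    n = X.shape[0]
    if n < MIN_CALIBRATION_SAMPLES:
        raise CalibrationDataError(
            f"need at least {MIN_CALIBRATION_SAMPLES} samples to fit a trivariate Gaussian, got {n}"
        )
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    sigma = 0.5 * (sigma + sigma.T)

    ridged = False
    eigvals = linalg.eigvalsh(sigma)
    cond = np.inf if eigvals[0] <= 0 else eigvals[-1] / eigvals[0]
    if eigvals[0] <= 0 or cond > max_condition:
        # scale-aware diagonal ridge; escalate if one application is not enough
        # (unit scale fallback when the covariance is exactly zero)
        base = ridge * (np.trace(sigma) / _DIM or 1.0)
        bump = base
        for _ in range(40):
            candidate = sigma + bump * np.eye(_DIM)
            ev = linalg.eigvalsh(candidate)
            if ev[0] > 0 and ev[-1] / ev[0] <= max_condition:
                sigma = candidate
                ridged = True
                break
            bump *= 10.0
        else:
            raise NumericalDegeneracyError("covariance could not be regularized to SPD")
    return mu, sigma, ridged


def gaussian_density(x, mu, sigma):
    """Trivariate normal density N(x; mu, sigma).

    ``x`` may be a single 3-vector or an (n, 3) array.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    try:
        rv = multivariate_normal(mean=mu, cov=sigma, allow_singular=False)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise NumericalDegeneracyError(f"covariance is not SPD: {exc}") from exc
    return rv.pdf(np.asarray(x, dtype=float))


def mahalanobis_sq(x, mu, sigma):
    """Squared Mahalanobis distance of ``x`` (3-vector or (n, 3)) from N(mu, sigma)."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    try:
        cho = linalg.cho_factor(np.asarray(sigma, dtype=float), lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(f"covariance is not SPD: {exc}") from exc
    diff = np.atleast_2d(x) - mu
    sol = linalg.cho_solve(cho, diff.T)
    d2 = np.einsum("ij,ji->i", diff, sol)
    return float(d2[0]) if x.ndim == 1 else d2


def confidence_offsets(sigma, c: float = DEFAULT_CONFIDENCE):
    """Semi-axis offset vectors of the confidence ellipsoid.

    Returns ``(delta, eigvals, eigvecs)``: ``delta`` is a (3, 3) array whose
    row j is the offset ``sqrt(chi2_3(c) * lambda_j) * v_j`` from the mean to
    the ellipsoid surface along principal axis j; ``eigvecs`` holds the
    orthonormal eigenvectors as columns (ascending eigenvalue order).
    Every point ``mu + delta[j]`` has squared Mahalanobis distance chi2_3(c).
    """
    q = chi2_quantile(c)
    sigma = np.asarray(sigma, dtype=float)
    eigvals, eigvecs = linalg.eigh(sigma)
    if eigvals[0] <= 0:
        raise NumericalDegeneracyError("covariance is not positive definite")
    delta = (np.sqrt(q * eigvals)[:, None] * eigvecs.T)
    return delta, eigvals, eigvecs


def compute_threshold(mu, sigma, c: float = DEFAULT_CONFIDENCE) -> float:
    """Density threshold tau delimiting the confidence region.

    Evaluates the closed form ``(2 pi)^{-3/2} |Sigma|^{-1/2} exp(-chi2_3(c)/2)``,
    which equals the density at any semi-axis endpoint ``mu + delta_j`` (``mu``
    is accepted for signature symmetry with :func:`gaussian_density`; the
    threshold does not depend on it).
    """
    q = chi2_quantile(c)
    sign, logdet = np.linalg.slogdet(np.asarray(sigma, dtype=float))
    if sign <= 0:
        raise NumericalDegeneracyError("covariance determinant is not positive")
    return float(np.exp(_LOG_NORM - 0.5 * logdet - 0.5 * q))


@dataclass
class GaussianRegion:
    """Fitted Gaussian and confidence-region threshold for one (sensor, pose)."""

    pose_label: str
    sensor: str
    mu: np.ndarray
    sigma: np.ndarray
    c: float
    tau: float = field(init=False)
    chi2_quantile: float = field(init=False)
    eigvals: np.ndarray = field(init=False)
    eigvecs: np.ndarray = field(init=False)
    delta: np.ndarray = field(init=False)
    ridged: bool = False

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != (_DIM,) or self.sigma.shape != (_DIM, _DIM):
            raise InvalidDataError("region requires a 3-vector mean and 3x3 covariance")
        if not np.allclose(self.sigma, self.sigma.T, rtol=0, atol=1e-8 * max(1.0, abs(self.sigma).max())):
            raise InvalidDataError("covariance must be symmetric")
        self.c = _check_confidence(self.c)
        self.chi2_quantile = chi2_quantile(self.c)
        self.delta, self.eigvals, self.eigvecs = confidence_offsets(self.sigma, self.c)
        self.tau = compute_threshold(self.mu, self.sigma, self.c)

    @classmethod
    def fit(cls, X, pose_label: str, sensor: str, c: float = DEFAULT_CONFIDENCE,
            *, ridge: float = 1e-6, max_condition: float = 1e12) -> "GaussianRegion":
        mu, sigma, ridged = fit_gaussian(X, ridge=ridge, max_condition=max_condition)
        return cls(pose_label=pose_label, sensor=sensor, mu=mu, sigma=sigma, c=c, ridged=ridged)

    def density(self, x):
        return gaussian_density(x, self.mu, self.sigma)

    def mahalanobis_sq(self, x):
        return mahalanobis_sq(x, self.mu, self.sigma)

    def contains(self, x):
        """Membership in the closed confidence region (boundary counts as inside)."""
        return self.mahalanobis_sq(x) <= self.chi2_quantile

    def to_dict(self) -> dict:
        return {
            "pose_label": self.pose_label,
            "sensor": self.sensor,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.ravel().tolist(),
            "c": self.c,
            "tau": self.tau,
            "ridged": self.ridged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianRegion":
        region = cls(
            pose_label=d["pose_label"],
            sensor=d["sensor"],
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float).reshape(_DIM, _DIM),
            c=float(d["c"]),
            ridged=bool(d.get("ridged", False)),
        )
        return region


@dataclass
class CalibrationModel:
    """Complete calibration: one :class:`GaussianRegion` per (sensor, pose)."""

    regions: dict  # (sensor, pose_label) -> GaussianRegion
    c: float = DEFAULT_CONFIDENCE
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self):
        self.c = _check_confidence(self.c)
        if not self.regions:
            raise CalibrationDataError("calibration model has no regions")
        for (sensor, pose), region in self.regions.items():
            if sensor not in SENSORS:
                raise InvalidDataError(f"unknown sensor {sensor!r}")
            if region.sensor != sensor or region.pose_label != pose:
                raise InvalidDataError("region key does not match region metadata")
            if abs(region.c - self.c) > 1e-12:
                raise InvalidDataError("all regions must share the model confidence level")

    @property
    def sensors(self) -> tuple:
        return tuple(s for s in SENSORS if any(k[0] == s for k in self.regions))

    def regions_for(self, sensor: str) -> list:
        if sensor not in SENSORS:
            raise InvalidParameterError(f"unknown sensor {sensor!r}")
        return [r for (s, _), r in sorted(self.regions.items()) if s == sensor]

    def classifier_for(self, sensor: str, combine: str = "any"):
        """A fitted :class:`~posturekit.estimator.GaussianRegionClassifier` for one sensor."""
        from .estimator import GaussianRegionClassifier

        regions = self.regions_for(sensor)
        if not regions:
            raise InvalidParameterError(f"model has no calibration regions for {sensor!r}")
        return GaussianRegionClassifier.from_regions(regions, combine=combine)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "posturekit-calibration-v1",
            "c": self.c,
            "units": dict(self.units),
            "regions": [r.to_dict() for _, r in sorted(self.regions.items())],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        regions = {}
        for rd in d["regions"]:
            region = GaussianRegion.from_dict(rd)
            regions[(region.sensor, region.pose_label)] = region
        return cls(regions=regions, c=float(d["c"]), units=dict(d["units"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate(pose_sets, c: float = DEFAULT_CONFIDENCE, *,
              ridge: float = 1e-6, max_condition: float = 1e12) -> CalibrationModel:
    """Fit a :class:`CalibrationModel` from labelled calibration pose sets.

    Parameters
    ----------
    pose_sets : iterable of CalibrationPoseSet
        Recorded calibration data; each set yields one Gaussian region.
    c : float
        Confidence level of the acceptance regions (default 0.95).
    """
    pose_sets = list(pose_sets)
    if not pose_sets:
        raise CalibrationDataError("no calibration pose sets supplied")
    c = _check_confidence(c)

    units: dict = {}
    regions: dict = {}
    for ps in pose_sets:
        if not isinstance(ps, CalibrationPoseSet):
            ps = CalibrationPoseSet(**ps) if isinstance(ps, dict) else ps
        known = units.setdefault(ps.sensor, ps.units)
        if ps.units != known:
            raise InvalidDataError(
                f"mixed units for {ps.sensor}: {known!r} vs {ps.units!r}"
            )
        key = (ps.sensor, ps.pose_label)
        if key in regions:
            raise InvalidDataError(f"duplicate pose set for {key}")
        regions[key] = GaussianRegion.fit(
            ps.X, ps.pose_label, ps.sensor, c, ridge=ridge, max_condition=max_condition
        )
    return CalibrationModel(regions=regions, c=c, units=units)
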