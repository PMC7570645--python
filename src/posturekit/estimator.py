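"""Scikit-learn style confidence-region classifier for a single sensor.

:class:`GaussianRegionClassifier` is the estimator at the core of the
package.  It plays the same role as ``sklearn.covariance.EllipticEnvelope``
— a Gaussian inlier/outlier test — but fits one ellipsoidal acceptance
region per calibration pose and accepts a reading that falls inside the
union of them (a reading compatible with *some* correctly-held reference
pose is a correct posture).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .calibration import DEFAULT_CONFIDENCE, GaussianRegion, chi2_quantile
from .data import Posture
from .errors import InvalidDataError, InvalidParameterError

_COMBINE_MODES = ("any", "all")


class GaussianRegionClassifier(OutlierMixin, BaseEstimator):
    """Posture classifier from per-pose Gaussian confidence regions.

    Parameters
    ----------
    confidence : float, default=0.95
        Coverage c of each acceptance ellipsoid; the squared-Mahalanobis
        acceptance bound is the chi-squared(3 df) quantile at c.
    combine : {"any", "all"}, default="any"
        How the per-pose regions are combined: ``"any"`` accepts a point
        inside at least one region (the operational reading — pose clusters
        are spatially disjoint); ``"all"`` requires membership in every
        region and is kept for comparison only.
    ridge : float, default=1e-6
        Relative diagonal ridge applied to singular/ill-conditioned sample
        covariances, as a fraction of the mean covariance eigenvalue.
    max_condition : float, default=1e12
        Condition-number bound above which the ridge kicks in.

    Attributes
    ----------
    regions_ : list of GaussianRegion
        One fitted region per calibration pose, ordered by pose label.
    chi2_quantile_ : float
        chi-squared(3) quantile at ``confidence``.
    n_features_in_ : int
        Always 3.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal([0, 0, 9.81], 0.05, size=(200, 3))
    >>> clf = GaussianRegionClassifier().fit(X)
    >>> clf.predict(X[:3])
    array([1, 1, 1])
    """

    def __init__(self, confidence: float = DEFAULT_CONFIDENCE, combine: str = "any",
                 ridge: float = 1e-6, max_condition: float = 1e12):
        self.confidence = confidence
        self.combine = combine
        self.ridge = ridge
        self.max_condition = max_condition

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        """Fit one Gaussian region per pose label in ``y``.

        Parameters
        ----------
        X : array-like of shape (n_samples, 3)
            Sensor readings recorded during calibration.
        y : array-like of pose labels, optional
            Which calibration pose each sample belongs to.  ``None`` fits a
            single region to all samples.
        """
        self._check_combine()
        X = check_array(X, ensure_min_samples=4)
        if X.shape[1] != 3:
            raise InvalidDataError(f"expected 3-axis readings, got {X.shape[1]} columns")
        if y is None:
            y = np.zeros(X.shape[0], dtype=object)
            y[:] = "pose"
        y = np.asarray(y, dtype=object)
        if y.shape != (X.shape[0],):
            raise InvalidDataError("y must hold one pose label per sample")
        self.regions_ = [
            GaussianRegion.fit(
                X[y == label], str(label), sensor="accelerometer",
                c=self.confidence, ridge=self.ridge, max_condition=self.max_condition,
            )
            for label in sorted(set(y.tolist()))
        ]
        self.chi2_quantile_ = chi2_quantile(self.confidence)
        self.n_features_in_ = 3
        return self

    @classmethod
    def from_regions(cls, regions, combine: str = "any") -> "GaussianRegionClassifier":
        """Build an already-fitted classifier from externally fitted regions."""
        regions = list(regions)
        if not regions:
            raise InvalidParameterError("at least one region is required")
        c = regions[0].c
        if any(abs(r.c - c) > 1e-12 for r in regions):
            raise InvalidDataError("regions disagree on the confidence level")
        clf = cls(confidence=c, combine=combine)
        clf._check_combine()
        clf.regions_ = regions
        clf.chi2_quantile_ = chi2_quantile(c)
        clf.n_features_in_ = 3
        return clf

    def _check_combine(self):
        if self.combine not in _COMBINE_MODES:
            raise InvalidParameterError(
                f"combine must be one of {_COMBINE_MODES}, got {self.combine!r}"
            )

    def _validate_points(self, X):
        check_is_fitted(self, "regions_")
        X = check_array(np.atleast_2d(np.asarray(X, dtype=float)))
        if X.shape[1] != 3:
            raise InvalidDataError(f"expected 3-axis readings, got {X.shape[1]} columns")
        return X

    # -- inference ---------------------------------------------------------
    def mahalanobis(self, X) -> np.ndarray:
        """Combined squared Mahalanobis distance to the fitted regions.

        The minimum over regions under ``combine="any"`` (distance to the
        nearest acceptance ellipsoid), the maximum under ``"all"``.
        """
        X = self._validate_points(X)
        d2 = np.stack([r.mahalanobis_sq(X) for r in self.regions_])
        return d2.min(axis=0) if self.combine == "any" else d2.max(axis=0)

    def decision_function(self, X) -> np.ndarray:
        """Signed margin: >= 0 inside the acceptance set, < 0 outside."""
        d2 = self.mahalanobis(X)  # validates fitted state first
        return self.chi2_quantile_ - d2

    def score_samples(self, X) -> np.ndarray:
        """Highest per-region Gaussian density at each point."""
        X = self._validate_points(X)
        return np.stack([r.density(X) for r in self.regions_]).max(axis=0)

    def predict(self, X) -> np.ndarray:
        """+1 for readings inside the acceptance set (correct posture), -1 outside.

        The boundary (density exactly equal to the threshold) counts as
        inside: the confidence region is closed.
        """
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def predict_posture(self, X) -> np.ndarray:
        """Like :meth:`predict` but as :class:`~posturekit.data.Posture` labels."""
        inside = self.predict(X) == 1
        out = np.empty(inside.shape, dtype=object)
        out[inside] = Posture.CORRECT
        out[~inside] = Posture.INCORRECT
        return out
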