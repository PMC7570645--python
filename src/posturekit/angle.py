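"""Back-angle estimation from accelerometer data.

The back angle is the angle between the measured acceleration vector and a
fixed gravitational reference vector.  Under the device orientation adopted
here the reference points down, ``(0, 0, -9.81)``, while a static upright
wearer senses the reaction to gravity pointing up, so an upright back reads
close to 180 deg and forward tilt by theta reads 180 - theta.  An angle
below 160 deg is treated as a substantially non-upright (crooked) back when
deriving ground-truth labels for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Posture, SensorTrace
from .errors import InvalidDataError, InvalidParameterError

#: Gravitational acceleration reference vector (m/s^2), pointing down.
DEFAULT_GRAVITY = np.array([0.0, 0.0, -9.81])

#: Back angles below this many degrees count as a crooked back.
CROOKED_ANGLE_THRESHOLD = 160.0


@dataclass
class AngleTrace:
    """Time series of back angles in degrees, each in [0, 180]."""

    t: np.ndarray
    angle_deg: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.t.shape != self.angle_deg.shape or self.t.ndim != 1:
            raise InvalidDataError("angle trace arrays must be 1-D and equal length")
        if self.t.size and np.any(np.diff(self.t) < 0):
            raise InvalidDataError("angle-trace timestamps must be non-decreasing")
        if np.any(self.angle_deg < -1e-9) or np.any(self.angle_deg > 180.0 + 1e-9):
            raise InvalidDataError("angles must lie in [0, 180] degrees")
        self.angle_deg = np.clip(self.angle_deg, 0.0, 180.0)

    def __len__(self) -> int:
        return self.t.size


def _angles_deg(V: np.ndarray, g: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(V, axis=1)
    gn = np.linalg.norm(g)
    if gn == 0.0 or np.any(norms == 0.0):
        raise InvalidDataError("zero-norm vector has no direction; cannot compute an angle")
    cosang = V @ g / (norms * gn)
    # rounding can push |cos| marginally past 1; clamp before arccos
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def back_angle(a, g=DEFAULT_GRAVITY) -> float:
    """Angle in degrees between an acceleration reading and the gravity reference.

    Invariant to positive rescaling of either vector and symmetric in its
    arguments; always in [0, 180].
    """
    a = np.asarray(a, dtype=float)
    g = np.asarray(g, dtype=float)
    if a.shape != (3,) or g.shape != (3,):
        raise InvalidDataError("back_angle expects two 3-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(g))):
        raise InvalidDataError("non-finite vector components")
    return float(_angles_deg(a[None, :], g)[0])


def angle_trace(acc_trace: SensorTrace, g=DEFAULT_GRAVITY) -> AngleTrace:
    """Back angle of every sample of an accelerometer trace."""
    if len(acc_trace) == 0:
        raise InvalidDataError("cannot compute angles of an empty trace")
    g = np.asarray(g, dtype=float)
    return AngleTrace(t=acc_trace.t.copy(), angle_deg=_angles_deg(acc_trace.v, g))


def rms_difference(trace_a: AngleTrace, trace_b: AngleTrace,
                   tolerance: float | None = None) -> float:
    """Root-mean-square angle difference between two traces.

    Samples are paired by nearest timestamp within ``tolerance`` (default:
    half the median sampling interval of the denser trace); pairs beyond
    tolerance are discarded.
    """
    if len(trace_a) == 0 or len(trace_b) == 0:
        raise InvalidDataError("cannot compare empty angle traces")
    if tolerance is None:
        dts = [np.median(np.diff(tr.t)) for tr in (trace_a, trace_b) if len(tr) > 1]
        tolerance = 0.5 * min(dts) if dts else np.inf
    pos = np.searchsorted(trace_b.t, trace_a.t)
    left = np.clip(pos - 1, 0, len(trace_b) - 1)
    right = np.clip(pos, 0, len(trace_b) - 1)
    pick = np.where(
        np.abs(trace_b.t[right] - trace_a.t) < np.abs(trace_b.t[left] - trace_a.t),
        right, left,
    )
    ok = np.abs(trace_b.t[pick] - trace_a.t) <= tolerance
    if not np.any(ok):
        raise InvalidDataError("angle traces share no timestamps within tolerance")
    diff = trace_a.angle_deg[ok] - trace_b.angle_deg[pick[ok]]
    return float(np.sqrt(np.mean(diff ** 2)))


def label_by_angle(angle, threshold: float = CROOKED_ANGLE_THRESHOLD):
    """Ground-truth label from the back angle: incorrect iff strictly below threshold.

    Accepts a scalar (returns a :class:`Posture`) or an array (returns an
    object array of labels).
    """
    if not 0.0 < threshold <= 180.0:
        raise InvalidParameterError(f"angle threshold must be in (0, 180], got {threshold}")
    angle_arr = np.asarray(angle, dtype=float)
    if np.any(angle_arr < 0.0) or np.any(angle_arr > 180.0):
        raise InvalidDataError("angles must lie in [0, 180] degrees")
    crooked = angle_arr < threshold
    if angle_arr.ndim == 0:
        return Posture.INCORRECT if crooked else Posture.CORRECT
    labels = np.empty(crooked.shape, dtype=object)
    labels[crooked] = Posture.INCORRECT
    labels[~crooked] = Posture.CORRECT
    return labels
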