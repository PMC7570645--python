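"""Core containers: sensor samples, traces, calibration pose sets.

Conventions used throughout the package:

* sensor channels are named ``"accelerometer"`` and ``"magnetometer"``;
* accelerometer readings are specific force in m/s^2 (an upright, static
  wearer reads ``(0, 0, +9.81)``: the sensed reaction to gravity points up);
* magnetometer readings are in microtesla (uT);
* a calibration pose is one of eight reference positions, a stance
  (standing/sitting) combined with an arm configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import CalibrationDataError, InvalidDataError

ACCELEROMETER = "accelerometer"
MAGNETOMETER = "magnetometer"
SENSORS = (ACCELEROMETER, MAGNETOMETER)

DEFAULT_UNITS = {ACCELEROMETER: "m/s^2", MAGNETOMETER: "uT"}

ARM_POSES = ("arms_down", "right_up", "left_up", "arms_up")
STANCES = ("standing", "sitting")
#: The eight reference poses recorded during calibration.
CALIBRATION_POSES = tuple(f"{stance}_{arms}" for stance in STANCES for arms in ARM_POSES)

#: Minimum number of samples for a full-rank 3-D sample covariance.
MIN_CALIBRATION_SAMPLES = 4


class Posture(str, Enum):
    """Binary posture verdict."""

    CORRECT = "correct"
    INCORRECT = "incorrect"

    def __str__(self) -> str:  # serialise as the bare value
        return self.value


@dataclass(frozen=True)
class SensorSample:
    """One time-stamped 3-axis reading from one sensor."""

    t: float
    sensor: str
    v: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise InvalidDataError(f"sample value must be a finite 3-vector, got {self.v!r}")
        if self.t < 0:
            raise InvalidDataError(f"sample timestamp must be >= 0, got {self.t}")
        if self.sensor not in SENSORS:
            raise InvalidDataError(f"unknown sensor {self.sensor!r}")
        object.__setattr__(self, "v", v)


@dataclass
class SensorTrace:
    """A time-ordered series of 3-axis readings from a single sensor.

    Stored column-wise: ``t`` is an (n,) array of seconds, ``v`` an (n, 3)
    array of readings.  Timestamps must be non-decreasing.
    """

    sensor: str
    t: np.ndarray
    v: np.ndarray
    units: str | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.sensor not in SENSORS:
            raise InvalidDataError(f"unknown sensor {self.sensor!r}")
        if self.t.ndim != 1 or self.v.shape != (self.t.size, 3):
            raise InvalidDataError(
                f"trace shapes inconsistent: t{self.t.shape} vs v{self.v.shape}"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.v)):
            raise InvalidDataError("trace contains non-finite values")
        if self.t.size and (np.any(np.diff(self.t) < 0) or self.t[0] < 0):
            raise InvalidDataError(f"{self.sensor} timestamps must be non-negative and non-decreasing")
        if self.units is None:
            self.units = DEFAULT_UNITS[self.sensor]

    def __len__(self) -> int:
        return self.t.size

    def samples(self):
        """Iterate over the trace as :class:`SensorSample` objects."""
        for ti, vi in zip(self.t, self.v):
            yield SensorSample(float(ti), self.sensor, vi)

    @property
    def nominal_period(self) -> float:
        """Median sampling interval in seconds (nan for traces shorter than 2)."""
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.t)))


@dataclass
class CalibrationPoseSet:
    """All samples of one sensor recorded while holding one calibration pose."""

    pose_label: str
    sensor: str
    X: np.ndarray
    units: str | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.sensor not in SENSORS:
            raise InvalidDataError(f"unknown sensor {self.sensor!r}")
        if self.X.ndim != 2 or self.X.shape[1] != 3:
            raise InvalidDataError(f"pose-set samples must be (n, 3), got {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise InvalidDataError(f"pose set {self.pose_label!r} contains non-finite samples")
        if self.X.shape[0] < MIN_CALIBRATION_SAMPLES:
            raise CalibrationDataError(
                f"pose set {self.pose_label!r} has {self.X.shape[0]} samples; "
                f"at least {MIN_CALIBRATION_SAMPLES} are required for a 3-D covariance"
            )
        if self.units is None:
            self.units = DEFAULT_UNITS[self.sensor]

    def __len__(self) -> int:
        return self.X.shape[0]


def as_posture_array(labels) -> np.ndarray:
    """Coerce a sequence of labels/strings to an object array of :class:`Posture`."""
    return np.array([Posture(l) for l in labels], dtype=object)
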