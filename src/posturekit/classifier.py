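"""Stream classification, dual-sensor fusion, and session scoring.

Each sensor reading is tested against that sensor's calibrated confidence
regions.  The two sensor verdicts are then fused conservatively: the posture
is flagged incorrect only when *both* the accelerometer and the magnetometer
classifiers reject the reading.  This asymmetry is deliberate — a straight
back tilted away from vertical moves the accelerometer far from every
calibration cluster while leaving the shoulder-blade magnets (and hence the
magnetometer) in place, and must not be penalised.

The session score is the percentage of fused records in a monitoring window
(up to 24 h) that are classified correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationModel
from .data import ACCELEROMETER, MAGNETOMETER, Posture, SensorTrace
from .errors import InvalidDataError, InvalidParameterError, UndefinedScoreError

MAX_WINDOW_S = 24 * 3600.0


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-timestamp verdicts: one per sensor (when present) plus the fusion."""

    t: float
    acc_label: Posture | None
    mag_label: Posture | None
    fused_label: Posture
    paired: bool = True


@dataclass(frozen=True)
class SessionScore:
    """Posture score over a monitoring window."""

    window_start: float
    window_end: float
    n_records: int
    score: float  # percent of records fused-correct, in [0, 100]

    def to_dict(self) -> dict:
        return {
            "window_start": self.window_start,
            "window_end": self.window_end,
            "n_records": self.n_records,
            "score_percent": self.score,
        }


def fuse(acc: Posture, mag: Posture) -> Posture:
    """Dual-sensor truth table: incorrect only if both sensors say incorrect."""
    acc, mag = Posture(acc), Posture(mag)
    if acc is Posture.INCORRECT and mag is Posture.INCORRECT:
        return Posture.INCORRECT
    return Posture.CORRECT


def classify_point(x, model: CalibrationModel, sensor: str, combine: str = "any") -> Posture:
    """Classify a single 3-axis reading against one sensor's regions."""
    return classify_points(np.asarray(x, dtype=float)[None, :], model, sensor, combine)[0]


def classify_points(X, model: CalibrationModel, sensor: str, combine: str = "any") -> np.ndarray:
    """Vectorised :func:`classify_point`: (n, 3) readings -> n posture labels."""
    clf = model.classifier_for(sensor, combine=combine)
    return clf.predict_posture(X)


def _pair_indices(t_primary: np.ndarray, t_other: np.ndarray, tol: float):
    """Index of the nearest ``t_other`` within ``tol`` for each primary time (-1 if none)."""
    if t_other.size == 0:
        return np.full(t_primary.size, -1)
    pos = np.searchsorted(t_other, t_primary)
    left = np.clip(pos - 1, 0, t_other.size - 1)
    right = np.clip(pos, 0, t_other.size - 1)
    pick = np.where(
        np.abs(t_other[right] - t_primary) < np.abs(t_other[left] - t_primary), right, left
    )
    pick = np.where(np.abs(t_other[pick] - t_primary) <= tol, pick, -1)
    return pick


def classify_stream(acc_trace: SensorTrace | None, mag_trace: SensorTrace | None,
                    model: CalibrationModel, *, pairing_tolerance: float | None = None,
                    combine: str = "any") -> list[ClassificationRecord]:
    """Classify paired accelerometer/magnetometer traces into fused records.

    Samples from the two sensors are paired by nearest timestamp within
    ``pairing_tolerance`` (default: half the nominal sample period of the
    denser trace).  Samples with no partner within tolerance degrade to
    single-sensor fusion (the fused label equals the available sensor's
    label) and are flagged ``paired=False`` so score denominators are
    preserved.  Records are emitted in time order.
    """
    if acc_trace is None and mag_trace is None:
        raise InvalidDataError("at least one sensor trace is required")
    for trace, sensor in ((acc_trace, ACCELEROMETER), (mag_trace, MAGNETOMETER)):
        if trace is not None and trace.sensor != sensor:
            raise InvalidDataError(f"expected a {sensor} trace, got {trace.sensor}")
        if trace is not None and trace.units != model.units.get(sensor, trace.units):
            raise InvalidDataError(
                f"{sensor} trace units {trace.units!r} do not match the "
                f"calibration units {model.units.get(sensor)!r}"
            )

    labels = {}
    for trace, sensor in ((acc_trace, ACCELEROMETER), (mag_trace, MAGNETOMETER)):
        if trace is not None and len(trace):
            labels[sensor] = classify_points(trace.v, model, sensor, combine)

    if ACCELEROMETER not in labels and MAGNETOMETER not in labels:
        return []

    if ACCELEROMETER not in labels or MAGNETOMETER not in labels:
        sensor = ACCELEROMETER if ACCELEROMETER in labels else MAGNETOMETER
        trace = acc_trace if sensor == ACCELEROMETER else mag_trace
        lab = labels[sensor]
        return [
            ClassificationRecord(
                t=float(t),
                acc_label=lab[i] if sensor == ACCELEROMETER else None,
                mag_label=lab[i] if sensor == MAGNETOMETER else None,
                fused_label=lab[i],
                paired=False,
            )
            for i, t in enumerate(trace.t)
        ]

    if pairing_tolerance is None:
        periods = [tr.nominal_period for tr in (acc_trace, mag_trace) if len(tr) > 1]
        finite = [p for p in periods if np.isfinite(p)]
        pairing_tolerance = 0.5 * min(finite) if finite else np.inf
    if pairing_tolerance < 0:
        raise InvalidParameterError("pairing tolerance must be >= 0")

    acc_lab, mag_lab = labels[ACCELEROMETER], labels[MAGNETOMETER]
    mate = _pair_indices(acc_trace.t, mag_trace.t, pairing_tolerance)

    records = []
    for i, t in enumerate(acc_trace.t):
        j = mate[i]
        if j >= 0:
            records.append(ClassificationRecord(
                t=float(t), acc_label=acc_lab[i], mag_label=mag_lab[j],
                fused_label=fuse(acc_lab[i], mag_lab[j]), paired=True))
        else:
            records.append(ClassificationRecord(
                t=float(t), acc_label=acc_lab[i], mag_label=None,
                fused_label=acc_lab[i], paired=False))
    # magnetometer samples never claimed by an accelerometer sample
    claimed = set(mate[mate >= 0].tolist())
    for j, t in enumerate(mag_trace.t):
        if j not in claimed:
            records.append(ClassificationRecord(
                t=float(t), acc_label=None, mag_label=mag_lab[j],
                fused_label=mag_lab[j], paired=False))
    records.sort(key=lambda r: r.t)
    return records


def score_session(records, window: tuple[float, float] | None = None) -> SessionScore:
    """Percentage of records in ``window`` whose fused label is correct."""
    records = list(records)
    if window is None:
        if not records:
            raise UndefinedScoreError("cannot score an empty record list")
        window = (records[0].t, records[-1].t)
    start, end = float(window[0]), float(window[1])
    if end < start:
        raise InvalidParameterError("window end must be >= window start")
    if end - start > MAX_WINDOW_S:
        raise InvalidParameterError("scoring window is limited to 24 h")
    in_window = [r for r in records if start <= r.t <= end]
    if not in_window:
        raise UndefinedScoreError("no classification records fall inside the window")
    n_correct = sum(r.fused_label is Posture.CORRECT for r in in_window)
    return SessionScore(
        window_start=start, window_end=end, n_records=len(in_window),
        score=100.0 * n_correct / len(in_window),
    )


def accuracy(predicted, truth) -> float:
    """Percentage of positions where the predicted label matches the truth."""
    predicted = [Posture(p) for p in predicted]
    truth = [Posture(p) for p in truth]
    if len(predicted) != len(truth):
        raise InvalidDataError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if not predicted:
        raise InvalidDataError("cannot compute accuracy of empty label lists")
    hits = sum(p is t for p, t in zip(predicted, truth))
    return 100.0 * hits / len(predicted)
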