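"""Readers and writers for traces, models, records and reports.

Traces travel as comma-delimited text with ``#``-prefixed metadata lines::

    # posturekit-trace v1
    # units: accelerometer=m/s^2;magnetometer=uT
    # sample_rate_hz: 50.0
    t,sensor,x,y,z[,truth][,pose]
    0.0,accelerometer,0.012,-0.031,9.803,correct,
    ...

Units are declared in the metadata, never guessed.  ``truth`` carries
optional ground-truth labels, ``pose`` tags calibration segments with their
pose label.  All float serialization is round-trip lossless (17 significant
digits).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .angle import AngleTrace
from .calibration import CalibrationModel
from .classifier import ClassificationRecord, SessionScore
from .data import DEFAULT_UNITS, SENSORS, CalibrationPoseSet, Posture, SensorTrace
from .errors import InvalidDataError, TraceParseError
from .synthetic import SimulationScenario, scenario_from_dict, scenario_to_dict

_MAGIC = "posturekit-trace v1"


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


@dataclass
class TraceFile:
    """Parsed contents of one trace file."""

    traces: dict  # sensor -> SensorTrace
    truth: dict = field(default_factory=dict)  # sensor -> object array of Posture
    pose: dict = field(default_factory=dict)  # sensor -> array of pose labels
    sample_rate: float | None = None


def write_trace(path, traces, truth=None, pose=None, sample_rate=None) -> None:
    """Write sensor traces (and optional per-sample truth/pose tags) to ``path``.

    ``traces`` is an iterable of :class:`SensorTrace`; ``truth`` and ``pose``
    map sensor names to per-sample label sequences aligned with that
    sensor's trace.  Rows are interleaved in time order.
    """
    traces = list(traces)
    if not traces:
        raise InvalidDataError("nothing to write: no traces supplied")
    truth = truth or {}
    pose = pose or {}
    has_truth = bool(truth)
    has_pose = bool(pose)

    rows = []
    for tr in traces:
        tru = truth.get(tr.sensor)
        pos = pose.get(tr.sensor)
        for i in range(len(tr)):
            rows.append((
                tr.t[i], tr.sensor, tr.v[i],
                Posture(tru[i]).value if tru is not None else "",
                str(pos[i]) if pos is not None else "",
            ))
    rows.sort(key=lambda r: r[0])

    units = ";".join(f"{tr.sensor}={tr.units}" for tr in traces)
    header = ["t", "sensor", "x", "y", "z"]
    if has_truth:
        header.append("truth")
    if has_pose:
        header.append("pose")
    with open(path, "w", newline="") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"# units: {units}\n")
        if sample_rate is not None:
            fh.write(f"# sample_rate_hz: {_fmt(sample_rate)}\n")
        writer = csv.writer(fh)
        writer.writerow(header)
        for t, sensor, v, tru, pos in rows:
            row = [_fmt(t), sensor, _fmt(v[0]), _fmt(v[1]), _fmt(v[2])]
            if has_truth:
                row.append(tru)
            if has_pose:
                row.append(pos)
            writer.writerow(row)


def read_trace(path) -> TraceFile:
    """Parse a trace file; malformed rows raise :class:`TraceParseError`
    naming the 1-based line."""
    units: dict = {}
    sample_rate = None
    header = None
    per_sensor: dict = {}

    with open(path) as fh:
        lines = fh.read().splitlines()

    reader_rows = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            meta = line.lstrip("# ").strip()
            if meta.startswith("units:"):
                for part in meta[len("units:"):].strip().split(";"):
                    if part:
                        sensor, _, unit = part.partition("=")
                        units[sensor.strip()] = unit.strip()
            elif meta.startswith("sample_rate_hz:"):
                try:
                    sample_rate = float(meta.split(":", 1)[1])
                except ValueError as exc:
                    raise TraceParseError(f"bad sample_rate_hz: {exc}", lineno) from exc
            continue
        reader_rows.append((lineno, line))

    if not reader_rows:
        raise TraceParseError("trace file contains no data rows")

    for lineno, line in reader_rows:
        cells = next(csv.reader([line]))
        if header is None:
            header = [c.strip() for c in cells]
            required = ["t", "sensor", "x", "y", "z"]
            if header[: len(required)] != required:
                raise TraceParseError(
                    f"expected columns {required}[,truth][,pose], got {header}", lineno
                )
            col = {name: i for i, name in enumerate(header)}
            continue
        if len(cells) != len(header):
            raise TraceParseError(
                f"expected {len(header)} fields, got {len(cells)}", lineno
            )
        sensor = cells[col["sensor"]].strip()
        if sensor not in SENSORS:
            raise TraceParseError(f"unknown sensor name {sensor!r}", lineno)
        try:
            t = float(cells[col["t"]])
            v = [float(cells[col[a]]) for a in ("x", "y", "z")]
        except ValueError as exc:
            raise TraceParseError(f"non-numeric value: {exc}", lineno) from exc
        if not np.isfinite([t, *v]).all():
            raise TraceParseError("non-finite value", lineno)
        entry = per_sensor.setdefault(sensor, {"t": [], "v": [], "truth": [], "pose": [], "line": []})
        if entry["t"] and t < entry["t"][-1]:
            raise TraceParseError(f"timestamps for {sensor} decrease", lineno)
        entry["t"].append(t)
        entry["v"].append(v)
        entry["line"].append(lineno)
        if "truth" in col:
            raw = cells[col["truth"]].strip()
            try:
                entry["truth"].append(Posture(raw) if raw else None)
            except ValueError as exc:
                raise TraceParseError(f"bad truth label {raw!r}", lineno) from exc
        if "pose" in col:
            entry["pose"].append(cells[col["pose"]].strip() or None)

    traces, truth, pose = {}, {}, {}
    for sensor, entry in per_sensor.items():
        traces[sensor] = SensorTrace(
            sensor,
            np.asarray(entry["t"]),
            np.asarray(entry["v"]),
            units=units.get(sensor) or DEFAULT_UNITS[sensor],
        )
        if any(x is not None for x in entry["truth"]):
            truth[sensor] = np.array(entry["truth"], dtype=object)
        if any(x is not None for x in entry["pose"]):
            pose[sensor] = np.array(entry["pose"], dtype=object)
    return TraceFile(traces=traces, truth=truth, pose=pose, sample_rate=sample_rate)


def pose_sets_from_trace(trace_file: TraceFile) -> list:
    """Group a pose-tagged calibration trace into :class:`CalibrationPoseSet`."""
    pose_sets = []
    for sensor, tr in sorted(trace_file.traces.items()):
        tags = trace_file.pose.get(sensor)
        if tags is None:
            raise InvalidDataError(
                f"calibration trace for {sensor} lacks the per-segment 'pose' column"
            )
        for label in sorted({str(x) for x in tags if x is not None}):
            mask = np.array([str(x) == label for x in tags])
            pose_sets.append(CalibrationPoseSet(label, sensor, tr.v[mask], units=tr.units))
    return pose_sets


# -- classification records -------------------------------------------------

_REC_HEADER = ["t", "acc_label", "mag_label", "fused_label", "paired"]


def write_records(path, records) -> None:
    """Classification records as delimited text (one row per timestamp)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REC_HEADER)
        for r in records:
            writer.writerow([
                _fmt(r.t),
                r.acc_label.value if r.acc_label is not None else "",
                r.mag_label.value if r.mag_label is not None else "",
                r.fused_label.value,
                "1" if r.paired else "0",
            ])


def read_records(path) -> list:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _REC_HEADER:
            raise TraceParseError(f"expected header {_REC_HEADER}, got {header}", 1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                records.append(ClassificationRecord(
                    t=float(row[0]),
                    acc_label=Posture(row[1]) if row[1] else None,
                    mag_label=Posture(row[2]) if row[2] else None,
                    fused_label=Posture(row[3]),
                    paired=row[4] == "1",
                ))
            except (ValueError, IndexError) as exc:
                raise TraceParseError(f"bad record row: {exc}", lineno) from exc
    return records


# -- angle traces ------------------------------------------------------------

def write_angle_trace(path, trace: AngleTrace) -> None:
    """Angle trace as two-column delimited text (t, angle_deg)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "angle_deg"])
        for t, a in zip(trace.t, trace.angle_deg):
            writer.writerow([_fmt(t), _fmt(a)])


def read_angle_trace(path) -> AngleTrace:
    t, angles = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["t", "angle_deg"]:
            raise TraceParseError(f"expected header ['t', 'angle_deg'], got {header}", 1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                t.append(float(row[0]))
                angles.append(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise TraceParseError(f"bad angle row: {exc}", lineno) from exc
    return AngleTrace(t=np.asarray(t), angle_deg=np.asarray(angles))


# -- reports, models, scenarios ----------------------------------------------

def write_score(path, score: SessionScore) -> None:
    with open(path, "w") as fh:
        json.dump(score.to_dict(), fh, indent=1)
        fh.write("\n")


def read_score(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_model(path, model: CalibrationModel) -> None:
    model.save(path)


def load_model(path) -> CalibrationModel:
    return CalibrationModel.load(path)


def save_scenario(path, scenario: SimulationScenario) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)


def load_scenario(path) -> SimulationScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return scenario_from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise InvalidDataError(f"malformed scenario file {path}: {exc}") from exc
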