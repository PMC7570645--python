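"""Physics-based wearer/sensor simulator.

Generates calibration pose sets and labelled test traces for the two sensors
carried on the upper back of a simulated wearer:

* **accelerometer** — reads the gravity reaction projected into the sensor
  frame.  Tilting the (straight) back rotates the sensor relative to the
  world, so the reading rotates accordingly; the magnitude stays at g for a
  quasi-static wearer.
* **magnetometer** — reads the Earth field projected into the sensor frame
  plus the field of two permanent magnets worn over the shoulder blades,
  modelled as point dipoles.  The magnets are body-fixed: tilting a straight
  back moves only the (small) Earth-field contribution, whereas slumping the
  shoulders displaces the magnets and shifts the (dominant, ~2.2 mT) dipole
  contribution by ~1 mT.  This decoupling is what lets the magnetometer
  vouch for a straight-but-tilted back.

Noise model: additive Gaussian sensor noise per axis, small random postural
sway (a per-sample random pitch/roll of the whole torso, which moves both
gravity and Earth-field projections coherently), and a small jitter of the
shoulder position transferring to the magnet geometry.  All randomness flows
from a single seed, so every output is a pure function of
(scenario, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .angle import CROOKED_ANGLE_THRESHOLD, DEFAULT_GRAVITY, AngleTrace, label_by_angle
from .data import (
    ACCELEROMETER,
    ARM_POSES,
    MAGNETOMETER,
    STANCES,
    CalibrationPoseSet,
    Posture,
    SensorTrace,
)
from .errors import InvalidDataError, InvalidParameterError, SaturationWarning

MU0_OVER_4PI = 1e-7  # T * m / A


@dataclass(frozen=True)
class WearerState:
    """Quasi-static description of the wearer at one instant.

    ``back_tilt`` is the forward deviation of the thoracic axis from upright
    in degrees; ``shoulder_state`` interpolates the magnet geometry between
    the anatomically ideal, retracted position (0, magnets nearest the
    sensor) and fully slumped shoulders (1).
    """

    back_tilt: float = 0.0
    back_straight: bool = True
    shoulder_state: float = 0.0
    arm_pose: str = "arms_down"
    stance: str = "standing"

    def __post_init__(self):
        if not 0.0 <= self.back_tilt <= 90.0:
            raise InvalidParameterError(f"back_tilt must be in [0, 90] deg, got {self.back_tilt}")
        if not 0.0 <= self.shoulder_state <= 1.0:
            raise InvalidParameterError(
                f"shoulder_state must be in [0, 1], got {self.shoulder_state}"
            )
        if self.arm_pose not in ARM_POSES:
            raise InvalidParameterError(f"unknown arm pose {self.arm_pose!r}")
        if self.stance not in STANCES:
            raise InvalidParameterError(f"unknown stance {self.stance!r}")


#: per-arm-pose deterministic perturbations: (pitch deg, roll deg, mag offset uT)
_ARM_OFFSETS = {
    "arms_down": (0.0, 0.0, (0.0, 0.0, 0.0)),
    "right_up": (0.0, 2.0, (25.0, -12.0, 8.0)),
    "left_up": (0.0, -2.0, (-25.0, -12.0, 8.0)),
    "arms_up": (-1.5, 0.0, (0.0, -20.0, 18.0)),
}
#: per-stance perturbations: (pitch deg, mag offset uT)
_STANCE_OFFSETS = {
    "standing": (0.0, (0.0, 0.0, 0.0)),
    "sitting": (1.0, (10.0, 15.0, -10.0)),
}


@dataclass
class SensorPhysicsConfig:
    """Physical parameters of the simulated wearer + sensor assembly.

    The magnet geometry (dipole moment, retracted and slumped positions) is
    chosen so that the magnets contribute ~2.2 mT at the sensor in the ideal
    posture and the correct-to-slumped field swing is ~1 mT, inside a
    +-5 mT magnetometer dynamic range.  Actual magnet-to-sensor distances of
    the hardware are not published; these are synthetic stand-ins.
    """

    gravity_magnitude: float = 9.81  # m/s^2
    earth_field: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 26.0, -36.0])
    )  # uT, mid-latitude magnitude/inclination; wearer faces +y
    magnet_moment: float = 6.982  # A*m^2 per magnet, along sensor +z
    magnet_positions_retracted: np.ndarray = field(
        default_factory=lambda: np.array([[0.04, 0.0, 0.09], [-0.04, 0.0, 0.09]])
    )  # m, sensor frame
    magnet_positions_slumped: np.ndarray = field(
        default_factory=lambda: np.array([[0.05, 0.02, 0.10], [-0.05, 0.02, 0.10]])
    )
    acc_noise_sd: float = 0.05  # m/s^2 per axis
    mag_noise_sd: float = 3.0  # uT per axis (manufacturer sensitivity)
    sway_sd_deg: float = 0.5  # postural sway, random pitch/roll per sample
    shoulder_jitter_sd: float = 0.005  # garment wobble, in shoulder_state units
    dynamic_range_ut: float = 5000.0  # magnetometer saturation (+-5 mT)

    def __post_init__(self):
        self.earth_field = np.asarray(self.earth_field, dtype=float)
        self.magnet_positions_retracted = np.asarray(self.magnet_positions_retracted, float)
        self.magnet_positions_slumped = np.asarray(self.magnet_positions_slumped, float)
        for name in ("acc_noise_sd", "mag_noise_sd", "sway_sd_deg", "shoulder_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.gravity_magnitude <= 0 or np.linalg.norm(self.earth_field) <= 0:
            raise InvalidParameterError("field magnitudes must be positive")


@dataclass(frozen=True)
class Segment:
    """One scripted stretch of a scenario timeline."""

    duration_s: float
    state: WearerState
    truth: Posture

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidParameterError("segment durations must be positive")


@dataclass
class SimulationScenario:
    """Scripted posture timeline with per-segment ground-truth labels."""

    name: str
    segments: list
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self):
        self.segments = list(self.segments)
        if not self.segments:
            raise InvalidParameterError("scenario needs at least one segment")
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")

    @property
    def duration_s(self) -> float:
        return sum(seg.duration_s for seg in self.segments)


@dataclass
class SimulationResult:
    """Traces plus per-sample ground truth produced by :func:`simulate_scenario`."""

    acc: SensorTrace
    mag: SensorTrace
    truth: np.ndarray  # object array of Posture, aligned with the trace timestamps
    angle_truth: AngleTrace


def dipole_field(moment, r):
    """Magnetic field (tesla) of a point dipole ``moment`` (A*m^2) at offset ``r`` (m).

    ``r`` points from the dipole to the field point and may be a single
    3-vector or an (n, 3) array.
    """
    moment = np.asarray(moment, dtype=float)
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    R = np.atleast_2d(r)
    norms = np.linalg.norm(R, axis=1)
    if np.any(norms == 0.0):
        raise InvalidDataError("dipole field is singular at zero displacement")
    rhat = R / norms[:, None]
    B = MU0_OVER_4PI * (3.0 * (rhat @ moment)[:, None] * rhat - moment) / norms[:, None] ** 3
    return B[0] if single else B


def _orientation(state: WearerState, pitch_sway=0.0, roll_sway=0.0) -> Rotation:
    """Sensor-to-world rotation for a wearer state (plus optional sway angles)."""
    arm_pitch, arm_roll, _ = _ARM_OFFSETS[state.arm_pose]
    stance_pitch, _ = _STANCE_OFFSETS[state.stance]
    pitch = state.back_tilt + arm_pitch + stance_pitch + np.asarray(pitch_sway)
    roll = arm_roll + np.asarray(roll_sway)
    angles = np.stack(np.broadcast_arrays(pitch, roll), axis=-1)
    return Rotation.from_euler("xy", angles, degrees=True)


def _magnet_field_ut(shoulder_state, cfg: SensorPhysicsConfig) -> np.ndarray:
    """Total field of both magnets at the sensor, in uT (sensor frame)."""
    s = np.atleast_1d(np.asarray(shoulder_state, dtype=float))[:, None, None]
    pos = (1.0 - s) * cfg.magnet_positions_retracted + s * cfg.magnet_positions_slumped
    moment = np.array([0.0, 0.0, cfg.magnet_moment])
    B = np.zeros((s.shape[0], 3))
    for k in range(pos.shape[1]):
        B += dipole_field(moment, -pos[:, k, :]) * 1e6
    return B


def _mag_offset_ut(state: WearerState) -> np.ndarray:
    return np.asarray(_ARM_OFFSETS[state.arm_pose][2]) + np.asarray(_STANCE_OFFSETS[state.stance][1])


def _readings_batch(state: WearerState, cfg: SensorPhysicsConfig, n: int, rng):
    """(n, 3) accelerometer and magnetometer readings for one held state."""
    if rng is None:
        sway = np.zeros((2, n))
        acc_noise = mag_noise = 0.0
        shoulder = np.full(n, state.shoulder_state)
    else:
        sway = rng.normal(0.0, cfg.sway_sd_deg, size=(2, n))
        acc_noise = rng.normal(0.0, cfg.acc_noise_sd, size=(n, 3))
        mag_noise = rng.normal(0.0, cfg.mag_noise_sd, size=(n, 3))
        # two-sided garment wobble: may extrapolate marginally past [0, 1]
        shoulder = state.shoulder_state + rng.normal(0.0, cfg.shoulder_jitter_sd, size=n)
    rot = _orientation(state, pitch_sway=sway[0], roll_sway=sway[1])
    f_world = np.array([0.0, 0.0, cfg.gravity_magnitude])  # gravity reaction, points up
    acc = rot.apply(np.tile(f_world, (n, 1)), inverse=True) + acc_noise
    mag = (
        rot.apply(np.tile(cfg.earth_field, (n, 1)), inverse=True)
        + _magnet_field_ut(shoulder, cfg)
        + _mag_offset_ut(state)
        + mag_noise
    )
    return acc, mag


def sensor_readings(state: WearerState, cfg: SensorPhysicsConfig | None = None, rng=None):
    """One (accelerometer, magnetometer) reading pair for a wearer state.

    With ``rng=None`` the reading is noiseless (no sensor noise, no sway, no
    shoulder jitter): the accelerometer magnitude is exactly g.
    """
    cfg = cfg or SensorPhysicsConfig()
    acc, mag = _readings_batch(state, cfg, 1, rng)
    return acc[0], mag[0]


def _segment_sample_counts(scenario: SimulationScenario):
    counts = [max(1, int(round(seg.duration_s * scenario.sample_rate))) for seg in scenario.segments]
    return counts


def simulate_scenario(scenario: SimulationScenario,
                      cfg: SensorPhysicsConfig | None = None) -> SimulationResult:
    """Synthesize sensor traces, truth labels and the true angle trace.

    Output is reproducible: it depends only on (scenario, cfg, scenario.seed).
    A warning is raised if any magnetometer sample exceeds the configured
    dynamic range.
    """
    cfg = cfg or SensorPhysicsConfig()
    rng = np.random.default_rng(scenario.seed)
    counts = _segment_sample_counts(scenario)
    dt = 1.0 / scenario.sample_rate

    acc_parts, mag_parts, truth_parts, angle_parts = [], [], [], []
    for seg, n in zip(scenario.segments, counts):
        acc, mag = _readings_batch(seg.state, cfg, n, rng)
        acc_parts.append(acc)
        mag_parts.append(mag)
        truth_parts.extend([seg.truth] * n)
        true_acc, _ = _readings_batch(seg.state, cfg, 1, None)
        cosang = true_acc[0] @ DEFAULT_GRAVITY / (
            np.linalg.norm(true_acc[0]) * np.linalg.norm(DEFAULT_GRAVITY)
        )
        angle_parts.append(np.full(n, np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))))

    n_total = sum(counts)
    t = np.arange(n_total) * dt
    acc_v = np.vstack(acc_parts)
    mag_v = np.vstack(mag_parts)
    if np.any(np.abs(mag_v) > cfg.dynamic_range_ut):
        warnings.warn(
            "simulated magnetometer reading exceeds the sensor dynamic range",
            SaturationWarning,
            stacklevel=2,
        )
    truth = np.array(truth_parts, dtype=object)
    return SimulationResult(
        acc=SensorTrace(ACCELEROMETER, t, acc_v),
        mag=SensorTrace(MAGNETOMETER, t, mag_v),
        truth=truth,
        angle_truth=AngleTrace(t=t, angle_deg=np.concatenate(angle_parts)),
    )


def simulate_calibration(cfg: SensorPhysicsConfig | None = None, n_per_pose: int = 200,
                         seed: int = 0) -> list:
    """Calibration recordings: 8 poses x 2 sensors, all in the correct posture.

    Every pose is held upright with retracted shoulders; only the stance and
    arm configuration vary, as in the calibration protocol.
    """
    if n_per_pose < 4:
        raise InvalidParameterError("n_per_pose must be at least 4")
    cfg = cfg or SensorPhysicsConfig()
    rng = np.random.default_rng(seed)
    pose_sets = []
    for stance in STANCES:
        for arm_pose in ARM_POSES:
            state = WearerState(arm_pose=arm_pose, stance=stance)
            acc, mag = _readings_batch(state, cfg, n_per_pose, rng)
            label = f"{stance}_{arm_pose}"
            pose_sets.append(CalibrationPoseSet(label, ACCELEROMETER, acc))
            pose_sets.append(CalibrationPoseSet(label, MAGNETOMETER, mag))
    return pose_sets


# ---------------------------------------------------------------------------
# canned scenarios mirroring the two validation protocols
# ---------------------------------------------------------------------------

def tilting_scenario(seed: int = 0, sample_rate: float = 50.0) -> SimulationScenario:
    """Straight-back tilting test: the wearer leans forward and back while
    keeping the spine straight and the shoulders retracted.

    Ground truth is *correct* throughout — the posture itself never breaks —
    even though the accelerometer alone drifts out of its calibration
    clusters at a couple of degrees of tilt.
    """
    def seg(duration, tilt):
        return Segment(duration, WearerState(back_tilt=tilt), Posture.CORRECT)

    segments = [seg(10.0, 0.0)]
    segments += [seg(5.0, tilt) for tilt in (3.0, 6.0, 8.0, 6.0, 3.0)]
    segments += [seg(10.0, 0.0)]
    return SimulationScenario("tilting", segments, sample_rate=sample_rate, seed=seed)


def crooked_scenario(seed: int = 0, sample_rate: float = 50.0,
                     cycles: int = 3) -> SimulationScenario:
    """Crooked-back test: the wearer alternates between an upright straight
    back and a crooked, slumped one, passing briefly through intermediate
    postures.

    Ground-truth labels follow the back-angle rule: a segment is *incorrect*
    iff its true back angle (180 deg minus the tilt) falls strictly below
    160 deg.  Crooked segments combine a 30 deg thoracic tilt (true angle
    150 deg) with fully slumped shoulders, so both sensors move out of their
    calibration regions.
    """
    def seg(duration, tilt, shoulder, straight=True):
        truth = label_by_angle(180.0 - tilt, CROOKED_ANGLE_THRESHOLD)
        state = WearerState(back_tilt=tilt, back_straight=straight, shoulder_state=shoulder)
        return Segment(duration, state, truth)

    cycle = [
        seg(8.0, 0.0, 0.0),
        seg(1.0, 10.0, 0.4),
        seg(1.0, 25.0, 0.8),
        seg(8.0, 30.0, 1.0, straight=False),
        seg(1.0, 25.0, 0.8),
        seg(1.0, 10.0, 0.4),
    ]
    segments = cycle * cycles + [seg(8.0, 0.0, 0.0)]
    return SimulationScenario("crooked", segments, sample_rate=sample_rate, seed=seed)


SCENARIO_FACTORIES = {"tilting": tilting_scenario, "crooked": crooked_scenario}


# ---------------------------------------------------------------------------
# scenario (de)serialization helpers used by the io layer
# ---------------------------------------------------------------------------

def scenario_to_dict(scenario: SimulationScenario) -> dict:
    return {
        "name": scenario.name,
        "sample_rate": scenario.sample_rate,
        "seed": scenario.seed,
        "segments": [
            {
                "duration_s": seg.duration_s,
                "back_tilt_deg": seg.state.back_tilt,
                "back_straight": seg.state.back_straight,
                "shoulder_state": seg.state.shoulder_state,
                "arm_pose": seg.state.arm_pose,
                "stance": seg.state.stance,
                "truth": seg.truth.value,
            }
            for seg in scenario.segments
        ],
    }


def scenario_from_dict(d: dict) -> SimulationScenario:
    segments = [
        Segment(
            duration_s=float(sd["duration_s"]),
            state=WearerState(
                back_tilt=float(sd.get("back_tilt_deg", 0.0)),
                back_straight=bool(sd.get("back_straight", True)),
                shoulder_state=float(sd.get("shoulder_state", 0.0)),
                arm_pose=sd.get("arm_pose", "arms_down"),
                stance=sd.get("stance", "standing"),
            ),
            truth=Posture(sd["truth"]),
        )
        for sd in d["segments"]
    ]
    return SimulationScenario(
        name=d.get("name", "custom"),
        segments=segments,
        sample_rate=float(d.get("sample_rate", 50.0)),
        seed=int(d.get("seed", 0)),
    )
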