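# Methods

## Statistical model

Calibration data are modelled per (sensor, pose) as i.i.d. draws from a
trivariate Gaussian. The mean is the sample mean; the covariance is the
unbiased (N−1 divisor) sample covariance, symmetrized. Because only correct
posture can be demonstrated by the wearer, classification is one-sided: a
reading is *correct* for a sensor iff it falls inside the confidence
ellipsoid of at least one pose,

    (x − μᵢ)ᵀ Σᵢ⁻¹ (x − μᵢ) ≤ χ²₃(c),

which is exactly the density test N(x; μᵢ, Σᵢ) ≥ τᵢ with

    τᵢ = (2π)^{−3/2} |Σᵢ|^{−1/2} exp(−χ²₃(c)/2).

The union ("any region") combination is the operational default. The eight
pose clusters are spatially disjoint, so requiring membership in *all*
regions would reject nearly everything including the calibration data
itself; the intersection variant is nevertheless available
(`combine="all"`) for comparison. Under the Gaussian model the acceptance
region of the generating pose has coverage exactly c; the empirical
coverage check in the acceptance suite verifies this at c = 0.95 with a
5σ binomial band on 100,000 draws.

The ellipsoid semi-axis offsets are δⱼ = √(χ²₃(c)·λⱼ)·vⱼ for eigenpairs
(λⱼ, vⱼ) of Σᵢ. The density is identical at all semi-axis endpoints, which
is what makes τ a single well-defined scalar; the implementation computes τ
by the closed form and the test suite re-derives it from the endpoint
construction on random SPD covariances (agreement required to 1e−10
relative, all three axes).

### Fusion and scoring

Per-sample sensor verdicts are fused by the conservative truth table:
incorrect only when both sensors are incorrect. The two sensor streams are
paired by nearest timestamp within a tolerance (default: half the nominal
sample period); unpaired samples degrade to single-sensor fusion and are
flagged rather than dropped, so score denominators are preserved. The
session score is the unweighted percentage of fused-correct records in the
window (uniform sampling assumed; no time-weighted integration, no
smoothing/debouncing of per-sample labels).

### Back angle

The back angle is arccos(a·ĝ)/|a| between an accelerometer reading and a
fixed gravity reference g = (0, 0, −9.81) m/s². With the adopted mounting
convention an upright wearer senses the gravity reaction (0, 0, +9.81), so
upright reads 180° and a forward tilt of θ reads 180° − θ; an angle
strictly below 160° is labelled crooked when building ground truth.
Numerical cosines marginally outside [−1, 1] are clamped before arccos.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `c` (confidence) | 0.95 | — | coverage of each acceptance ellipsoid |
| `combine` | `"any"` | — | union vs intersection of pose regions |
| pairing tolerance | half sample period | s | max clock skew when pairing sensors |
| angle threshold | 160 | deg | crooked-back label boundary (strict `<`) |
| `ridge` | 1e−6 | — | relative diagonal ridge for degenerate Σ |
| `max_condition` | 1e12 | — | condition bound that triggers the ridge |

A singular or ill-conditioned sample covariance (e.g. noiseless synthetic
fixtures) receives a diagonal ridge of `ridge · trace(Σ)/3` (unit scale
when Σ = 0), escalating tenfold until SPD; the event is recorded on the
region (`ridged`) and in the serialized model rather than raised, so exact
fixtures remain usable. Fewer than 4 samples per pose is a hard error (no
full-rank 3-D covariance). Calibration refuses mixed units per sensor, and
classification refuses traces whose units differ from the model's.

## Simulator

The simulator generates what the worn device would measure, as a pure
function of (scenario, physics config, seed):

* **Accelerometer** — the gravity reaction rotated into the sensor frame by
  the wearer's orientation (back tilt = pitch; small deterministic
  pitch/roll offsets per arm pose and stance), magnitude exactly g when
  noiseless.
* **Magnetometer** — the Earth field (default (0, 26, −36) μT ≈ 44 μT at a
  mid-latitude inclination, wearer facing +y) rotated into the sensor
  frame, plus the field of two body-fixed permanent magnets modelled as
  point dipoles (B = (μ₀/4π)(3(m·r̂)r̂ − m)/r³), plus small deterministic
  per-pose offsets.

The magnet geometry is not published for the hardware; the defaults here
are synthetic stand-ins tuned once so that the magnet contribution at the
sensor is 2.200 mT in the ideal posture and the correct→slumped swing is
1.04 mT, matching the device's two reported field figures: dipole moment
6.982 A·m² per magnet (≈ 6.5 cm³ of N45-grade material), magnets at
(±4, 0, 9) cm from the sensor when the shoulders are retracted and
(±5, 2, 10) cm when slumped, linearly interpolated by `shoulder_state`.
All magnetometer readings stay inside the sensor's ±5 mT dynamic range in
the default scenarios; exceeding it raises a `SaturationWarning`.

Noise model (all configurable): additive Gaussian sensor noise of
0.05 m/s² (accelerometer) and 3 μT (magnetometer, the manufacturer
sensitivity) per axis; postural sway as a per-sample random pitch/roll of
0.5° s.d. applied coherently to both field projections; and a 0.005 s.d.
jitter of `shoulder_state` representing garment wobble of the magnets
(two-sided, so it may extrapolate marginally past [0, 1]).

The key mechanism the simulator encodes is the *decoupling* of the two
sensors: tilting a straight back rotates the gravity and Earth-field
projections but leaves the magnet-to-sensor geometry unchanged, whereas
slumping moves the magnets (≈1 mT shift, huge against the ~8 μT radius of
the magnetometer's acceptance regions) while barely moving the
accelerometer. With the defaults, the accelerometer leaves its calibration
regions at ≈2° of tilt and the magnetometer — via Earth-field rotation
only — at ≈12°.

### Scenarios

* **Calibration** (`simulate_calibration`): 8 poses × 2 sensors, 200
  samples per pose by default at 50 Hz-equivalent, all upright with
  retracted shoulders; only stance and arm configuration vary.
* **Tilting** (`tilting_scenario`, 55 s at 50 Hz): upright 10 s, then 5 s
  holds at 3°, 6°, 8°, 6°, 3° of forward tilt with a straight back, then
  upright 10 s. Ground truth is all-correct. The tilt range was chosen from
  the detection-threshold analysis above: deep enough that the
  accelerometer alone rejects most of the session, shallow enough that the
  straight back genuinely remains a correct posture.
* **Crooked** (`crooked_scenario`, 68 s at 50 Hz): three cycles of upright
  8 s → 1 s ramp (10° tilt, shoulders 0.4) → 1 s ramp (25°, 0.8) → crooked
  hold 8 s (30° tilt, shoulders fully slumped, true angle 150°) → ramps
  back, then a final upright hold. Segment truth follows the 160° angle
  rule, so the 10° ramp segments are labelled correct while the classifier
  already rejects them — intermediate postures are the natural error source
  of this protocol.

Problem sizes (200 samples/pose, ≈3 000 samples per scenario, 10-seed
sweeps in the acceptance suite) keep the full test suite in a few seconds
while leaving Monte-Carlo tolerances comfortably met.

### What the simulator does and does not show

The simulator emulates quasi-static poses with Gaussian sensor noise,
coherent postural sway and a rigid magnet/garment geometry. It does not
model gait or dynamic acceleration, soft-tissue and garment deformation,
magnetic disturbances from the environment, sensor bias/drift or
temperature effects, and it synthesizes no gyroscope channel (the
classifier ignores gyroscope data; no stance-detection algorithm is
defined). Passing tests therefore demonstrate the correctness and the
statistical behaviour of the *algorithm* under its own model assumptions —
not the clinical accuracy of any physical device; the single-subject
accuracies reported for the hardware are not reproducible quantities and
are used only as directional references (fusion must beat the
accelerometer alone on the tilting protocol; both protocols must classify
well above chance).

## Numerical choices

* χ²₃ quantiles via `scipy.stats.chi2.ppf`; densities via
  `scipy.stats.multivariate_normal`; Mahalanobis distances via Cholesky
  solves; τ via `slogdet` in log space. Tests cross-check against
  independent routines (explicit inverse/determinant density, bisection on
  the regularized incomplete gamma, numeric gradient of the dipole
  potential).
* Boundary ties classify as correct (the confidence region is closed);
  equality is exact floating-point `≥`, and oracle comparisons exclude a
  1e−10 band around the boundary.
* Eigendecomposition by `scipy.linalg.eigh` (ascending eigenvalues);
  eigenvector sign is irrelevant to every derived quantity.
* Serialization uses 17-significant-digit decimal floats; round-trips are
  bit-lossless.

## Known limitations

* The classifier is memoryless per sample; contiguous misclassification
  blocks at pose transitions are not debounced.
* Single-sensor fallback keeps the record but cannot benefit from fusion;
  long sensor dropouts therefore inherit that sensor's false-alarm rate.
* The union rule assumes pose clusters do not bridge the correct/incorrect
  boundary; a calibration pose held with poor posture would poison its
  region (no outlier rejection inside a pose set).
* Sitting vs standing differ only by small deterministic offsets in the
  simulator; real seated kinematics are richer.
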