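"""Core domain types for boot-IMU ski motion analysis.

The pipeline follows the activity recognition chain: raw two-boot inertial
streams plus a 1 Hz GNSS speed track are segmented into turns, each turn is
enriched with four time-normalized variables (edge angle, edge-angle
symmetry, radial force, speed), classified by style and size, and scored
against a per-variable principal-component reference model.

Axis convention (boot-cuff mounted IMU): Y vertical (superior), X lateral
(to the right), Z posterior — so Z is the roll axis of the boot, and the
roll-rate channel is ``gyro[:, 2]`` while the yaw-rate channel (rotation
about the vertical) is ``gyro[:, 1]``.  Accelerometer values are stored in
g (full scale +/-16 g), gyroscope values in degrees/second (full scale
+/-1000 dps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError, DimensionError

#: number of points of a time-normalized turn variable (0..100 % duration)
N_POINTS = 101
GRAVITY = 9.80665  # m/s^2
ACCEL_FULL_SCALE_G = 16.0
GYRO_FULL_SCALE_DPS = 1000.0
#: transmitted sample rate of the boot IMUs, Hz
NOMINAL_IMU_RATE_HZ = 54.0

VARIABLES = ("edge_angle", "symmetry", "radial_force", "speed")
STYLES = ("carving", "drifting", "non_parallel", "snowplow", "snowplow_steering")
#: styles for which reference cells are fitted / percentage scoring applies
SCORED_STYLES = ("carving", "drifting")
SIZES = ("small", "medium", "large")
DIRECTIONS = ("left", "right")

#: run-level intended style/size codes used in test protocols
RUN_CODES = {
    "CL": ("carving", "large"),
    "CM": ("carving", "medium"),
    "CS": ("carving", "small"),
    "DL": ("drifting", "large"),
    "DM": ("drifting", "medium"),
    "DS": ("drifting", "small"),
    "Max": ("carving", "large"),
}

DEFAULT_BODY_MASS_KG = 75.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class SensorStream:
    """One boot's IMU stream: timestamps (s), accel (n,3) in g, gyro (n,3) in dps."""

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    side: str
    #: sample indices preceded by a transmission gap > 3 nominal intervals
    gap_indices: tuple = ()

    def __post_init__(self):
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        self.accel = _as_float_array(self.accel, "accel")
        self.gyro = _as_float_array(self.gyro, "gyro")
        if self.side not in DIRECTIONS:
            raise ValidationError(f"side must be left|right, got {self.side!r}")
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValidationError(
                f"channel length mismatch: {n} timestamps, accel {self.accel.shape}, "
                f"gyro {self.gyro.shape}"
            )
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            k = int(np.argmax(np.diff(self.timestamps) <= 0)) + 1
            raise ValidationError(f"timestamps not strictly increasing at row {k}")
        if np.any(np.abs(self.accel) > ACCEL_FULL_SCALE_G + 1e-9):
            raise ValidationError("accelerometer values exceed +/-16 g full scale")
        if np.any(np.abs(self.gyro) > GYRO_FULL_SCALE_DPS + 1e-9):
            raise ValidationError("gyroscope values exceed +/-1000 dps full scale")

    @property
    def nominal_rate_hz(self) -> float:
        """Nominal sample rate recovered as 1 / median inter-sample interval."""
        if len(self.timestamps) < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @property
    def roll_rate_dps(self) -> np.ndarray:
        """Roll-axis (boot Z) angular rate, dps."""
        return self.gyro[:, 2]

    @property
    def yaw_rate_dps(self) -> np.ndarray:
        """Yaw-axis (boot Y, vertical) angular rate, dps."""
        return self.gyro[:, 1]


@dataclass
class GnssTrack:
    """1 Hz GNSS speed track: timestamps (s), speed (m/s, non-negative)."""

    timestamps: np.ndarray
    speed: np.ndarray

    def __post_init__(self):
        self.timestamps = _as_float_array(self.timestamps, "timestamps")
        self.speed = _as_float_array(self.speed, "speed")
        if self.timestamps.shape != self.speed.shape:
            raise ValidationError("GNSS timestamps and speed differ in length")
        if len(self.timestamps) >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError("GNSS timestamps not strictly increasing")
        if np.any(self.speed < 0):
            raise ValidationError("GNSS speeds must be non-negative")


@dataclass
class RawRun:
    """One ski run: two boot streams, a GNSS track and run metadata."""

    left: SensorStream
    right: SensorStream
    gnss: GnssTrack
    skier_id: str = "unknown"
    intended_style: Optional[str] = None  # CL/CM/CS/DL/DM/DS/Max
    body_mass: float = DEFAULT_BODY_MASS_KG
    run_id: str = "run"

    def __post_init__(self):
        if self.intended_style is not None and self.intended_style not in RUN_CODES:
            raise ValidationError(
                f"unknown intended_style {self.intended_style!r}; "
                f"expected one of {sorted(RUN_CODES)}"
            )
        spans = [
            (s.timestamps[0], s.timestamps[-1])
            for s in (self.left, self.right)
            if len(s.timestamps)
        ]
        if len(self.gnss.timestamps):
            spans.append((self.gnss.timestamps[0], self.gnss.timestamps[-1]))
        if spans:
            latest_start = max(t0 for t0, _ in spans)
            earliest_end = min(t1 for _, t1 in spans)
            if latest_start >= earliest_end:
                raise ValidationError("sensor streams do not overlap in time")


@dataclass
class TurnSegment:
    """One detected turn: [start_time, end_time) between roll-rate extrema."""

    start_time: float
    end_time: float
    direction: str
    mean_speed: Optional[float] = None

    def __post_init__(self):
        if self.end_time <= self.start_time:
            raise ValidationError("segment end_time must exceed start_time")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be left|right, got {self.direction!r}")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class EnrichedTurn:
    """One turn's four 101-point variables plus style/size labels.

    Units: edge_angle and symmetry in degrees, radial_force in multiples of
    body weight, speed in m/s.  Vectors live on the normalized 0-100 % turn
    duration base.
    """

    edge_angle: np.ndarray
    symmetry: np.ndarray
    radial_force: np.ndarray
    speed: np.ndarray
    style: str
    size: str
    direction: str = "left"
    mean_speed: float = 0.0
    symmetry_missing: bool = False  # True when no opposite-direction neighbour existed
    run_id: str = "run"
    turn_index: int = 0
    skier_id: str = "unknown"

    def __post_init__(self):
        for name in VARIABLES:
            vec = _as_float_array(getattr(self, name), name)
            if vec.shape != (N_POINTS,):
                raise DimensionError(
                    f"{name} must have exactly {N_POINTS} points, got {vec.shape}"
                )
            setattr(self, name, vec)
        if np.any(self.speed < 0):
            raise ValidationError("speed entries must be non-negative")
        if self.style not in STYLES:
            raise ValidationError(f"unknown style {self.style!r}")
        if self.size not in SIZES:
            raise ValidationError(f"unknown size {self.size!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")

    def variable(self, name: str) -> np.ndarray:
        if name not in VARIABLES:
            raise ValidationError(f"unknown variable {name!r}")
        return getattr(self, name)


@dataclass
class VariableModel:
    """PCA reference model for one (style, size, variable) cell.

    ``loadings`` rows are the first three principal-component loading
    vectors of the centered n x 101 reference matrix (orthonormal);
    ``varfrac`` the fractions of *total* variance they explain;
    ``score_sd`` the SDs (ddof=1) of the reference PC scores, which define
    the Z-scale for new turns.  Components beyond the matrix rank carry
    varfrac 0 and a sentinel score_sd of 1 (they never contribute:
    Z is defined as 0 where varfrac is 0).
    """

    mean_curve: np.ndarray
    loadings: np.ndarray
    varfrac: np.ndarray
    score_sd: np.ndarray
    n_ref: int
    n_effective: int = 3  # number of genuine (non-padded) components

    def __post_init__(self):
        self.mean_curve = _as_float_array(self.mean_curve, "mean_curve")
        self.loadings = _as_float_array(self.loadings, "loadings")
        self.varfrac = _as_float_array(self.varfrac, "varfrac")
        self.score_sd = _as_float_array(self.score_sd, "score_sd")
        k = self.loadings.shape[0]
        if self.mean_curve.shape != (N_POINTS,):
            raise DimensionError("mean_curve must have 101 points")
        if self.loadings.shape != (k, N_POINTS):
            raise DimensionError("loadings must be k x 101")
        if self.varfrac.shape != (k,) or self.score_sd.shape != (k,):
            raise DimensionError("varfrac and score_sd must have one entry per PC")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValidationError("loading vectors are not orthonormal within 1e-8")
        if np.any(np.diff(self.varfrac) > 1e-12):
            raise ValidationError("variance fractions must be non-increasing")
        if self.varfrac.sum() > 1 + 1e-9 or np.any(self.varfrac < -1e-12):
            raise ValidationError("variance fractions must lie in [0, 1] and sum <= 1")
        if np.any(self.score_sd <= 0):
            raise ValidationError("score SDs must be strictly positive")
        if not 0 <= self.n_effective <= k:
            raise ValidationError("n_effective out of range")


@dataclass
class ReferenceModel:
    """Persisted gold-standard model: (style, size, variable) -> VariableModel."""

    cells: dict
    schema_version: str = "1"
    fit_config: dict = field(default_factory=dict)

    def __post_init__(self):
        for key, vm in self.cells.items():
            style, size, variable = key
            if style not in SCORED_STYLES:
                raise ValidationError(f"model cells only cover {SCORED_STYLES}, got {style!r}")
            if size not in SIZES or variable not in VARIABLES:
                raise ValidationError(f"bad cell key {key!r}")
            if not isinstance(vm, VariableModel):
                raise ValidationError("cell values must be VariableModel instances")
        # every fitted (style, size) group must carry all four variables
        for style, size in {(s, z) for s, z, _ in self.cells}:
            missing = [v for v in VARIABLES if (style, size, v) not in self.cells]
            if missing:
                raise ValidationError(
                    f"cell ({style}, {size}) incomplete: missing {missing}"
                )

    def groups(self):
        """Sorted (style, size) pairs with a complete set of variables."""
        return sorted({(s, z) for s, z, _ in self.cells})

    def has_group(self, style: str, size: str) -> bool:
        return (style, size, "edge_angle") in self.cells


@dataclass
class TurnScore:
    """Scoring result for one turn: Z-scores, bins, sub-scores, final 1-10 score."""

    style: str
    size: str
    z: dict = field(default_factory=dict)          # variable -> (3,) absolute Z
    bins: dict = field(default_factory=dict)       # variable -> (3,) ints in 1..4
    subscores: dict = field(default_factory=dict)  # variable -> weighted sum
    percentage: Optional[float] = None             # in [25, 100] for scored styles
    final_score: Optional[float] = None            # on the 1-10 scale
    flags: tuple = ()
    reason: Optional[str] = None                   # set when unscorable
    run_id: str = "run"
    turn_index: int = 0
    skier_id: str = "unknown"

    @property
    def scorable(self) -> bool:
        return self.final_score is not None


@dataclass
class SyntheticParams:
    """Parameters of the synthetic run/cohort generators.

    ``mode_sigmas`` holds three SDs per variable (magnitude, timing,
    double-peak modes); ``noise_sd`` the white-noise SD per variable in the
    variable's own units; ``skill_offset`` shifts every mode-coefficient
    draw by that many mode SDs (0 = reference-like skier).
    """

    n_turns: int = 12
    turn_period: float = 2.0  # s
    mode_sigmas: dict = field(
        default_factory=lambda: {
            "edge_angle": (8.0, 3.0, 1.5),     # degrees
            "symmetry": (4.0, 2.0, 1.0),       # degrees
            "radial_force": (0.30, 0.12, 0.06),  # body weights
            "speed": (1.5, 0.5, 0.2),          # m/s
        }
    )
    noise_sd: dict = field(
        default_factory=lambda: {
            "edge_angle": 0.8,
            "symmetry": 0.4,
            "radial_force": 0.03,
            "speed": 0.15,
        }
    )
    skill_offset: float = 0.0
    # raw-sensor noise levels
    gyro_noise_dps: float = 1.0
    accel_noise_g: float = 0.02
    gnss_noise_mps: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if self.turn_period <= 0:
            raise ValidationError("turn_period must be positive")
        for var in VARIABLES:
            sig = self.mode_sigmas[var]
            if len(sig) != 3 or any(s <= 0 for s in sig):
                raise ValidationError(f"mode_sigmas[{var!r}] must be 3 positive SDs")
            if self.noise_sd[var] < 0:
                raise ValidationError("noise_sd must be non-negative")
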