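"""Per-turn variable enrichment: edge angle, symmetry, radial force, speed.

These are deliberately simple estimators built only on the boot IMU and the
1 Hz GNSS track:

* edge angle — boot roll relative to gravity from a complementary filter
  fusing the integrated roll-rate gyro with the accelerometer roll
  (``atan2(ax, ay)``); the reported edge angle is the magnitude ``|theta|``
  of the outside boot of the turn.
* edge-angle symmetry — signed pointwise difference between the current
  turn's edge-angle profile and the previous opposite-direction turn's, on
  the common 101-point base (the following opposite turn for the first
  scored turn of a run).
* radial force — quasi-static centripetal estimate ``v * |omega_yaw| / g``
  in multiples of body weight.
* speed — the 1 Hz GNSS speed linearly interpolated to the IMU timestamps.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from . import classify
from .config import Config
from .errors import (
    DimensionError,
    EmptyInputError,
    SegmentRangeError,
    ValidationError,
)
from .types import (
    GRAVITY,
    N_POINTS,
    EnrichedTurn,
    GnssTrack,
    RawRun,
    SensorStream,
    TurnSegment,
)
from .preprocess import time_normalize


def _segment_slice(stream: SensorStream, segment: TurnSegment):
    mask = (stream.timestamps >= segment.start_time) & (
        stream.timestamps <= segment.end_time)
    if mask.sum() < 2:
        raise SegmentRangeError(
            f"segment [{segment.start_time:.2f}, {segment.end_time:.2f}] s "
            f"not covered by the {stream.side} stream")
    return mask


def estimate_edge_angle(stream: SensorStream, segment: TurnSegment,
                        alpha: float = 0.98):
    """Boot roll magnitude (deg) over a segment via a complementary filter.

    theta_t = alpha * (theta_{t-1} + omega_roll * dt) + (1 - alpha) * theta_acc,t
    with theta_acc = atan2(ax, ay) in degrees, initialised at the first
    accelerometer estimate.  Returns ``(times, |theta|)``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("complementary-filter alpha must lie in (0, 1)")
    mask = _segment_slice(stream, segment)
    t = stream.timestamps[mask]
    roll_rate = stream.roll_rate_dps[mask]
    ax = stream.accel[mask, 0]
    ay = stream.accel[mask, 1]
    theta_acc = np.degrees(np.arctan2(ax, ay))
    theta = np.empty_like(theta_acc)
    theta[0] = theta_acc[0]
    dt = np.diff(t)
    for i in range(1, len(theta)):
        theta[i] = alpha * (theta[i - 1] + roll_rate[i] * dt[i - 1]) \
            + (1 - alpha) * theta_acc[i]
    return t, np.abs(theta)


def estimate_symmetry(current: np.ndarray,
                      previous_opposite: Optional[np.ndarray]):
    """Signed edge-angle difference to the neighbouring opposite-direction turn.

    Returns ``(vector, missing)`` where ``missing`` flags that no neighbour
    existed (the vector is then all zeros).
    """
    current = np.asarray(current, float)
    if current.shape != (N_POINTS,):
        raise DimensionError("symmetry inputs must have 101 points")
    if previous_opposite is None:
        return np.zeros(N_POINTS), True
    previous_opposite = np.asarray(previous_opposite, float)
    if previous_opposite.shape != (N_POINTS,):
        raise DimensionError("symmetry inputs must have 101 points")
    return current - previous_opposite, False


def estimate_radial_force(speed_mps: np.ndarray,
                          yaw_rate_rads: np.ndarray) -> np.ndarray:
    """Radial force in body weights: F/BW = v * |omega_yaw| / g, pointwise."""
    speed_mps = np.asarray(speed_mps, float)
    yaw_rate_rads = np.asarray(yaw_rate_rads, float)
    if speed_mps.shape != yaw_rate_rads.shape:
        raise ValidationError("speed and yaw-rate series differ in length")
    if np.any(speed_mps < 0):
        raise ValidationError("speeds must be non-negative")
    return speed_mps * np.abs(yaw_rate_rads) / GRAVITY


def interpolate_speed(gnss: GnssTrack, target_times: np.ndarray) -> np.ndarray:
    """Linear interpolation of the 1 Hz GNSS speed onto IMU times (edges clamped)."""
    if len(gnss.timestamps) == 0:
        raise EmptyInputError("GNSS track is empty")
    return np.interp(np.asarray(target_times, float), gnss.timestamps, gnss.speed)


def outside_stream(run: RawRun, direction: str) -> SensorStream:
    """Outside boot of a turn: a left turn loads the right ski/boot."""
    return run.right if direction == "left" else run.left


def edge_angle_vector(run: RawRun, segment: TurnSegment,
                      config: Optional[Config] = None) -> np.ndarray:
    """Time-normalized 101-point edge-angle profile for one segment."""
    config = config or Config()
    alpha = config.enrich.alpha
    if config.enrich.edge_boot == "mean":
        vecs = []
        for stream in (run.left, run.right):
            t, theta = estimate_edge_angle(stream, segment, alpha)
            vecs.append(time_normalize(theta, t))
        return np.mean(vecs, axis=0)
    stream = outside_stream(run, segment.direction)
    t, theta = estimate_edge_angle(stream, segment, alpha)
    return time_normalize(theta, t)


def enrich_turn(run: RawRun, segment: TurnSegment,
                neighbours: Optional[dict] = None,
                style_label: Optional[str] = None,
                config: Optional[Config] = None,
                edge: Optional[np.ndarray] = None,
                turn_index: int = 0) -> EnrichedTurn:
    """Compute the four 101-point variables and labels for one retained turn.

    ``neighbours`` may hold ``prev_opposite`` / ``next_opposite`` 101-point
    edge-angle profiles of the adjacent opposite-direction turns; the
    previous one is preferred for symmetry, the following one is the
    fallback for the first scored turn of a run.
    """
    config = config or Config()
    neighbours = neighbours or {}
    if edge is None:
        edge = edge_angle_vector(run, segment, config)

    stream = outside_stream(run, segment.direction)
    mask = _segment_slice(stream, segment)
    t = stream.timestamps[mask]
    yaw_rads = np.radians(stream.yaw_rate_dps[mask])
    v = interpolate_speed(run.gnss, t)
    speed = time_normalize(v, t)
    radial = time_normalize(estimate_radial_force(v, yaw_rads), t)

    opposite = neighbours.get("prev_opposite")
    if opposite is None:
        opposite = neighbours.get("next_opposite")
    symmetry, missing = estimate_symmetry(edge, opposite)

    mean_speed = float(np.mean(v))
    mean_yaw = float(np.mean(np.abs(yaw_rads)))
    if config.classify.size_from == "run" and run.intended_style:
        from .types import RUN_CODES
        size = RUN_CODES[run.intended_style][1]
    else:
        size = classify.assign_size(mean_speed, mean_yaw)
    if style_label is None and config.classify.style_from == "intended" \
            and run.intended_style:
        from .types import RUN_CODES
        style_label = RUN_CODES[run.intended_style][0]
    style = classify.classify_style(
        edge, radial, provided_label=style_label,
        carve_angle_min=config.classify.carve_angle_min)

    return EnrichedTurn(
        edge_angle=edge, symmetry=symmetry, radial_force=radial,
        speed=np.maximum(speed, 0.0), style=style, size=size,
        direction=segment.direction, mean_speed=mean_speed,
        symmetry_missing=missing, run_id=run.run_id, turn_index=turn_index,
        skier_id=run.skier_id)
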