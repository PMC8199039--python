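"""Turn segmentation and time normalization.

Under the pendulum model of skiing the legs roll side to side once per
turn, so the boot roll-rate signal shows one prominent extremum of
alternating sign at every edge change.  A turn is the span between two
consecutive extrema.  The first and last detected turn of a run, and turns
slower than median - MAD of the run's interior turn speeds, are excluded
before any variable enters the scoring model.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .config import SegmentationConfig
from .errors import InsufficientDataError, ValidationError
from .types import N_POINTS, GnssTrack, TurnSegment

log = logging.getLogger(__name__)


def lowpass_roll(timestamps: np.ndarray, roll_dps: np.ndarray,
                 cutoff_hz: float) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass of the roll-rate signal."""
    fs = 1.0 / float(np.median(np.diff(timestamps)))
    if cutoff_hz >= fs / 2:
        return np.asarray(roll_dps, float)
    b, a = butter(2, cutoff_hz / (fs / 2))
    padlen = 3 * max(len(a), len(b))  # filtfilt's default pad length
    if len(roll_dps) <= padlen:
        raise InsufficientDataError(
            f"series of {len(roll_dps)} samples is shorter than the filter warm-up"
        )
    return filtfilt(b, a, roll_dps)


def _alternating_extrema(filtered: np.ndarray, prominence: float,
                         distance: int) -> list:
    """Indices/signs of alternating-sign extrema; same-sign runs keep the largest."""
    pos, _ = find_peaks(filtered, prominence=prominence, distance=distance)
    neg, _ = find_peaks(-filtered, prominence=prominence, distance=distance)
    extrema = sorted(
        [(int(i), 1) for i in pos] + [(int(i), -1) for i in neg])
    cleaned = []
    for idx, sign in extrema:
        if cleaned and cleaned[-1][1] == sign:
            # consecutive same-sign extrema: keep the more prominent one
            if abs(filtered[idx]) > abs(filtered[cleaned[-1][0]]):
                cleaned[-1] = (idx, sign)
        else:
            cleaned.append((idx, sign))
    return cleaned


def detect_turn_boundaries(timestamps: np.ndarray, roll_dps: np.ndarray,
                           params: Optional[SegmentationConfig] = None,
                           gap_times: Sequence[float] = ()) -> List[TurnSegment]:
    """Segment a run into turns from roll-rate extrema.

    Turn boundaries sit at the alternating-sign extrema of the low-pass
    filtered roll-rate; each turn spans one extremum to the next.  The
    direction of a turn is taken from the sign of the roll rate at its
    starting extremum (positive roll rate = right by the boot-Z
    convention).  Segments spanning a flagged transmission gap are dropped.
    Returns an empty list when no qualifying extrema exist.
    """
    params = params or SegmentationConfig()
    timestamps = np.asarray(timestamps, float)
    roll_dps = np.asarray(roll_dps, float)
    if timestamps.shape != roll_dps.shape:
        raise ValidationError("timestamps and roll series differ in length")
    span = timestamps[-1] - timestamps[0] if len(timestamps) >= 2 else 0.0
    if span <= 2 * params.min_period_s:
        raise InsufficientDataError(
            f"series spans {span:.2f} s; need more than {2 * params.min_period_s:.2f} s"
        )
    filtered = lowpass_roll(timestamps, roll_dps, params.lowpass_hz)
    fs = 1.0 / float(np.median(np.diff(timestamps)))
    distance = max(1, int(round(params.min_period_s * fs)))
    extrema = _alternating_extrema(filtered, params.min_prominence_dps, distance)
    segments: List[TurnSegment] = []
    for (i0, sign0), (i1, _) in zip(extrema[:-1], extrema[1:]):
        t0, t1 = float(timestamps[i0]), float(timestamps[i1])
        if t1 - t0 < params.min_period_s:
            continue
        if any(t0 < g <= t1 for g in gap_times):
            continue
        segments.append(
            TurnSegment(start_time=t0, end_time=t1,
                        direction="right" if sign0 > 0 else "left"))
    return segments


def attach_mean_speeds(segments: List[TurnSegment], gnss: GnssTrack) -> None:
    """Fill each segment's mean speed from linearly interpolated GNSS."""
    for seg in segments:
        t = np.linspace(seg.start_time, seg.end_time, N_POINTS)
        seg.mean_speed = float(
            np.mean(np.interp(t, gnss.timestamps, gnss.speed)))


def filter_turns(segments: List[TurnSegment], mad_rule: bool = True
                 ) -> List[TurnSegment]:
    """Apply the turn-exclusion rules.

    The first and last detected turn of the run are always removed (the
    skier is accelerating/decelerating there).  Among the interior turns a
    turn is removed iff its mean speed is strictly below
    ``median(speeds) - MAD(speeds)``, where MAD is the raw median absolute
    deviation (no consistency constant) over the interior turns.  With
    fewer than three segments an empty list is returned with a warning.
    """
    if len(segments) < 3:
        log.warning("only %d segment(s); need >= 3 to retain any turn",
                    len(segments))
        return []
    interior = segments[1:-1]
    if not mad_rule:
        return list(interior)
    speeds = np.array([s.mean_speed for s in interior], float)
    if np.any(np.isnan(speeds)):
        raise ValidationError("mean_speed missing on a segment; "
                              "call attach_mean_speeds first")
    median = float(np.median(speeds))
    mad = float(np.median(np.abs(speeds - median)))
    threshold = median - mad
    return [s for s in interior if not s.mean_speed < threshold]


def time_normalize(values: np.ndarray, times: Optional[np.ndarray] = None
                   ) -> np.ndarray:
    """Linearly resample a turn's samples onto 101 points over 0-100 % duration.

    Endpoints are preserved exactly.  When ``times`` is omitted the samples
    are assumed evenly spaced.
    """
    values = np.asarray(values, float)
    if values.ndim != 1 or len(values) < 2:
        raise InsufficientDataError("time_normalize needs at least 2 samples")
    if times is None:
        times = np.arange(len(values), dtype=float)
    else:
        times = np.asarray(times, float)
        if times.shape != values.shape:
            raise ValidationError("times and values differ in length")
    target = np.linspace(times[0], times[-1], N_POINTS)
    out = np.interp(target, times, values)
    out[0], out[-1] = values[0], values[-1]
    return out
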