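"""Turn style and size assignment.

Style labels from an external classifier (or protocol bookkeeping) are
always taken verbatim when provided.  Without a label a deliberately naive
demonstration rule is applied: a turn counts as carving when its mean edge
angle is high and its radial-force waveform is single-peaked, otherwise as
drifting; the naive rule never emits ``non_parallel``.

Turn size follows the quasi-static radius estimate r = v / omega from mean
speed and mean yaw rate, with the snow-cat-width class boundaries:
large > 12 m, medium 8-12 m, small < 8 m.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import ValidationError
from .types import STYLES

log = logging.getLogger(__name__)

LARGE_RADIUS_M = 12.0
SMALL_RADIUS_M = 8.0


def estimate_turn_radius(mean_speed: float, mean_yaw_rads: float) -> float:
    """Quasi-static turn radius r = v / omega (m); inf for straight glides."""
    if mean_speed < 0:
        raise ValidationError("mean speed must be non-negative")
    if mean_yaw_rads <= 0:
        return float("inf")
    return mean_speed / mean_yaw_rads


def assign_size(mean_speed: float, mean_yaw_rads: float) -> str:
    """small | medium | large from the estimated radius (medium band [8, 12] m)."""
    r = estimate_turn_radius(mean_speed, mean_yaw_rads)
    if not np.isfinite(r):
        log.warning("zero mean yaw rate: straight glide classified as large")
        return "large"
    if r > LARGE_RADIUS_M:
        return "large"
    if r < SMALL_RADIUS_M:
        return "small"
    return "medium"


def is_single_peaked(waveform: np.ndarray, rel_prominence: float = 0.15) -> bool:
    """True when a 101-point waveform has exactly one prominent interior peak."""
    waveform = np.asarray(waveform, float)
    span = float(waveform.max() - waveform.min())
    if span <= 0:
        return False
    peaks, _ = find_peaks(waveform, prominence=rel_prominence * span)
    return len(peaks) == 1


def classify_style(edge_angle: np.ndarray, radial_force: np.ndarray,
                   provided_label: Optional[str] = None,
                   carve_angle_min: float = 30.0) -> str:
    """Return a provided label verbatim, else apply the naive carving rule."""
    if provided_label is not None:
        if provided_label not in STYLES:
            raise ValidationError(
                f"unknown style label {provided_label!r}; expected one of {STYLES}")
        return provided_label
    edge_angle = np.asarray(edge_angle, float)
    if float(np.mean(edge_angle)) >= carve_angle_min and is_single_peaked(radial_force):
        return "carving"
    return "drifting"
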