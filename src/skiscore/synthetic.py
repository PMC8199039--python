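"""Seeded synthetic data with ground truth.

Two generators make every pipeline stage testable without field data:

* ``generate_turn_curves`` / ``generate_cohort`` build enriched turns
  directly on the 101-point base as ``mean + sum_k a_k * phi_k + noise``,
  with three orthogonal variability modes per variable — a magnitude mode,
  a timing-shift mode and a single-vs-double-peak mode — and coefficients
  ``a_k ~ Normal(skill_offset * sigma_k, sigma_k^2)``.  The true mode
  coefficients are returned so parameter-recovery and scoring tests have
  an oracle.
* ``generate_raw_run`` builds a two-boot IMU + GNSS run from the pendulum
  model: the signed boot roll follows ``A_k * sin(pi * tau)`` within each
  turn with alternating sign, so the roll-rate gyro shows one
  alternating-sign pulse per turn transition.  Accelerometer, yaw-rate and
  GNSS channels are generated consistently; true boundary times and
  per-turn mean speeds are returned for segmentation tests.

For the bell-shaped variables the modes are the harmonics ``sin(k*pi*tau)``
(k = 1..3), which are exactly orthogonal on the 101-point grid and vanish
at the turn transitions as the pendulum model demands; for the
near-constant speed variable they are the shifted Legendre polynomials
(offset, linear trend, curvature), orthogonalized on the grid.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .types import (
    GRAVITY,
    N_POINTS,
    EnrichedTurn,
    GnssTrack,
    RawRun,
    SensorStream,
    SyntheticParams,
    VARIABLES,
)

TAU = np.linspace(0.0, 1.0, N_POINTS)

#: mean-profile anchors per turn size: (base speed m/s, target radius m)
SIZE_KINEMATICS = {"large": (14.0, 15.0), "medium": (10.0, 10.0),
                   "small": (7.0, 6.0)}
#: peak edge angle (deg) of the mean profile per style
STYLE_PEAK_EDGE = {"carving": 50.0, "drifting": 25.0}


def _gram_schmidt(rows: np.ndarray) -> np.ndarray:
    """Orthogonalize rows in order, then rescale each to unit max magnitude."""
    out = []
    for row in np.asarray(rows, float):
        v = row.copy()
        for u in out:
            v -= (v @ u) / (u @ u) * u
        peak = np.abs(v).max()
        if peak < 1e-12:
            raise ConfigError("degenerate (non-orthogonalizable) mode family")
        out.append(v / peak)
    return np.vstack(out)


def variable_modes(variable: str) -> np.ndarray:
    """The three orthogonal variability modes (3 x 101, unit max magnitude)."""
    if variable == "speed":
        base = np.vstack([
            np.ones(N_POINTS),            # offset (magnitude)
            2 * TAU - 1,                  # linear trend (timing/acceleration)
            6 * TAU ** 2 - 6 * TAU + 1,   # curvature
        ])
    else:
        base = np.vstack([np.sin((k + 1) * np.pi * TAU) for k in range(3)])
    return _gram_schmidt(base)


def variable_mean(variable: str, style: str, size: str) -> np.ndarray:
    """Mean profile of a variable for a (style, size) condition."""
    v0, radius = SIZE_KINEMATICS[size]
    if variable == "edge_angle":
        peak = STYLE_PEAK_EDGE.get(style, 25.0)
        return peak * np.sin(np.pi * TAU)
    if variable == "radial_force":
        peak = v0 ** 2 / (radius * GRAVITY)
        if style != "carving":
            peak *= 0.7  # drifted turns shed speed laterally
        return peak * np.sin(np.pi * TAU) ** 2
    if variable == "speed":
        return v0 * (1.0 - 0.03 * np.sin(np.pi * TAU))
    if variable == "symmetry":
        return np.zeros(N_POINTS)
    raise ConfigError(f"unknown variable {variable!r}")


def generate_turn_curves(params: SyntheticParams, style: str, size: str,
                         rng: Optional[np.random.Generator] = None,
                         direction: str = "left",
                         coefficients: Optional[dict] = None,
                         ) -> Tuple[EnrichedTurn, dict]:
    """One synthetic enriched turn plus its true mode coefficients.

    ``coefficients`` may pin the mode coefficients (dict variable ->
    3-vector) instead of drawing them; noise is still added unless
    ``noise_sd`` is zero.
    """
    rng = rng or np.random.default_rng(params.seed)
    truth = {}
    vectors = {}
    for var in VARIABLES:
        sig = np.asarray(params.mode_sigmas[var], float)
        if coefficients is not None and var in coefficients:
            a = np.asarray(coefficients[var], float)
        else:
            a = rng.normal(params.skill_offset * sig, sig)
        noise = rng.normal(0.0, params.noise_sd[var], N_POINTS) \
            if params.noise_sd[var] > 0 else 0.0
        x = variable_mean(var, style, size) + a @ variable_modes(var) + noise
        truth[var] = a
        vectors[var] = x
    vectors["speed"] = np.maximum(vectors["speed"], 0.0)
    turn = EnrichedTurn(style=style, size=size, direction=direction,
                        mean_speed=float(vectors["speed"].mean()), **vectors)
    return turn, truth


def generate_cohort(params: SyntheticParams, n_turns_per_cell: int,
                    cells: Sequence[Tuple[str, str]], seed: Optional[int] = None,
                    ) -> Tuple[List[EnrichedTurn], List[dict]]:
    """Independent draws of ``generate_turn_curves`` for every cell."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    turns: List[EnrichedTurn] = []
    truths: List[dict] = []
    for style, size in cells:
        for i in range(n_turns_per_cell):
            turn, truth = generate_turn_curves(
                params, style, size, rng,
                direction="left" if i % 2 == 0 else "right")
            turn.turn_index = len(turns)
            turns.append(turn)
            truths.append(truth)
    return turns, truths


def _style_size(style_code: str) -> Tuple[str, str]:
    from .types import RUN_CODES
    return RUN_CODES[style_code]


def generate_raw_run(params: SyntheticParams, seed: Optional[int] = None,
                     style_code: str = "CM",
                     speed_multipliers: Optional[Sequence[float]] = None,
                     fs: float = 54.0, lead_s: float = 2.0,
                     speed_mod: float = 0.0,
                     skier_id: str = "synthetic", run_id: str = "run",
                     ) -> Tuple[RawRun, dict]:
    """A pendulum-model two-boot IMU + GNSS run with ground truth.

    ``speed_multipliers`` (one per turn) scale the speed profile within the
    corresponding turn, e.g. to inject a slow turn that the median-MAD
    exclusion rule must drop.  The within-turn speed modulation
    (``speed_mod``, fraction of base speed at the turn frequency, default
    off) is mean-neutral per turn, so per-turn mean speeds differ only
    through the multipliers and sensor noise; the exclusion rule trims
    roughly a quarter of otherwise-equal turns under any independent
    per-turn speed jitter, so a constant base speed keeps end-to-end turn
    counts deterministic.  Ground truth holds the boundary times,
    per-turn directions and mean speeds, per-turn roll amplitudes and the
    target turn radius.
    """
    if params.n_turns < 3:
        raise ConfigError("need at least 3 turns per run")
    T = params.turn_period
    if T * fs < 4:
        raise ConfigError("turn_period shorter than 4 samples")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    style, size = _style_size(style_code)
    v0, radius = SIZE_KINEMATICS[size]
    n = params.n_turns
    duration = 2 * lead_s + n * T
    t = np.arange(0.0, duration, 1.0 / fs)

    amp = np.clip(
        STYLE_PEAK_EDGE[style]
        + rng.normal(0.0, 0.5 * params.mode_sigmas["edge_angle"][0], n),
        10.0, 65.0)
    mult = np.ones(n) if speed_multipliers is None \
        else np.asarray(speed_multipliers, float)
    if len(mult) != n:
        raise ConfigError("speed_multipliers must hold one factor per turn")

    k = np.floor((t - lead_s) / T).astype(int)
    in_turn = (k >= 0) & (k < n)
    kc = np.clip(k, 0, n - 1)
    tau = np.where(in_turn, (t - lead_s) / T - kc, 0.0)
    sign = np.where(kc % 2 == 0, 1.0, -1.0)

    chi = np.where(in_turn, sign * amp[kc] * np.sin(np.pi * tau), 0.0)  # deg
    roll_rate = np.where(
        in_turn, sign * amp[kc] * (np.pi / T) * np.cos(np.pi * tau), 0.0)
    v = v0 * (1.0 + speed_mod * np.sin(2 * np.pi * (t - lead_s) / T))
    v = np.where(in_turn, v * mult[kc], v0)
    yaw_rad = np.where(
        in_turn, sign * (np.pi / 2) * (v / radius) * np.sin(np.pi * tau), 0.0)

    chi_r = np.radians(chi)

    def boot(side: str) -> SensorStream:
        accel = np.column_stack([
            np.sin(chi_r), np.cos(chi_r), np.zeros_like(chi_r)])
        accel = accel + rng.normal(0.0, params.accel_noise_g, accel.shape)
        gyro = np.column_stack([
            np.zeros_like(t), np.degrees(yaw_rad), roll_rate])
        gyro = gyro + rng.normal(0.0, params.gyro_noise_dps, gyro.shape)
        return SensorStream(
            timestamps=t.copy(),
            accel=np.clip(accel, -16.0, 16.0),
            gyro=np.clip(gyro, -1000.0, 1000.0),
            side=side)

    left = boot("left")
    right = boot("right")
    gnss_t = np.arange(0.0, duration, 1.0)
    gnss_v = np.interp(gnss_t, t, v) + rng.normal(
        0.0, params.gnss_noise_mps, len(gnss_t))
    gnss = GnssTrack(timestamps=gnss_t, speed=np.maximum(gnss_v, 0.0))

    boundaries = lead_s + T * np.arange(n + 1)
    mean_speeds = np.array([
        float(np.mean(v[in_turn & (kc == j)])) for j in range(n)])
    truth = {
        "boundaries": boundaries,
        "directions": ["right" if j % 2 == 0 else "left" for j in range(n)],
        "mean_speeds": mean_speeds,
        "amplitudes": amp,
        "radius": radius,
        "style": style,
        "size": size,
    }
    run = RawRun(left=left, right=right, gnss=gnss, skier_id=skier_id,
                 intended_style=style_code, run_id=run_id)
    return run, truth
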