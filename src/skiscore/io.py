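"""CSV and JSON input/output.

IMU CSV schema (one file per boot): ``time_s, ax_g, ay_g, az_g, gx_dps,
gy_dps, gz_dps``.  GNSS CSV: ``time_s, speed_mps``.  Comma separated,
header row, '.' decimal, UTF-8.  Reference models persist as JSON with an
explicit ``schema_version`` so files stay human-inspectable and diff-able.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    SchemaVersionError,
    ValidationError,
)
from .types import (
    ACCEL_FULL_SCALE_G,
    DEFAULT_BODY_MASS_KG,
    GYRO_FULL_SCALE_DPS,
    GnssTrack,
    RawRun,
    ReferenceModel,
    SensorStream,
    VariableModel,
    VARIABLES,
)

log = logging.getLogger(__name__)

IMU_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps")
GNSS_COLUMNS = ("time_s", "speed_mps")
MODEL_SCHEMA_VERSION = "1"
#: a transmission gap longer than this many nominal intervals is flagged
GAP_FACTOR = 3.0


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        # round_trip parsing: written and re-read floats are bit-identical
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{path} holds no data rows")
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _check_monotone(time_s: np.ndarray, path) -> None:
    diffs = np.diff(time_s)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        raise FormatError(
            f"{path}: timestamp not strictly increasing at row {int(bad[0]) + 1}"
        )


def _clip_channel(values: np.ndarray, full_scale: float, label: str, path,
                  clip: bool) -> np.ndarray:
    over = np.abs(values) > full_scale
    if not over.any():
        return values
    if not clip:
        raise ValidationError(f"{path}: {label} values exceed +/-{full_scale} full scale")
    log.warning(
        "%s: %d %s sample(s) beyond +/-%g clipped to full scale",
        path, int(over.sum()), label, full_scale,
    )
    return np.clip(values, -full_scale, full_scale)


def read_sensor_csv(path, side: str, clip_out_of_range: bool = True) -> SensorStream:
    """Read one boot's IMU CSV, validating and clipping out-of-range samples."""
    df = _read_csv(path, IMU_COLUMNS)
    t = df["time_s"].to_numpy(float)
    _check_monotone(t, path)
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy(float)
    gyro = df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(float)
    accel = _clip_channel(accel, ACCEL_FULL_SCALE_G, "accelerometer", path,
                          clip_out_of_range)
    gyro = _clip_channel(gyro, GYRO_FULL_SCALE_DPS, "gyroscope", path,
                         clip_out_of_range)
    gaps: tuple = ()
    if len(t) >= 3:
        nominal = float(np.median(np.diff(t)))
        idx = np.nonzero(np.diff(t) > GAP_FACTOR * nominal)[0] + 1
        if idx.size:
            gaps = tuple(int(i) for i in idx)
            log.warning("%s: %d transmission gap(s) > %g nominal intervals flagged",
                        path, idx.size, GAP_FACTOR)
    return SensorStream(timestamps=t, accel=accel, gyro=gyro, side=side,
                        gap_indices=gaps)


def read_gnss_csv(path) -> GnssTrack:
    df = _read_csv(path, GNSS_COLUMNS)
    t = df["time_s"].to_numpy(float)
    _check_monotone(t, path)
    return GnssTrack(timestamps=t, speed=df["speed_mps"].to_numpy(float))


def read_run(imu_left_path, imu_right_path, gnss_path, skier_id: str = "unknown",
             intended_style: Optional[str] = None,
             body_mass: float = DEFAULT_BODY_MASS_KG, run_id: str = "run",
             clip_out_of_range: bool = True) -> RawRun:
    """Read and validate the three files of one ski run."""
    return RawRun(
        left=read_sensor_csv(imu_left_path, "left", clip_out_of_range),
        right=read_sensor_csv(imu_right_path, "right", clip_out_of_range),
        gnss=read_gnss_csv(gnss_path),
        skier_id=skier_id,
        intended_style=intended_style,
        body_mass=body_mass,
        run_id=run_id,
    )


def write_sensor_csv(stream: SensorStream, path) -> None:
    df = pd.DataFrame({
        "time_s": stream.timestamps,
        "ax_g": stream.accel[:, 0], "ay_g": stream.accel[:, 1],
        "az_g": stream.accel[:, 2],
        "gx_dps": stream.gyro[:, 0], "gy_dps": stream.gyro[:, 1],
        "gz_dps": stream.gyro[:, 2],
    })
    df.to_csv(path, index=False)


def write_gnss_csv(track: GnssTrack, path) -> None:
    pd.DataFrame({"time_s": track.timestamps, "speed_mps": track.speed}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# reference-model persistence

def _cell_key(style: str, size: str, variable: str) -> str:
    return f"{style}|{size}|{variable}"


def save_model(model: ReferenceModel, path) -> None:
    """Persist a reference model as JSON (full double precision via repr)."""
    payload = {
        "schema_version": model.schema_version,
        "fit_config": model.fit_config,
        "cells": {
            _cell_key(*key): {
                "mean_curve": vm.mean_curve.tolist(),
                "loadings": vm.loadings.tolist(),
                "varfrac": vm.varfrac.tolist(),
                "score_sd": vm.score_sd.tolist(),
                "n_ref": int(vm.n_ref),
                "n_effective": int(vm.n_effective),
            }
            for key, vm in sorted(model.cells.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> ReferenceModel:
    """Load and re-validate a persisted reference model."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from None
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: unknown model schema_version {version!r}; "
            f"this build reads version {MODEL_SCHEMA_VERSION!r}"
        )
    cells = {}
    for key, cell in payload.get("cells", {}).items():
        parts = key.split("|")
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed cell key {key!r}")
        cells[tuple(parts)] = VariableModel(
            mean_curve=np.array(cell["mean_curve"], float),
            loadings=np.array(cell["loadings"], float),
            varfrac=np.array(cell["varfrac"], float),
            score_sd=np.array(cell["score_sd"], float),
            n_ref=int(cell["n_ref"]),
            n_effective=int(cell.get("n_effective", 3)),
        )
    return ReferenceModel(cells=cells, schema_version=version,
                          fit_config=payload.get("fit_config", {}))


# ---------------------------------------------------------------------------
# score tables

def scores_to_frame(scores) -> pd.DataFrame:
    """Flatten TurnScore objects into the documented scores table."""
    rows = []
    for ts in scores:
        row = {
            "run_id": ts.run_id,
            "skier_id": ts.skier_id,
            "turn_index": ts.turn_index,
            "style": ts.style,
            "size": ts.size,
            "percentage": ts.percentage,
            "final_score": ts.final_score,
            "flags": ";".join(ts.flags),
            "reason": ts.reason or "",
        }
        for var in VARIABLES:
            z = ts.z.get(var)
            for k in range(3):
                row[f"{var}_pc{k + 1}_z"] = float(z[k]) if z is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores_csv(scores, path) -> None:
    scores_to_frame(scores).to_csv(path, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    df = _read_csv(path, ("run_id", "final_score"))
    return df


def read_labels_csv(path) -> dict:
    """Read per-turn style labels: columns run_id, turn_index, style."""
    df = _read_csv(path, ("run_id", "turn_index", "style"))
    return {
        (str(r.run_id), int(r.turn_index)): str(r.style)
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# bundled campaign bookkeeping table

def load_cohort_turn_counts() -> pd.DataFrame:
    """Classified-turn counts per participant from the data-collection campaign.

    Columns: participant, experience, group (ref/test) and six style-size
    count columns.  Used to document the participant-wise reference/test
    split of the default gold-standard cohort.
    """
    with resources.files("skiscore").joinpath(
            "data/cohort_turn_counts.csv").open() as fh:
        return pd.read_csv(fh)


def reference_split_share(counts: pd.DataFrame):
    """(reference turns, total turns, reference share in %) of a counts table."""
    count_cols = [c for c in counts.columns if c.startswith(("carving_", "drifting_"))]
    total = int(counts[count_cols].to_numpy().sum())
    ref = int(counts.loc[counts["group"] == "ref", count_cols].to_numpy().sum())
    if total == 0:
        raise EmptyInputError("turn-count table holds no turns")
    return ref, total, 100.0 * ref / total
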