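"""Scoring new turns against the reference model.

A turn's 101-point variable vector is centered by the reference mean and
projected onto the reference loading vectors; each PC score is expressed
as an absolute Z against the reference PC-score SD, discretised into bins
(4 best .. 1 worst), weighted by the PC's fraction of total reference
variance, summed within and across variables, expressed as a percentage
of the attainable maximum and finally mapped onto a single 1-10 scale:
carving turns span 7-10, drifting 3-6, while snowplow and snowplow
steering carry the constant scores 1 and 2.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np

from .errors import (
    DegenerateModelError,
    DimensionError,
    MissingCellError,
    ValidationError,
)
from .types import (
    EnrichedTurn,
    N_POINTS,
    ReferenceModel,
    TurnScore,
    VariableModel,
    VARIABLES,
)

log = logging.getLogger(__name__)

#: upper bin edges of the absolute-Z discretisation; boundary values fall
#: into the lower score (Z = 0.75 scores 3, not 4)
BIN_EDGES = (0.75, 1.5, 3.0)
BIN_MAX = 4

STYLE_BANDS = {"carving": (7.0, 10.0), "drifting": (3.0, 6.0)}
CONSTANT_SCORES = {"snowplow": 1.0, "snowplow_steering": 2.0}


def project(turn_vector: np.ndarray, vm: VariableModel) -> np.ndarray:
    """PC scores of a turn vector: <x - mean_curve, loading_k> for k = 1..3."""
    turn_vector = np.asarray(turn_vector, float)
    if turn_vector.shape != (N_POINTS,):
        raise DimensionError(f"turn vector must have {N_POINTS} points")
    return vm.loadings @ (turn_vector - vm.mean_curve)


def zscore(scores: np.ndarray, vm: VariableModel) -> np.ndarray:
    """Absolute Z of each PC score against the reference SD (0 where varfrac=0)."""
    scores = np.asarray(scores, float)
    if np.any((vm.varfrac > 0) & (vm.score_sd <= 0)):
        raise DegenerateModelError("zero score SD on a PC with non-zero varfrac")
    z = np.abs(scores) / vm.score_sd
    return np.where(vm.varfrac > 0, z, 0.0)


def bin_z(z: float) -> int:
    """Discretise an absolute Z-score: [0,0.75)->4, [0.75,1.5)->3, [1.5,3)->2, [3,inf)->1."""
    if z < 0:
        raise ValidationError("absolute Z-scores cannot be negative")
    for worst, edge in enumerate(BIN_EDGES):
        if z < edge:
            return BIN_MAX - worst
    return 1


def pc_contributions(bins, varfrac) -> np.ndarray:
    """Per-PC contributions bin_k * varfrac_k to a variable sub-score."""
    bins = np.asarray(bins, float)
    varfrac = np.asarray(varfrac, float)
    if bins.shape != varfrac.shape:
        raise ValidationError("bins and varfrac differ in length")
    if np.any((bins < 1) | (bins > BIN_MAX)):
        raise ValidationError("bins must lie in 1..4")
    return bins * varfrac


def variable_subscore(bins, varfrac) -> float:
    """Variance-weighted sub-score of one variable: sum_k bin_k * varfrac_k."""
    return float(pc_contributions(bins, varfrac).sum())


def turn_percentage(subscores: dict, varfracs: dict) -> float:
    """Turn score as a percentage of the attainable maximum across variables.

    The maximum per variable is ``4 * sum_k varfrac_k``; with the minimum
    bin being 1 the percentage lives in [25, 100].
    """
    for var in VARIABLES:
        if var not in subscores or var not in varfracs:
            raise ValidationError(f"missing variable {var!r} in turn scores")
    total = sum(float(subscores[v]) for v in VARIABLES)
    maximum = sum(BIN_MAX * float(np.sum(varfracs[v])) for v in VARIABLES)
    if maximum <= 0:
        raise DegenerateModelError("all variance fractions are zero")
    return 100.0 * total / maximum


def scale_score(pct: float, style: str) -> Tuple[float, Tuple[str, ...]]:
    """Map a turn percentage onto the 1-10 scale for the turn's style.

    Carving spans 7-10 and drifting 3-6 linearly in the percentage;
    snowplow and snowplow steering are the constants 1 and 2.  Non-parallel
    turns have no band of their own and are scored in the drifting band
    with a flag.  Returns ``(score, flags)``.
    """
    if style in CONSTANT_SCORES:
        return CONSTANT_SCORES[style], ()
    if not 0 <= pct <= 100:
        raise ValidationError("percentage must lie in [0, 100]")
    flags: Tuple[str, ...] = ()
    band_style = style
    if style == "non_parallel":
        band_style, flags = "drifting", ("non_parallel_scored_as_drifting",)
    if band_style not in STYLE_BANDS:
        raise ValidationError(f"unknown style {style!r}")
    lo, hi = STYLE_BANDS[band_style]
    return lo + (hi - lo) * pct / 100.0, flags


def score_turn(turn: EnrichedTurn, model: ReferenceModel,
               strict: bool = True) -> TurnScore:
    """Full scoring chain for one enriched turn.

    Snowplow styles bypass the model entirely.  A missing (style, size)
    cell raises ``MissingCellError`` when ``strict``, otherwise returns an
    unscorable ``TurnScore`` carrying the reason.
    """
    meta = dict(style=turn.style, size=turn.size, run_id=turn.run_id,
                turn_index=turn.turn_index, skier_id=turn.skier_id)
    if turn.style in CONSTANT_SCORES:
        return TurnScore(final_score=CONSTANT_SCORES[turn.style], **meta)

    model_style = "drifting" if turn.style == "non_parallel" else turn.style
    if not model.has_group(model_style, turn.size):
        msg = f"no reference cell for ({model_style}, {turn.size})"
        if strict:
            raise MissingCellError(msg)
        return TurnScore(reason=msg, **meta)

    z, bins, subscores, varfracs = {}, {}, {}, {}
    for var in VARIABLES:
        vm = model.cells[(model_style, turn.size, var)]
        zz = zscore(project(turn.variable(var), vm), vm)
        bb = np.array([bin_z(v) for v in zz])
        z[var], bins[var] = zz, bb
        subscores[var] = variable_subscore(bb, vm.varfrac)
        varfracs[var] = vm.varfrac
    pct = turn_percentage(subscores, varfracs)
    final, flags = scale_score(pct, turn.style)
    if turn.symmetry_missing:
        flags = flags + ("symmetry_neighbour_missing",)
    return TurnScore(z=z, bins=bins, subscores=subscores, percentage=pct,
                     final_score=final, flags=flags, **meta)


def score_run(turns, model: ReferenceModel
              ) -> Tuple[List[TurnScore], dict]:
    """Score every turn of a run; unscorable turns carry a reason, not an error.

    The summary reports both the mean and the median of the final scores
    (the validation design compares both against rater scores).
    """
    scores = [score_turn(t, model, strict=False) for t in turns]
    finals = [s.final_score for s in scores if s.scorable]
    summary = {
        "n_turns": len(scores),
        "n_scored": len(finals),
        "n_unscorable": len(scores) - len(finals),
        "mean_score": float(np.mean(finals)) if finals else None,
        "median_score": float(np.median(finals)) if finals else None,
    }
    if not finals:
        summary["reasons"] = sorted({s.reason for s in scores if s.reason})
        log.warning("no scorable turns in run: %s", summary["reasons"])
    return scores, summary
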