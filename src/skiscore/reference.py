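"""Learning the gold-standard reference model.

For every (style, size) group of the reference cohort and each of the four
turn variables, a centered PCA is fitted on the n x 101 matrix of
time-normalized profiles.  The first three loading vectors, their
explained fractions of *total* variance, and the standard deviations of
the reference PC scores together define how far a new turn may wander
from the reference mean before losing points.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import numpy as np

from .config import ModelConfig
from .errors import EmptyModelError, InsufficientReferenceError
from .types import (
    EnrichedTurn,
    N_POINTS,
    ReferenceModel,
    SCORED_STYLES,
    VariableModel,
    VARIABLES,
)

log = logging.getLogger(__name__)


def fit_variable_pca(matrix: np.ndarray, n_components: int = 3,
                     min_ref_turns: int = 10,
                     cell: str = "") -> VariableModel:
    """Centered PCA of one n x 101 reference matrix via SVD.

    Loading signs are fixed so each vector's largest-magnitude element is
    positive.  Rank-deficient matrices are fitted with the available
    components; the remaining slots are padded with orthonormal complement
    directions carrying zero variance fraction and a sentinel score SD of
    1 (``n_effective`` records the genuine component count).
    """
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("reference matrix must be 2-D")
    n, p = X.shape
    if n < min_ref_turns:
        raise InsufficientReferenceError(
            f"{cell or 'cell'}: {n} reference turns < minimum {min_ref_turns}")
    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (n - 1)          # variances along each component
    total_var = float(eigvals.sum())
    # rank tolerance anchored to the data scale, so a constant matrix whose
    # centered residual is pure rounding noise counts as rank 0
    scale = max(1.0, float(np.abs(X).max()))
    tol = max(n, p) * np.finfo(float).eps * max(
        s[0] if len(s) else 0.0, scale)
    rank = int(np.sum(s > tol))
    k_eff = min(n_components, rank)
    if k_eff < n_components:
        log.warning("%s: matrix rank %d < %d components; padding with "
                    "zero-variance directions", cell or "cell", rank, n_components)

    if Vt.shape[0] < n_components:  # cannot happen for p=101, n>=2, but be safe
        extra = np.eye(p)[: n_components - Vt.shape[0]]
        Vt = np.vstack([Vt, extra])
    loadings = Vt[:n_components].copy()
    # deterministic sign convention
    for row in loadings:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1

    scores = Xc @ loadings.T
    varfrac = np.zeros(n_components)
    score_sd = np.ones(n_components)
    if total_var > 0:
        varfrac[:k_eff] = eigvals[:k_eff] / total_var
        sd = scores[:, :k_eff].std(axis=0, ddof=1)
        score_sd[:k_eff] = np.where(sd > 0, sd, 1.0)
    return VariableModel(mean_curve=mean_curve, loadings=loadings,
                         varfrac=varfrac, score_sd=score_sd, n_ref=n,
                         n_effective=k_eff)


def cohort_matrix(turns: Iterable[EnrichedTurn], variable: str) -> np.ndarray:
    return np.vstack([t.variable(variable) for t in turns])


def fit_reference(cohort, config: Optional[ModelConfig] = None
                  ) -> ReferenceModel:
    """Group a cohort by (style, size) and fit all four variables per group.

    Groups below ``min_ref_turns`` are skipped with a warning; styles
    outside carving/drifting are never fitted.  Raises ``EmptyModelError``
    when no group qualifies.
    """
    config = config or ModelConfig()
    cohort = list(cohort)
    if not cohort:
        raise EmptyModelError("empty cohort")
    groups: dict = {}
    for turn in cohort:
        if turn.style in SCORED_STYLES:
            groups.setdefault((turn.style, turn.size), []).append(turn)

    cells = {}
    for (style, size), turns in sorted(groups.items()):
        if len(turns) < config.min_ref_turns:
            log.warning("skipping cell (%s, %s): %d turns < minimum %d",
                        style, size, len(turns), config.min_ref_turns)
            continue
        for variable in VARIABLES:
            cells[(style, size, variable)] = fit_variable_pca(
                cohort_matrix(turns, variable),
                n_components=config.n_components,
                min_ref_turns=config.min_ref_turns,
                cell=f"({style}, {size}, {variable})")
        log.info("fitted cell (%s, %s) on %d turns", style, size, len(turns))
    if not cells:
        raise EmptyModelError(
            f"no (style, size) group reached {config.min_ref_turns} turns")
    return ReferenceModel(
        cells=cells, schema_version="1",
        fit_config={"n_components": config.n_components,
                    "min_ref_turns": config.min_ref_turns,
                    "n_points": N_POINTS})
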