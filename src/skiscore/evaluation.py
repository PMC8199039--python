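"""Validation statistics for score tables.

Pearson correlation with the small/medium/large effect-size bands used in
the validation design (|r| < 0.3 small, 0.3-0.6 medium, >= 0.6 large), a
tie-corrected Kruskal-Wallis comparison of score distributions across
skiers, and the adjusted Fisher-Pearson sample skewness of a score
distribution.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError


def correlation_band(r: float) -> str:
    """small | medium | large interpretation of |r|."""
    r = abs(r)
    if r < 0.3:
        return "small"
    if r < 0.6:
        return "medium"
    return "large"


def pearson_with_band(x, y) -> dict:
    """Pearson r with two-sided p and its effect-size band."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("inputs differ in length")
    if len(x) < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined: an input has zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return {"r": r, "p": float(res.pvalue), "band": correlation_band(r)}


def kruskal_wallis(*groups) -> dict:
    """Tie-corrected Kruskal-Wallis H with chi-square p on k-1 df.

    When every pooled value is identical the test is degenerate and
    ``H = 0, p = 1`` is returned.
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise ValidationError("every group needs at least 1 observation")
    if sum(len(a) for a in arrays) < 3:
        raise ValidationError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"H": 0.0, "p": 1.0}
    H, p = stats.kruskal(*arrays)
    return {"H": float(H), "p": float(p)}


def skewness(scores) -> float:
    """Adjusted Fisher-Pearson standardized third moment of a sample."""
    scores = np.asarray(scores, float)
    if len(scores) < 3:
        raise ValidationError("skewness needs at least 3 observations")
    if np.std(scores, ddof=1) == 0:
        raise UndefinedStatisticError("skewness undefined for zero-SD sample")
    return float(stats.skew(scores, bias=False))
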