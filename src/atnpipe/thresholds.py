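"""Empirical ROC analysis and Youden-index cutoff derivation.

CSF positivity thresholds are derived against amyloid-PET visual-read
status: for each candidate marker the empirical AUC (Mann-Whitney
formulation, ties counted 0.5), a DeLong-variance normal-approximation
confidence interval (deliberately not clipped to [0, 1]) and a two-sided
tie-corrected p-value for AUC ≠ 0.5 are computed, and the cutoff
maximizing the Youden index J = sensitivity + specificity − 1 is selected.

Markers whose AUC does not differ significantly from 0.5 (p ≥ 0.05) are
flagged ``insufficient accuracy`` and no cutoff is recommended; for p-tau
and t-tau the conventional fallback cutoffs (> 61 and > 500 pg/ml) then
apply, carried by :class:`atnpipe.core.ThresholdSet` as configuration
defaults rather than derived quantities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from atnpipe.core import SubjectRecord, ValidationError

__all__ = [
    "Direction",
    "RocResult",
    "DERIVATION_MARKERS",
    "MARKER_DIRECTIONS",
    "roc_auc",
    "youden_cutoff",
    "derive_thresholds",
]

logger = logging.getLogger(__name__)

Direction = Literal["lower_is_positive", "higher_is_positive"]

#: Markers examined when deriving thresholds, with their fixed direction.
MARKER_DIRECTIONS: dict[str, Direction] = {
    "abeta42": "lower_is_positive",
    "ptau": "higher_is_positive",
    "ttau": "higher_is_positive",
    "ttau_abeta_ratio": "higher_is_positive",
    "ptau_abeta_ratio": "higher_is_positive",
}

DERIVATION_MARKERS: tuple[str, ...] = tuple(MARKER_DIRECTIONS)

#: Significance level below which a marker is considered discriminative.
ALPHA = 0.05


@dataclass(frozen=True)
class RocResult:
    """ROC summary for one candidate marker.

    ``ci_low``/``ci_high`` are normal-approximation bounds on the AUC and
    may exceed [0, 1] — they are intentionally left unclipped.  ``youden``
    is exactly ``sensitivity + specificity - 1``.  ``flag`` is ``None`` for
    a discriminative marker, otherwise a short reason such as
    ``"insufficient accuracy"`` or ``"non-discriminative"``.
    """

    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: Direction
    n_positive: int
    n_negative: int
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    youden: float | None = None
    flag: str | None = None
    marker: str | None = None

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "direction": self.direction,
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden": self.youden,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "flag": self.flag,
        }


def _validate_inputs(
    values: Sequence[float], reference: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference)
    if values.shape != reference.shape:
        raise ValidationError(
            f"length mismatch: {values.size} values vs {reference.size} reference labels"
        )
    if values.size == 0:
        raise ValidationError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValidationError("marker values must be finite")
    ref = reference.astype(bool)
    if ref.all() or (~ref).all():
        raise ValidationError("degenerate reference: need at least one positive and one negative")
    return values, ref


def _orient(values: np.ndarray, direction: Direction) -> np.ndarray:
    """Map values to scores where *higher* means *more positive-like*."""
    if direction == "lower_is_positive":
        return -values
    if direction == "higher_is_positive":
        return values
    raise ValidationError(f"unknown direction {direction!r}")


def _auc_from_scores(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    # Mann-Whitney formulation via midranks: ties contribute 0.5
    n1, n0 = scores_pos.size, scores_neg.size
    ranks = stats.rankdata(np.concatenate([scores_pos, scores_neg]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _delong_variance(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """DeLong's variance of the empirical AUC via placement values."""
    n1, n0 = scores_pos.size, scores_neg.size
    # V10[i]: fraction of negatives strictly below positive i, ties 0.5
    v10 = np.array(
        [(np.sum(scores_neg < s) + 0.5 * np.sum(scores_neg == s)) / n0 for s in scores_pos]
    )
    v01 = np.array(
        [(np.sum(scores_pos > s) + 0.5 * np.sum(scores_pos == s)) / n1 for s in scores_neg]
    )
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def _hanley_mcneil_variance(auc: float, n1: int, n0: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)


def _mann_whitney_p(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Two-sided normal-approximation p for AUC ≠ 0.5 with tie correction."""
    n1, n0 = scores_pos.size, scores_neg.size
    pooled = np.concatenate([scores_pos, scores_neg])
    n = n1 + n0
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values tied
        return 1.0
    z = (u - n1 * n0 / 2.0) / math.sqrt(sigma2)
    return float(2.0 * stats.norm.sf(abs(z)))


def roc_auc(
    values: Sequence[float],
    reference: Sequence[int],
    direction: Direction,
    ci_method: str = "delong",
    ci_level: float = 0.95,
) -> RocResult:
    """Empirical AUC with confidence interval and significance.

    Parameters
    ----------
    values
        Marker measurements.
    reference
        Binary PET statuses (truthy = positive), same length as ``values``.
    direction
        Which tail of the marker indicates positivity.
    ci_method
        ``"delong"`` (default) or ``"hanley"`` for the Hanley–McNeil
        binormal-free variance.
    ci_level
        Coverage of the normal-approximation interval.

    Returns
    -------
    RocResult
        AUC, unclipped CI bounds and two-sided p-value; the cutoff fields
        are left unset (see :func:`youden_cutoff`).
    """
    vals, ref = _validate_inputs(values, reference)
    scores = _orient(vals, direction)
    pos, neg = scores[ref], scores[~ref]
    auc = _auc_from_scores(pos, neg)
    if ci_method == "delong":
        var = _delong_variance(pos, neg)
    elif ci_method == "hanley":
        var = _hanley_mcneil_variance(auc, pos.size, neg.size)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(var)
    p = _mann_whitney_p(pos, neg)
    return RocResult(
        auc=float(auc),
        ci_low=float(auc - half),
        ci_high=float(auc + half),
        p_value=p,
        direction=direction,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus ±∞ sentinels."""
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def youden_cutoff(
    values: Sequence[float],
    reference: Sequence[int],
    direction: Direction,
    ci_method: str = "delong",
) -> RocResult:
    """Select the cutoff maximizing the Youden index.

    Candidate cutoffs are midpoints between consecutive distinct observed
    values plus ±∞ sentinels, so the choice is invariant to which side
    tied observations fall on.  Youden ties are broken by higher
    sensitivity, then by the candidate nearer the pooled median.
    Sensitivity is the positivity rate among PET-positives and specificity
    the negativity rate among PET-negatives, with strict-inequality
    positivity per ``direction``.
    """
    vals, ref = _validate_inputs(values, reference)
    base = roc_auc(vals, ref, direction, ci_method=ci_method)
    n1, n0 = int(ref.sum()), int((~ref).sum())
    median = float(np.median(vals))

    cuts = _candidate_cutoffs(vals)
    # vectorised scan: candidates x observations
    if direction == "lower_is_positive":
        called = vals[None, :] < cuts[:, None]
    else:
        called = vals[None, :] > cuts[:, None]
    sens = (called & ref).sum(axis=1) / n1
    spec = (~called & ~ref).sum(axis=1) / n0
    youden_all = sens + spec - 1.0
    dist = np.where(np.isfinite(cuts), np.abs(cuts - median), np.inf)
    # maximise youden, then sensitivity, then proximity to the pooled median
    pick = int(np.lexsort((dist, -sens, -youden_all))[0])
    best_cut, best_sens, best_spec = float(cuts[pick]), float(sens[pick]), float(spec[pick])

    youden = best_sens + best_spec - 1.0
    flag = "non-discriminative" if youden <= 0.0 else None
    return replace(
        base,
        cutoff=best_cut,
        sensitivity=best_sens,
        specificity=best_spec,
        youden=youden,
        flag=flag,
    )


def derive_thresholds(
    pet_subcohort: Sequence[SubjectRecord],
    max_interval_days: int = 365,
    ci_method: str = "delong",
    alpha: float = ALPHA,
) -> dict[str, RocResult]:
    """Derive CSF positivity cutoffs from amyloid-PET visual-read status.

    Every subject needs a ``pet_visual`` read and a complete CSF panel;
    subjects whose LP-PET interval exceeds ``max_interval_days`` are
    excluded with a log entry.  For each marker in
    :data:`DERIVATION_MARKERS` the full ROC summary is computed; markers
    with AUC p-value ≥ ``alpha`` are flagged ``"insufficient accuracy"``
    and their cutoff is withdrawn (no recommendation).

    Returns
    -------
    dict
        Marker name → :class:`RocResult`.
    """
    subjects = list(pet_subcohort)
    if not subjects:
        raise ValidationError("empty PET subcohort")
    usable: list[SubjectRecord] = []
    for s in subjects:
        if s.pet_visual is None:
            raise ValidationError(f"subject {s.subject_id}: missing pet_visual")
        interval = s.lp_pet_interval_days()
        if interval is not None and interval > max_interval_days:
            logger.info(
                "excluding subject %s: LP-PET interval %d d exceeds %d d",
                s.subject_id, interval, max_interval_days,
            )
            continue
        usable.append(s)
    if not usable:
        raise ValidationError("no subjects within the LP-PET interval limit")

    reference = [s.pet_visual == "positive" for s in usable]
    results: dict[str, RocResult] = {}
    for marker, direction in MARKER_DIRECTIONS.items():
        values = [getattr(s.csf, marker) for s in usable]
        res = youden_cutoff(values, reference, direction, ci_method=ci_method)
        if res.p_value >= alpha:
            res = replace(res, cutoff=None, sensitivity=None, specificity=None,
                          youden=None, flag="insufficient accuracy")
        results[marker] = replace(res, marker=marker)
    return results
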