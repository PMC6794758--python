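"""Cohort-level statistics: prevalence tables, group tests, concordance.

Percentages in prevalence tables are computed within each syndrome row and
rounded to one decimal, half away from zero.  Chi-square tests use the
Pearson statistic without continuity correction; Mann-Whitney p-values use
the tie-corrected normal approximation; Spearman correlations use average
ranks with the two-sided t-approximation p-value.  The CSF-PET concordance
is the fraction of subjects whose dichotomized CSF marker agrees with
their amyloid-PET visual read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from atnpipe.core import (
    AtnCategory,
    AtnProfile,
    PROFILE_LABELS,
    SubjectRecord,
    ThresholdSet,
    ValidationError,
    dichotomize,
)

__all__ = [
    "ConcordanceResult",
    "PrevalenceTable",
    "chi_square_contingency",
    "csf_pet_concordance",
    "mann_whitney",
    "prevalence_table",
    "round_half_away",
    "spearman",
]

CATEGORY_COLUMNS = ("NORMAL", "AD_CONTINUUM", "NON_AD")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for printed percentages)."""
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class PrevalenceTable:
    """Syndrome × profile counts with within-row percentages.

    ``counts`` has one row per syndrome (plus a ``Total`` row) and one
    column per profile label, the three categories and ``n``;
    ``percentages`` carries the same layout with one-decimal within-row
    percentages (count / row total × 100).
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame

    def row(self, syndrome: str) -> pd.Series:
        return self.counts.loc[syndrome]


def _percentage_frame(counts: pd.DataFrame) -> pd.DataFrame:
    pct = counts.drop(columns="n").astype(float)
    for idx in pct.index:
        total = counts.loc[idx, "n"]
        pct.loc[idx] = [
            round_half_away(100.0 * c / total, 1) if total else math.nan
            for c in counts.loc[idx, pct.columns]
        ]
    return pct


def prevalence_table(
    classified: Sequence[tuple[SubjectRecord, AtnProfile]],
    split_mci: bool = False,
) -> PrevalenceTable:
    """Tabulate profile and category prevalence per clinical syndrome.

    Parameters
    ----------
    classified
        Pairs of subject record and its AT(N) profile.
    split_mci
        When True, MCI subjects are stratified by their ``sub_syndrome``
        (``aMCI`` vs ``naMCI``) into separate rows.

    Returns
    -------
    PrevalenceTable
        Counts and one-decimal within-row percentages; rows appear in
        first-seen order with a final ``Total`` row.
    """
    classified = list(classified)
    if not classified:
        raise ValidationError("empty classified cohort")

    def row_key(subject: SubjectRecord) -> str:
        if split_mci and subject.syndrome == "MCI":
            sub = subject.sub_syndrome or "MCI"
            if sub not in ("aMCI", "naMCI", "MCI"):
                raise ValidationError(
                    f"subject {subject.subject_id}: unexpected MCI sub-syndrome {sub!r}"
                )
            return sub
        return subject.syndrome

    rows: dict[str, dict[str, int]] = {}
    for subject, profile in classified:
        key = row_key(subject)
        cell = rows.setdefault(key, {lab: 0 for lab in PROFILE_LABELS})
        cell[profile.label] += 1

    columns = list(PROFILE_LABELS) + list(CATEGORY_COLUMNS) + ["n"]
    data = []
    for key, cell in rows.items():
        normal = cell["A-T-(N-)"]
        ad_cont = sum(cell[l] for l in PROFILE_LABELS if l.startswith("A+"))
        non_ad = sum(
            cell[l] for l in PROFILE_LABELS if l.startswith("A-") and l != "A-T-(N-)"
        )
        n = sum(cell.values())
        data.append([*(cell[l] for l in PROFILE_LABELS), normal, ad_cont, non_ad, n])
    counts = pd.DataFrame(data, index=list(rows), columns=columns)
    counts.loc["Total"] = counts.sum(axis=0)
    return PrevalenceTable(counts=counts, percentages=_percentage_frame(counts))


def chi_square_contingency(counts) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r × k count table.

    No continuity correction is applied.  Returns ``(statistic, df, p)``.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2 x 2")
    if np.any(table < 0) or not np.all(np.isfinite(table)):
        raise ValidationError("counts must be non-negative and finite")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValidationError("degenerate table: all-zero row or column")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney(group1: Sequence[float], group2: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with two-sided tie-corrected normal-approximation p."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("both groups must be non-empty")
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between amyloid-PET visual reads and a dichotomized CSF marker.

    ``n_pp``: PET-positive with pathologic CSF; ``n_pn``: PET-positive with
    normal CSF; ``n_np``: PET-negative with pathologic CSF; ``n_nn``:
    PET-negative with normal CSF.  ``concordance`` is
    ``(n_pp + n_nn) / n``.  ``cells`` maps each cell name to the subject
    ids it contains.
    """

    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int
    cells: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.n_pp + self.n_pn + self.n_np + self.n_nn

    @property
    def concordance(self) -> float:
        return (self.n_pp + self.n_nn) / self.n

    @property
    def sensitivity(self) -> float:
        """CSF positivity rate among PET-positives."""
        return self.n_pp / (self.n_pp + self.n_pn)

    @property
    def specificity(self) -> float:
        """CSF negativity rate among PET-negatives."""
        return self.n_nn / (self.n_np + self.n_nn)


def _csf_positive(subject: SubjectRecord, thresholds: ThresholdSet, marker: str) -> bool:
    if marker == "abeta42":
        return subject.csf.abeta42 < thresholds.abeta_cut
    if marker == "ptau_abeta_ratio":
        return subject.csf.ptau_abeta_ratio > thresholds.ratio_cut
    raise ValidationError(f"unsupported concordance marker {marker!r}")


def csf_pet_concordance(
    pet_subcohort: Sequence[SubjectRecord],
    thresholds: ThresholdSet | None = None,
    marker: str = "abeta42",
) -> ConcordanceResult:
    """Cross-tabulate PET visual reads against a dichotomized CSF marker.

    Every subject must carry a ``pet_visual`` read; ``marker`` is either
    ``"abeta42"`` (pathologic when strictly below ``abeta_cut``) or
    ``"ptau_abeta_ratio"`` (pathologic when strictly above ``ratio_cut``).
    """
    thresholds = thresholds or ThresholdSet()
    subjects = list(pet_subcohort)
    if not subjects:
        raise ValidationError("empty PET subcohort")
    cells: dict[str, list[str]] = {"pp": [], "pn": [], "np": [], "nn": []}
    for s in subjects:
        if s.pet_visual is None:
            raise ValidationError(f"subject {s.subject_id}: missing pet_visual")
        pet_pos = s.pet_visual == "positive"
        csf_pos = _csf_positive(s, thresholds, marker)
        key = ("p" if pet_pos else "n") + ("p" if csf_pos else "n")
        cells[key].append(s.subject_id)
    return ConcordanceResult(
        n_pp=len(cells["pp"]),
        n_pn=len(cells["pn"]),
        n_np=len(cells["np"]),
        n_nn=len(cells["nn"]),
        cells=cells,
    )
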