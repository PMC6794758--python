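"""Synthetic cohort generators.

Two complementary generators make every pipeline stage testable without
patient-level data:

* :func:`generate_fixture` emits a cohort realising an exact
  (syndrome × profile) count grid — by default the published 628-subject
  grid of a memory-clinic cohort — by placing each subject's CSF values
  strictly on the required side of each default cutoff.  Classifying the
  output reproduces the input grid exactly, making the generator /
  classifier / tabulator loop an identity on count grids.

* :func:`generate_distributional` emits a PET subcohort with
  amyloid-PET-positive (aP+) and negative (aP−) groups whose Aβ1-42,
  t-tau, p-tau and GM-mean SUVR marginals follow truncated normal
  distributions with published group means and SDs, coupled through a
  Gaussian copula so that Aβ1-42 and SUVR are negatively rank-correlated
  within each group while the marginals stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from atnpipe.core import (
    CsfPanel,
    PROFILE_LABELS,
    SubjectRecord,
    ThresholdSet,
    ValidationError,
)

__all__ = [
    "TABLE_GRID",
    "DEMOGRAPHICS",
    "FixtureSpec",
    "DistributionalSpec",
    "generate_fixture",
    "generate_distributional",
]

#: Default (syndrome × profile) count grid: the 628-subject clinical cohort.
#: Columns follow :data:`atnpipe.core.PROFILE_LABELS` order.
TABLE_GRID: dict[str, tuple[int, ...]] = {
    "AD": (1, 56, 34, 118, 7, 5, 1, 7),
    "FTD": (39, 11, 7, 9, 1, 15, 4, 21),
    "LBD": (13, 9, 4, 3, 2, 2, 1, 3),
    "PSP_CBS": (9, 1, 0, 2, 0, 0, 0, 0),
    "PD": (4, 1, 0, 0, 0, 0, 0, 0),
    "VAD_MIXED": (17, 16, 6, 8, 0, 10, 0, 10),
    "OTHER": (15, 7, 1, 2, 0, 1, 1, 3),
    "MCI": (27, 35, 18, 25, 4, 11, 0, 12),
    "CU": (7, 2, 0, 0, 0, 0, 0, 0),
}

#: Per-syndrome (age mean, age SD, male fraction) used as realistic filler.
DEMOGRAPHICS: dict[str, tuple[float, float, float]] = {
    "AD": (72.0, 8.0, 96 / 229),
    "FTD": (73.0, 7.0, 61 / 107),
    "LBD": (76.0, 5.0, 20 / 37),
    "PSP_CBS": (69.0, 7.0, 6 / 12),
    "PD": (62.0, 18.0, 2 / 5),
    "VAD_MIXED": (76.0, 6.0, 37 / 67),
    "OTHER": (73.0, 8.0, 0.5),
    "MCI": (73.0, 7.0, 62 / 132),
    "CU": (69.0, 6.0, 8 / 9),
}

#: MCI row split into amnestic vs non-amnestic, per profile (sums to the
#: MCI row); derived by largest-remainder apportionment of the 99:33 split.
_MCI_SPLIT: dict[str, tuple[int, ...]] = {
    "aMCI": (20, 26, 14, 19, 3, 8, 0, 9),
    "naMCI": (7, 9, 4, 6, 1, 3, 0, 3),
}

# physiological caps bounding the uniform draws (pg/ml)
_CAPS = {"abeta42": 2000.0, "ttau": 2500.0, "ptau": 300.0}
_FLOORS = {"abeta42": 100.0, "ttau": 50.0, "ptau": 5.0}


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of an exact-count fixture cohort.

    ``counts`` maps syndrome → per-profile counts (profile order as in
    :data:`atnpipe.core.PROFILE_LABELS`); ``value_margin`` is the
    fractional distance from each cutoff kept when placing values, so a
    margin of 0.1 draws A+ Aβ1-42 values at or below 0.9 × 660 pg/ml.
    """

    counts: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: dict(TABLE_GRID)
    )
    seed: int = 0
    value_margin: float = 0.1

    def __post_init__(self) -> None:
        for syndrome, row in self.counts.items():
            if len(row) != len(PROFILE_LABELS):
                raise ValidationError(
                    f"{syndrome}: expected {len(PROFILE_LABELS)} profile counts"
                )
            if any(c < 0 or int(c) != c for c in row):
                raise ValidationError(f"{syndrome}: counts must be non-negative integers")
        if not 0 < self.value_margin < 1:
            raise ValidationError("value_margin must lie in (0, 1)")


def _draw_value(
    rng: np.random.Generator, marker: str, cut: float, positive: bool,
    margin: float, lower_is_positive: bool,
) -> float:
    """Uniform draw strictly on the requested side of the cutoff."""
    below = positive if lower_is_positive else not positive
    if below:
        lo, hi = _FLOORS[marker], cut * (1.0 - margin)
    else:
        lo, hi = cut * (1.0 + margin), _CAPS[marker]
    if lo >= hi:
        raise ValidationError(f"infeasible draw window for {marker}")
    return float(rng.uniform(lo, hi))


def generate_fixture(spec: FixtureSpec | None = None) -> list[SubjectRecord]:
    """Generate a cohort realising an exact (syndrome × profile) count grid.

    For each grid cell exactly ``count`` subjects are emitted whose CSF
    values lie strictly on the profile's side of the default cutoffs
    (Aβ1-42 660, p-tau 61, t-tau 500 pg/ml), offset by ``value_margin``.
    Ages and sexes are sampled from per-syndrome summaries as filler.
    Output is reproducible under a fixed seed, and classifying it with the
    default thresholds reproduces the input grid exactly.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    cuts = ThresholdSet()
    subjects: list[SubjectRecord] = []
    counter = 0
    for syndrome, row in spec.counts.items():
        age_mean, age_sd, male_frac = DEMOGRAPHICS.get(syndrome, (72.0, 8.0, 0.5))
        mci_split = syndrome == "MCI" and tuple(row) == TABLE_GRID["MCI"]
        for profile_idx, (label, count) in enumerate(zip(PROFILE_LABELS, row)):
            a = label[1] == "+"
            t = label[3] == "+"
            n = label[6] == "+"
            amci_quota = _MCI_SPLIT["aMCI"][profile_idx] if mci_split else 0
            for k in range(int(count)):
                counter += 1
                csf = CsfPanel(
                    abeta42=_draw_value(rng, "abeta42", cuts.abeta_cut, a,
                                        spec.value_margin, lower_is_positive=True),
                    ptau=_draw_value(rng, "ptau", cuts.ptau_cut, t,
                                     spec.value_margin, lower_is_positive=False),
                    ttau=_draw_value(rng, "ttau", cuts.ttau_cut, n,
                                     spec.value_margin, lower_is_positive=False),
                )
                sub_syndrome = None
                if mci_split:
                    sub_syndrome = "aMCI" if k < amci_quota else "naMCI"
                subjects.append(
                    SubjectRecord(
                        subject_id=f"S{counter:04d}",
                        syndrome=syndrome,
                        sub_syndrome=sub_syndrome,
                        csf=csf,
                        age=float(np.clip(rng.normal(age_mean, age_sd), 40.0, 95.0)),
                        sex="M" if rng.random() < male_frac else "F",
                    )
                )
    return subjects


@dataclass(frozen=True)
class DistributionalSpec:
    """Specification of a two-group (aP+/aP−) distributional PET subcohort.

    Marker marginals are truncated normals (truncated strictly above 0)
    with per-status means and SDs; the defaults are the published aP+/aP−
    group summaries of the 44-subject PET-LP subcohort.  ``coupling`` is
    the within-group Gaussian-copula correlation between Aβ1-42 and
    GM-mean SUVR (negative: more amyloid deposition, less CSF Aβ1-42);
    ``tau_coupling`` correlates t-tau with p-tau.
    """

    n: int = 44
    prevalence_ap: float = 37 / 44
    # (mean, sd) per marker, keyed by PET status
    ap_pos: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "abeta42": (542.2, 119.2),
            "ttau": (700.5, 493.3),
            "ptau": (83.9, 38.5),
            "suvr": (1.47, 0.21),
        }
    )
    ap_neg: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "abeta42": (842.3, 341.9),
            "ttau": (681.3, 593.1),
            "ptau": (67.0, 31.8),
            "suvr": (0.98, 0.10),
        }
    )
    coupling: float = -0.4
    tau_coupling: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        if not 0 <= self.prevalence_ap <= 1:
            raise ValidationError("prevalence_ap must lie in [0, 1]")
        for params in (self.ap_pos, self.ap_neg):
            for marker, (mean, sd) in params.items():
                if sd <= 0 or mean <= 0:
                    raise ValidationError(f"{marker}: mean and SD must be positive")
        if not (-1 < self.coupling < 1 and -1 < self.tau_coupling < 1):
            raise ValidationError("copula correlations must lie in (-1, 1)")


_MARKER_ORDER = ("abeta42", "ttau", "ptau", "suvr")


def _copula_correlation(spec: DistributionalSpec) -> np.ndarray:
    corr = np.eye(4)
    i = {m: k for k, m in enumerate(_MARKER_ORDER)}
    corr[i["abeta42"], i["suvr"]] = corr[i["suvr"], i["abeta42"]] = spec.coupling
    corr[i["ttau"], i["ptau"]] = corr[i["ptau"], i["ttau"]] = spec.tau_coupling
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValidationError("infeasible copula correlation matrix")
    return corr


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float) -> np.ndarray:
    a = (0.0 - mean) / sd  # truncate strictly above zero
    return sps.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def generate_distributional(spec: DistributionalSpec | None = None) -> list[SubjectRecord]:
    """Generate a PET subcohort with the two-group distributional structure.

    PET-positive membership is drawn with probability ``prevalence_ap``;
    within each status group the four markers are drawn from truncated
    normal marginals coupled through the Gaussian copula, so Aβ1-42 and
    GM-mean SUVR are negatively rank-correlated.  The recorded visual read
    is consistent with the quantitative rule: positive iff the subject's
    GM-mean SUVR exceeds 1.11.
    """
    spec = spec or DistributionalSpec()
    rng = np.random.default_rng(spec.seed)
    if spec.n == 0:
        return []
    corr = _copula_correlation(spec)
    chol = np.linalg.cholesky(corr)
    status = rng.random(spec.n) < spec.prevalence_ap
    z = rng.standard_normal((spec.n, 4)) @ chol.T
    u = sps.norm.cdf(z)

    subjects: list[SubjectRecord] = []
    suvr_cut = ThresholdSet().suvr_cut
    for idx in range(spec.n):
        params = spec.ap_pos if status[idx] else spec.ap_neg
        draws = {
            marker: float(_truncnorm_ppf(u[idx, k], *params[marker]))
            for k, marker in enumerate(_MARKER_ORDER)
        }
        visual = "positive" if draws["suvr"] > suvr_cut else "negative"
        subjects.append(
            SubjectRecord(
                subject_id=f"P{idx + 1:04d}",
                syndrome="MCI",
                csf=CsfPanel(abeta42=draws["abeta42"], ttau=draws["ttau"],
                             ptau=draws["ptau"]),
                pet_visual=visual,
                pet_suvr={"gm_mean": draws["suvr"]},
            )
        )
    return subjects
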