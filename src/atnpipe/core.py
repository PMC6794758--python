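"""Domain types and deterministic AT(N) classification from CSF biomarkers.

The AT(N) scheme dichotomizes three biomarker axes — A (β-amyloid
deposition), T (pathologic phosphorylated tau) and N (neurodegeneration) —
into positive/negative, yielding eight profiles that collapse into three
categories: *normal* (all negative), *AD-continuum* (any A+ profile) and
*non-AD pathologic change* (A− with T+ and/or N+).

Here all three axes are measured in CSF: A by Aβ1-42 (low values are
positive) or alternatively by the p-tau/Aβ1-42 ratio (high values are
positive), T by p-tau and N by t-tau (high values are positive).  Values
exactly at a cutoff are negative: positivity is strict ``<`` for Aβ1-42 and
strict ``>`` for the others.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AtnCategory",
    "AtnProfile",
    "CsfPanel",
    "SubjectRecord",
    "ThresholdSet",
    "ValidationError",
    "PROFILE_LABELS",
    "SYNDROMES",
    "canonical_label",
    "categorize",
    "classify_cohort",
    "dichotomize",
]

#: Ratio-equality tolerance for the derived tau/Aβ ratios.
_RATIO_RTOL = 1e-9

#: The eight profile labels in canonical order: normal, the four
#: AD-continuum profiles, then the three non-AD profiles.
PROFILE_LABELS: tuple[str, ...] = (
    "A-T-(N-)",
    "A+T-(N-)",
    "A+T+(N-)",
    "A+T+(N+)",
    "A+T-(N+)",
    "A-T+(N-)",
    "A-T-(N+)",
    "A-T+(N+)",
)

#: Clinical syndrome labels accepted on input.
SYNDROMES: tuple[str, ...] = (
    "AD",
    "FTD",
    "LBD",
    "PSP_CBS",
    "PD",
    "VAD_MIXED",
    "OTHER",
    "MCI",
    "CU",
)


class ValidationError(ValueError):
    """Raised when a subject or panel violates a domain invariant."""


def _require_positive_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValidationError(f"{name} must be strictly positive and finite, got {value!r}")
    return value


class AtnCategory(str, enum.Enum):
    """Three-way AT(N) category."""

    NORMAL = "NORMAL"
    AD_CONTINUUM = "AD_CONTINUUM"
    NON_AD = "NON_AD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def canonical_label(label: str) -> str:
    """Normalise a profile label to its ASCII canonical form.

    Unicode minus (U+2212), en-dash and spaces are accepted on input;
    output always uses ASCII ``-`` and the ``A?T?(N?)`` layout.
    """
    cleaned = (
        label.replace("−", "-")
        .replace("–", "-")
        .replace(" ", "")
    )
    if cleaned not in PROFILE_LABELS:
        raise ValidationError(f"unrecognised AT(N) profile label {label!r}")
    return cleaned


@dataclass(frozen=True)
class CsfPanel:
    """One subject's CSF analyte concentrations plus derived ratios.

    Parameters
    ----------
    abeta42, ttau, ptau
        Concentrations in pg/ml; must be strictly positive and finite.
    ttau_abeta_ratio, ptau_abeta_ratio
        Dimensionless ratios over Aβ1-42.  Computed automatically when
        omitted; when supplied they must agree with the quotient of the
        concentrations to a relative tolerance of 1e-9.
    """

    abeta42: float
    ttau: float
    ptau: float
    ttau_abeta_ratio: float = field(default=math.nan)
    ptau_abeta_ratio: float = field(default=math.nan)

    def __post_init__(self) -> None:
        for name in ("abeta42", "ttau", "ptau"):
            object.__setattr__(self, name, _require_positive_finite(name, getattr(self, name)))
        for name, numerator in (("ttau_abeta_ratio", self.ttau), ("ptau_abeta_ratio", self.ptau)):
            expected = numerator / self.abeta42
            supplied = getattr(self, name)
            if math.isnan(supplied):
                object.__setattr__(self, name, expected)
            elif not math.isclose(supplied, expected, rel_tol=_RATIO_RTOL):
                raise ValidationError(
                    f"{name}={supplied!r} inconsistent with analytes (expected {expected!r})"
                )


@dataclass(frozen=True)
class ThresholdSet:
    """Dichotomization cutoffs with their direction semantics.

    ``abeta_cut`` marks positivity strictly *below* the cutoff; all other
    cutoffs mark positivity strictly *above*.  The default instance holds
    the clinically applied values Aβ1-42 < 660 pg/ml (A), p-tau > 61 pg/ml
    (T), t-tau > 500 pg/ml (N), p-tau/Aβ1-42 > 0.09 (alternative A) and
    GM-mean SUVR > 1.11 (amyloid-PET).
    """

    abeta_cut: float = 660.0
    ptau_cut: float = 61.0
    ttau_cut: float = 500.0
    ratio_cut: float = 0.09
    suvr_cut: float = 1.11

    def __post_init__(self) -> None:
        for name in ("abeta_cut", "ptau_cut", "ttau_cut", "ratio_cut", "suvr_cut"):
            _require_positive_finite(name, getattr(self, name))


# subtype names follow the research-framework nomenclature
_SUBTYPES: dict[tuple[bool, bool, bool], str] = {
    (False, False, False): "normal",
    (True, False, False): "AD pathologic change",
    (True, True, False): "AD",
    (True, True, True): "AD",
    (True, False, True): "AD and non-AD pathologic change",
    (False, True, False): "non-AD pathologic change",
    (False, False, True): "non-AD pathologic change",
    (False, True, True): "non-AD pathologic change",
}


@dataclass(frozen=True)
class AtnProfile:
    """A/T/N binary triple with its label, category and subtype."""

    a: bool
    t: bool
    n: bool

    @property
    def label(self) -> str:
        return (
            f"A{'+' if self.a else '-'}"
            f"T{'+' if self.t else '-'}"
            f"(N{'+' if self.n else '-'})"
        )

    @property
    def category(self) -> AtnCategory:
        if self.a:
            return AtnCategory.AD_CONTINUUM
        if self.t or self.n:
            return AtnCategory.NON_AD
        return AtnCategory.NORMAL

    @property
    def subtype(self) -> str:
        return _SUBTYPES[(self.a, self.t, self.n)]

    @classmethod
    def from_label(cls, label: str) -> "AtnProfile":
        lab = canonical_label(label)
        return cls(a=lab[1] == "+", t=lab[3] == "+", n=lab[6] == "+")


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort subject: syndrome, CSF panel and optional PET data.

    ``syndrome`` is taken as given clinical input (one of
    :data:`SYNDROMES`); ``sub_syndrome`` is an optional free-text variant
    such as ``aMCI`` or ``bv-FTD``.  ``pet_visual`` is an expert binary
    read ("positive"/"negative"); ``pet_suvr`` maps region names to SUVR
    values.  When both ``lp_date`` and ``pet_date`` are present their
    absolute difference in days is exposed as :meth:`lp_pet_interval_days`.
    """

    subject_id: str
    syndrome: str
    csf: CsfPanel
    age: float | None = None
    sex: str | None = None
    sub_syndrome: str | None = None
    pet_visual: str | None = None
    pet_suvr: Mapping[str, float] | None = None
    lp_date: date | None = None
    pet_date: date | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("subject_id must be non-empty")
        if self.syndrome not in SYNDROMES:
            raise ValidationError(
                f"subject {self.subject_id}: unknown syndrome {self.syndrome!r}"
            )
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValidationError(f"subject {self.subject_id}: sex must be M or F")
        if self.pet_visual is not None and self.pet_visual not in ("positive", "negative"):
            raise ValidationError(
                f"subject {self.subject_id}: pet_visual must be 'positive' or 'negative'"
            )

    def lp_pet_interval_days(self) -> int | None:
        """Absolute LP-to-PET interval in days, or None when a date is missing."""
        if self.lp_date is None or self.pet_date is None:
            return None
        return abs((self.pet_date - self.lp_date).days)


def dichotomize(
    csf: CsfPanel,
    thresholds: ThresholdSet | None = None,
    a_marker: str = "abeta42",
) -> AtnProfile:
    """Classify one CSF panel into its AT(N) profile.

    Parameters
    ----------
    csf
        Validated CSF panel.
    thresholds
        Cutoffs to apply; the clinical defaults when omitted.
    a_marker
        ``"abeta42"`` sets A+ when Aβ1-42 is strictly below ``abeta_cut``;
        ``"ptau_abeta_ratio"`` sets A+ when p-tau/Aβ1-42 is strictly above
        ``ratio_cut``.

    Returns
    -------
    AtnProfile
        The binary triple with label, category and subtype.  Values equal
        to a cutoff are negative on that axis.
    """
    thresholds = thresholds or ThresholdSet()
    if a_marker == "abeta42":
        a = csf.abeta42 < thresholds.abeta_cut
    elif a_marker == "ptau_abeta_ratio":
        a = csf.ptau_abeta_ratio > thresholds.ratio_cut
    else:
        raise ValidationError(f"unknown a_marker {a_marker!r}")
    t = csf.ptau > thresholds.ptau_cut
    n = csf.ttau > thresholds.ttau_cut
    return AtnProfile(a=a, t=t, n=n)


def categorize(profile: AtnProfile) -> AtnCategory:
    """Map a profile to NORMAL / AD_CONTINUUM / NON_AD (A+ ⇒ AD-continuum)."""
    return profile.category


def classify_cohort(
    cohort: Sequence[SubjectRecord] | Iterable[SubjectRecord],
    thresholds: ThresholdSet | None = None,
    a_marker: str = "abeta42",
) -> list[tuple[str, AtnProfile]]:
    """Classify every subject of a cohort, preserving order.

    Raises
    ------
    ValidationError
        If the cohort is empty or any subject fails validation; the error
        names the offending subject.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("cohort is empty")
    out: list[tuple[str, AtnProfile]] = []
    for subject in cohort:
        try:
            out.append((subject.subject_id, dichotomize(subject.csf, thresholds, a_marker)))
        except ValidationError as exc:
            raise ValidationError(f"subject {subject.subject_id}: {exc}") from exc
    return out
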