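"""SUV/SUVR quantification from tabulated regional tracer uptake.

The standardized uptake value is SUV = AC / (dose / BW), where AC is the
activity concentration (kBq/ml), dose the injected radiotracer dose
corrected for residual activity (MBq) and BW the body weight (kg).  SUVR
normalises a region's SUV by the whole-cerebellum SUV, so dose and weight
cancel and SUVR reduces to a ratio of activity concentrations.  The
grey-matter (GM) mean is the unweighted arithmetic mean over six cortical
target regions; a scan is amyloid-positive when GM-mean SUVR is strictly
above 1.11.

The module operates on region-level tabulated values; voxel-level image
processing is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from atnpipe.core import ValidationError

__all__ = [
    "GM_REGIONS",
    "REFERENCE_REGION",
    "PetAcquisition",
    "SuvrProfile",
    "suv",
    "suvr_profile",
]

#: The six grey-matter target regions entering the GM mean.
GM_REGIONS: tuple[str, ...] = (
    "anterior_cingulate",
    "frontal",
    "parietal",
    "posterior_cingulate",
    "precuneus",
    "temporal",
)

#: Reference region for the SUV relative ratio.
REFERENCE_REGION = "cerebellum"

#: GM-mean SUVR positivity threshold (strictly above).
SUVR_THRESHOLD = 1.11


def suv(ac: float, dose: float, bw: float) -> float:
    """Standardized uptake value, AC / (dose / BW).

    Parameters
    ----------
    ac
        Activity concentration, kBq/ml.
    dose
        Injected dose corrected for residual activity, MBq.
    bw
        Body weight, kg.
    """
    for name, value in (("ac", ac), ("dose", dose), ("bw", bw)):
        if not math.isfinite(value) or value <= 0:
            raise ValidationError(f"{name} must be strictly positive and finite, got {value!r}")
    return ac / (dose / bw)


@dataclass(frozen=True)
class PetAcquisition:
    """One scan's injected dose, body weight and regional uptake values."""

    injected_dose: float
    body_weight: float
    regional_ac: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in (("injected_dose", self.injected_dose),
                            ("body_weight", self.body_weight)):
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive and finite")
        for region, ac in self.regional_ac.items():
            if not math.isfinite(ac) or ac <= 0:
                raise ValidationError(f"activity concentration for {region!r} must be positive")


@dataclass(frozen=True)
class SuvrProfile:
    """Per-region SUVRs, their GM mean and the binary amyloid status."""

    regional_suvr: dict[str, float]
    gm_mean: float
    positive: bool

    def agrees_with_visual(self, visual_read: str) -> bool:
        """Whether the quantitative status matches a visual read."""
        return self.positive == (visual_read == "positive")


def suvr_profile(acq: PetAcquisition, threshold: float = SUVR_THRESHOLD) -> SuvrProfile:
    """Compute SUVRs relative to the whole cerebellum and classify the scan.

    All seven regions (six GM targets plus cerebellum) must be present.
    GM-mean SUVR strictly above ``threshold`` marks the scan positive; a
    value exactly at the threshold is negative.
    """
    missing = [r for r in (*GM_REGIONS, REFERENCE_REGION) if r not in acq.regional_ac]
    if missing:
        raise ValidationError(f"missing region(s): {', '.join(missing)}")
    ref_suv = suv(acq.regional_ac[REFERENCE_REGION], acq.injected_dose, acq.body_weight)
    regional = {
        region: suv(acq.regional_ac[region], acq.injected_dose, acq.body_weight) / ref_suv
        for region in GM_REGIONS
    }
    gm_mean = sum(regional.values()) / len(GM_REGIONS)
    return SuvrProfile(regional_suvr=regional, gm_mean=gm_mean, positive=gm_mean > threshold)
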