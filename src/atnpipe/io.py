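"""Cohort / threshold / table readers and writers, and the pipeline driver.

Tabular data travel as CSV (UTF-8, header required, dot decimal
separator); derived thresholds and run configuration as JSON.  Subjects
with an incomplete CSF panel are excluded on read with a logged reason
rather than imputed, mirroring a complete-case analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd

from atnpipe.core import (
    AtnProfile,
    CsfPanel,
    SubjectRecord,
    ThresholdSet,
    ValidationError,
    canonical_label,
    classify_cohort,
)
from atnpipe.simulate import DistributionalSpec, FixtureSpec, generate_distributional, generate_fixture
from atnpipe.stats import csf_pet_concordance, prevalence_table
from atnpipe.thresholds import RocResult, derive_thresholds

__all__ = [
    "PipelineConfig",
    "read_cohort",
    "read_thresholds",
    "run_pipeline",
    "write_cohort",
    "write_table",
    "write_thresholds",
]

logger = logging.getLogger(__name__)

_BASE_COLUMNS = [
    "subject_id", "age", "sex", "syndrome", "sub_syndrome",
    "abeta42", "ptau", "ttau", "pet_visual", "lp_date", "pet_date",
]
_REQUIRED_COLUMNS = ["subject_id", "syndrome", "abeta42", "ptau", "ttau"]


def _parse_date(raw) -> date | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    return date.fromisoformat(str(raw))


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV into subject records.

    Rows with a missing or unparseable CSF analyte are excluded with a
    logged reason (complete-case analysis); structural problems — missing
    columns, duplicate subject ids, malformed non-analyte fields — raise
    :class:`~atnpipe.core.ValidationError` with the row number.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    if frame["subject_id"].duplicated().any():
        dup = frame["subject_id"][frame["subject_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate subject_id {dup!r}")

    suvr_cols = [c for c in frame.columns if c.startswith("suvr_")]
    subjects: list[SubjectRecord] = []
    for i, row in frame.iterrows():
        rownum = i + 2  # 1-based, after header
        analytes = {}
        skip_reason = None
        for name in ("abeta42", "ptau", "ttau"):
            raw = row[name].strip()
            if raw in ("", "NA", "NaN", "nan", "None"):
                skip_reason = f"missing {name}"
                break
            try:
                analytes[name] = float(raw)
            except ValueError:
                raise ValidationError(
                    f"row {rownum}: unparseable {name} value {raw!r}"
                ) from None
        if skip_reason is None:
            try:
                csf = CsfPanel(**analytes)
            except ValidationError as exc:
                skip_reason = str(exc)
        if skip_reason is not None:
            logger.info("row %d (subject %s) excluded: %s",
                        rownum, row["subject_id"], skip_reason)
            continue

        def opt(col: str) -> str | None:
            val = row[col].strip() if col in frame.columns else ""
            return val or None

        suvr = {
            c.removeprefix("suvr_"): float(row[c])
            for c in suvr_cols if row[c].strip() != ""
        } or None
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=row["subject_id"],
                    syndrome=row["syndrome"],
                    sub_syndrome=opt("sub_syndrome"),
                    csf=csf,
                    age=float(row["age"]) if opt("age") else None,
                    sex=opt("sex"),
                    pet_visual=opt("pet_visual"),
                    pet_suvr=suvr,
                    lp_date=_parse_date(opt("lp_date")),
                    pet_date=_parse_date(opt("pet_date")),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
    return subjects


def write_cohort(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to CSV; ``read_cohort(write_cohort(x)) == x``."""
    suvr_regions = sorted({r for s in subjects if s.pet_suvr for r in s.pet_suvr})
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age": "" if s.age is None else repr(s.age),
            "sex": s.sex or "",
            "syndrome": s.syndrome,
            "sub_syndrome": s.sub_syndrome or "",
            "abeta42": repr(s.csf.abeta42),
            "ptau": repr(s.csf.ptau),
            "ttau": repr(s.csf.ttau),
            "pet_visual": s.pet_visual or "",
            "lp_date": s.lp_date.isoformat() if s.lp_date else "",
            "pet_date": s.pet_date.isoformat() if s.pet_date else "",
        }
        for region in suvr_regions:
            row[f"suvr_{region}"] = (
                repr(s.pet_suvr[region]) if s.pet_suvr and region in s.pet_suvr else ""
            )
        rows.append(row)
    pd.DataFrame(rows, columns=_BASE_COLUMNS + [f"suvr_{r}" for r in suvr_regions]).to_csv(
        path, index=False
    )


def write_thresholds(results: dict[str, RocResult], path: str | Path) -> None:
    """Serialise per-marker ROC results to JSON."""
    payload = {marker: res.to_dict() for marker, res in results.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_thresholds(path: str | Path) -> dict[str, dict]:
    """Read a thresholds JSON written by :func:`write_thresholds`."""
    return json.loads(Path(path).read_text())


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True, index_label="row")


def write_classified(
    classified: Sequence[tuple[SubjectRecord, AtnProfile]], path: str | Path
) -> None:
    """Write a classified cohort: subject, profile label, category, subtype."""
    rows = [
        {
            "subject_id": s.subject_id,
            "syndrome": s.syndrome,
            "sub_syndrome": s.sub_syndrome or "",
            "profile": p.label,
            "category": p.category.value,
            "subtype": p.subtype,
        }
        for s, p in classified
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_classified(path: str | Path) -> pd.DataFrame:
    """Read a classified-cohort CSV, canonicalising profile labels.

    Unicode minus signs in the ``profile`` column are normalised to the
    ASCII canonical labels.
    """
    frame = pd.read_csv(path, dtype=str)
    if "profile" not in frame.columns:
        raise ValidationError("classified CSV lacks a 'profile' column")
    frame["profile"] = frame["profile"].map(canonical_label)
    return frame


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    ``thresholds_source`` is ``"default"`` (use the clinical cutoffs) or
    ``"derived"`` (derive the Aβ1-42 cutoff from the PET subcohort and
    keep the conventional tau cutoffs).  ``a_marker`` selects the A-axis
    marker.  ``max_interval_days`` bounds the LP-PET interval for the
    derivation subcohort.
    """

    out_dir: str | Path = "atnpipe_out"
    thresholds_source: str = "default"
    a_marker: str = "abeta42"
    max_interval_days: int = 365
    seed: int = 0
    fixture_spec: FixtureSpec | None = None
    distributional_spec: DistributionalSpec | None = None

    def __post_init__(self) -> None:
        if self.a_marker not in ("abeta42", "ptau_abeta_ratio"):
            raise ValidationError(f"unknown a_marker {self.a_marker!r}")
        if self.thresholds_source not in ("default", "derived"):
            raise ValidationError(f"unknown thresholds_source {self.thresholds_source!r}")
        if self.max_interval_days <= 0:
            raise ValidationError("max_interval_days must be positive")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {k: repr(v) for k, v in dataclasses.asdict(config).items()}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline: thresholds → classification → tables → concordance.

    Generates the distributional PET subcohort and the fixture cohort from
    the configured (or default) specifications, derives thresholds from
    the PET subcohort, classifies the fixture cohort, tabulates prevalence
    (overall and with the MCI split) and computes CSF-PET concordance for
    both A-markers.  All artefacts are written under ``out_dir`` and a
    summary dictionary is returned.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dist_spec = config.distributional_spec or DistributionalSpec(seed=config.seed)
    fix_spec = config.fixture_spec or FixtureSpec(seed=config.seed)
    pet_subcohort = generate_distributional(dist_spec)
    cohort = generate_fixture(fix_spec)
    write_cohort(pet_subcohort, out / "pet_subcohort.csv")
    write_cohort(cohort, out / "cohort.csv")

    roc = derive_thresholds(pet_subcohort, max_interval_days=config.max_interval_days)
    write_thresholds(roc, out / "thresholds.json")

    thresholds = ThresholdSet()
    if config.thresholds_source == "derived":
        abeta = roc["abeta42"]
        if abeta.cutoff is None:
            raise ValidationError("derived thresholds requested but abeta42 was "
                                  "flagged insufficient accuracy")
        kwargs = {"abeta_cut": abeta.cutoff}
        ratio = roc["ptau_abeta_ratio"]
        if ratio.cutoff is not None:
            kwargs["ratio_cut"] = ratio.cutoff
        thresholds = ThresholdSet(**kwargs)

    pairs = classify_cohort(cohort, thresholds, config.a_marker)
    profiles = dict(pairs)
    classified = [(s, profiles[s.subject_id]) for s in cohort]
    write_classified(classified, out / "classified.csv")

    table = prevalence_table(classified)
    table_mci = prevalence_table(classified, split_mci=True)
    write_table(table.counts, out / "prevalence_counts.csv")
    write_table(table.percentages, out / "prevalence_percentages.csv")
    write_table(table_mci.counts, out / "prevalence_counts_mci_split.csv")

    concordance = {
        marker: csf_pet_concordance(pet_subcohort, thresholds, marker)
        for marker in ("abeta42", "ptau_abeta_ratio")
    }
    (out / "concordance.json").write_text(json.dumps({
        marker: {
            "n_pp": c.n_pp, "n_pn": c.n_pn, "n_np": c.n_np, "n_nn": c.n_nn,
            "concordance": c.concordance,
        } for marker, c in concordance.items()
    }, indent=2) + "\n")

    log = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_cohort": len(cohort),
        "n_pet_subcohort": len(pet_subcohort),
        "a_marker": config.a_marker,
        "thresholds": dataclasses.asdict(thresholds),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")

    return {
        "cohort": cohort,
        "pet_subcohort": pet_subcohort,
        "roc": roc,
        "thresholds": thresholds,
        "classified": classified,
        "prevalence": table,
        "prevalence_mci_split": table_mci,
        "concordance": concordance,
        "log": log,
    }
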