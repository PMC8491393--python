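"""Cohort tables: reading, validation, writing, and batch scoring.

The cohort dialect is five tab-separated tables with a shared ``patient_id``
key — ``patients``, ``alterations``, ``biomarkers``, ``treatments`` and
``outcomes`` — one row per alteration and per administered drug, and durations
in months with event flags rather than dates. Supplementary per-patient tables
from published trials can be reformatted into this dialect by hand or script.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .knowledge_base import KnowledgeBase
from .scoring import (
    Alteration,
    AlterationClass,
    BiomarkerProfile,
    MatchBreakdown,
    MatchingGrade,
    MsiStatus,
    Pathogenicity,
    Pdl1Category,
    TmbCategory,
    TreatmentPlan,
    assign_grade,
    matching_score,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseRecord",
    "SurvivalRecord",
    "PatientRecord",
    "Cohort",
    "CohortValidationError",
    "TABLE_NAMES",
    "TUMOR_TYPES",
    "read_cohort",
    "write_cohort",
    "score_cohort",
    "audit_table",
]

TABLE_NAMES = ("patients", "alterations", "biomarkers", "treatments", "outcomes")

# the trial's 19 observed tumor types plus a catch-all
TUMOR_TYPES = (
    "gastrointestinal_non_colorectal", "carcinoma_unknown_primary", "hepatobiliary",
    "colorectal", "pancreatic", "head_and_neck", "appendiceal", "gynecologic",
    "breast", "lung_non_small_cell", "genitourinary", "skin_melanoma",
    "neuroendocrine", "adrenocortical", "erdheim_chester", "ewing_sarcoma",
    "myxofibrosarcoma", "pecoma", "pleomorphic_sarcoma", "other",
)

BEST_RESPONSES = ("CR", "PR", "SD", "PD", "not_evaluable", "too_early")


class CohortValidationError(ValueError):
    pass


@dataclass
class ResponseRecord:
    """Best RECIST response, with stable-disease duration where applicable."""

    best_response: str  # CR | PR | SD | PD | not_evaluable | too_early
    sd_duration_months: Optional[float] = None
    sd_ongoing: bool = False

    def __post_init__(self) -> None:
        if self.best_response not in BEST_RESPONSES:
            raise CohortValidationError(
                f"unknown best_response {self.best_response!r}; expected one of {BEST_RESPONSES}")
        if self.sd_duration_months is not None and self.sd_duration_months < 0:
            raise CohortValidationError("sd_duration_months must be nonnegative")


@dataclass
class SurvivalRecord:
    """PFS and OS from treatment initiation, censored when event flags are false."""

    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool

    def __post_init__(self) -> None:
        if self.pfs_months < 0 or self.os_months < 0:
            raise CohortValidationError("survival times must be nonnegative")


@dataclass
class PatientRecord:
    patient_id: str
    tumor_type: str = "other"
    age: Optional[float] = None
    sex: Optional[str] = None  # "female" | "male"
    treated: bool = True
    alterations: list[Alteration] = field(default_factory=list)
    biomarkers: BiomarkerProfile = field(default_factory=BiomarkerProfile)
    treatment: TreatmentPlan = field(default_factory=lambda: TreatmentPlan(frozenset()))
    response: Optional[ResponseRecord] = None
    survival: Optional[SurvivalRecord] = None
    # filled in by score_cohort
    breakdown: Optional[MatchBreakdown] = None
    grade: Optional[MatchingGrade] = None

    def __post_init__(self) -> None:
        if self.treated and not self.treatment.drugs:
            raise CohortValidationError(
                f"patient {self.patient_id!r} is treated but has an empty treatment plan")

    @property
    def score(self) -> Optional[float]:
        return None if self.breakdown is None else float(self.breakdown.score)


@dataclass
class Cohort:
    patients: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortValidationError(f"duplicate patient_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def treated(self) -> list[PatientRecord]:
        return [p for p in self.patients if p.treated]


# ---------------------------------------------------------------------------
# reading

def _table_paths(source: Union[str, Path, dict]) -> dict[str, Path]:
    if isinstance(source, dict):
        paths = {name: Path(p) for name, p in source.items()}
    else:
        base = Path(source)
        paths = {name: base / f"{name}.tsv" for name in TABLE_NAMES}
    missing = [name for name in TABLE_NAMES if name not in paths or not paths[name].exists()]
    if missing:
        raise FileNotFoundError(f"missing cohort table(s): {missing}")
    return paths


def _as_bool(value, row: int, table: str, column: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise CohortValidationError(
        f"{table} row {row}: column {column!r} has non-boolean value {value!r}")


def _opt(value):
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    return value


def _enum(cls, value, row: int, table: str, column: str):
    try:
        return cls(str(value).strip())
    except ValueError:
        raise CohortValidationError(
            f"{table} row {row}: unknown {column} level {value!r}") from None


def read_cohort(source: Union[str, Path, dict]) -> Cohort:
    """Read and fully join the five cohort tables.

    ``source`` is a directory containing ``patients.tsv`` … ``outcomes.tsv``,
    or a mapping from table name to path. Unknown categorical levels and
    orphan foreign keys are rejected with the offending row number.
    """
    paths = _table_paths(source)
    tables = {name: pd.read_csv(paths[name], sep="\t", dtype=str).fillna("")
              for name in TABLE_NAMES}
    for name, df in tables.items():
        logger.info("read %s: %d rows from %s", name, len(df), paths[name])

    patients_df = tables["patients"]
    if patients_df["patient_id"].duplicated().any():
        dupes = patients_df.loc[patients_df["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortValidationError(f"patients: duplicate patient_id(s): {dupes}")
    known_ids = set(patients_df["patient_id"])
    for name in ("alterations", "biomarkers", "treatments", "outcomes"):
        for idx, pid in tables[name]["patient_id"].items():
            if pid not in known_ids:
                raise CohortValidationError(
                    f"{name} row {idx + 2}: unknown patient_id {pid!r}")

    alterations: dict[str, list[Alteration]] = {}
    for idx, row in tables["alterations"].iterrows():
        alt = Alteration(
            gene=row["gene"],
            alteration_class=_enum(AlterationClass, row["alteration_class"],
                                   idx + 2, "alterations", "alteration_class"),
            report_id=row["report_id"] or "r1",
            impact_group=_opt(row.get("impact_group", "")),
            pathogenicity=_enum(Pathogenicity, row["pathogenicity"],
                                idx + 2, "alterations", "pathogenicity"),
        )
        alterations.setdefault(row["patient_id"], []).append(alt)

    biomarkers: dict[str, BiomarkerProfile] = {}
    for idx, row in tables["biomarkers"].iterrows():
        pid = row["patient_id"]
        if pid in biomarkers:
            raise CohortValidationError(f"biomarkers row {idx + 2}: duplicate patient_id {pid!r}")
        er = _opt(row.get("er_positive", ""))
        ar = _opt(row.get("ar_positive", ""))
        biomarkers[pid] = BiomarkerProfile(
            tmb_category=_enum(TmbCategory, row.get("tmb_category", "unknown") or "unknown",
                               idx + 2, "biomarkers", "tmb_category"),
            msi_status=_enum(MsiStatus, row.get("msi_status", "unknown") or "unknown",
                             idx + 2, "biomarkers", "msi_status"),
            pdl1_category=_enum(Pdl1Category, row.get("pdl1_category", "unknown") or "unknown",
                                idx + 2, "biomarkers", "pdl1_category"),
            er_positive=None if er is None else _as_bool(er, idx + 2, "biomarkers", "er_positive"),
            ar_positive=None if ar is None else _as_bool(ar, idx + 2, "biomarkers", "ar_positive"),
        )

    treatments: dict[str, set[str]] = {}
    for idx, row in tables["treatments"].iterrows():
        treatments.setdefault(row["patient_id"], set()).add(row["drug"])

    responses: dict[str, ResponseRecord] = {}
    survivals: dict[str, SurvivalRecord] = {}
    for idx, row in tables["outcomes"].iterrows():
        pid = row["patient_id"]
        if pid in responses:
            raise CohortValidationError(f"outcomes row {idx + 2}: duplicate patient_id {pid!r}")
        if row["best_response"] not in BEST_RESPONSES:
            raise CohortValidationError(
                f"outcomes row {idx + 2}: unknown best_response {row['best_response']!r}")
        duration = _opt(row.get("sd_duration_months", ""))
        responses[pid] = ResponseRecord(
            best_response=row["best_response"],
            sd_duration_months=None if duration is None else float(duration),
            sd_ongoing=_as_bool(row.get("sd_ongoing", "false") or "false",
                                idx + 2, "outcomes", "sd_ongoing"),
        )
        survivals[pid] = SurvivalRecord(
            pfs_months=float(row["pfs_months"]),
            pfs_event=_as_bool(row["pfs_event"], idx + 2, "outcomes", "pfs_event"),
            os_months=float(row["os_months"]),
            os_event=_as_bool(row["os_event"], idx + 2, "outcomes", "os_event"),
        )

    records = []
    for idx, row in patients_df.iterrows():
        if row["tumor_type"] not in TUMOR_TYPES:
            raise CohortValidationError(
                f"patients row {idx + 2}: unknown tumor_type {row['tumor_type']!r}")
        pid = row["patient_id"]
        age = _opt(row.get("age", ""))
        records.append(PatientRecord(
            patient_id=pid,
            tumor_type=row["tumor_type"],
            age=None if age is None else float(age),
            sex=_opt(row.get("sex", "")),
            treated=_as_bool(row["treated"], idx + 2, "patients", "treated"),
            alterations=alterations.get(pid, []),
            biomarkers=biomarkers.get(pid, BiomarkerProfile()),
            treatment=TreatmentPlan(frozenset(treatments.get(pid, set()))),
            response=responses.get(pid),
            survival=survivals.get(pid),
        ))
    cohort = Cohort(patients=records, metadata={
        "source": {name: str(p) for name, p in paths.items()},
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "row_counts": {name: len(df) for name, df in tables.items()},
    })
    logger.info("cohort assembled: %d patients (%d treated)", len(cohort), len(cohort.treated))
    return cohort


# ---------------------------------------------------------------------------
# writing

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_cohort(cohort: Cohort, directory: Union[str, Path]) -> dict[str, Path]:
    """Write the five cohort tables to ``directory``; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = cohort_to_frames(cohort)
    paths = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.tsv"
        frames[name].to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def cohort_to_frames(cohort: Cohort) -> dict[str, pd.DataFrame]:
    patients, alts, bios, treats, outs = [], [], [], [], []
    for p in cohort:
        patients.append({"patient_id": p.patient_id, "tumor_type": p.tumor_type,
                         "age": _fmt(p.age), "sex": _fmt(p.sex), "treated": _fmt(p.treated)})
        for a in p.alterations:
            alts.append({"patient_id": p.patient_id, "report_id": a.report_id,
                         "gene": a.gene, "alteration_class": a.alteration_class.value,
                         "impact_group": _fmt(a.impact_group),
                         "pathogenicity": a.pathogenicity.value})
        b = p.biomarkers
        bios.append({"patient_id": p.patient_id, "tmb_category": b.tmb_category.value,
                     "msi_status": b.msi_status.value, "pdl1_category": b.pdl1_category.value,
                     "er_positive": _fmt(b.er_positive), "ar_positive": _fmt(b.ar_positive)})
        for d in sorted(p.treatment.drugs):
            treats.append({"patient_id": p.patient_id, "drug": d})
        if p.response is not None and p.survival is not None:
            outs.append({"patient_id": p.patient_id,
                         "best_response": p.response.best_response,
                         "sd_duration_months": _fmt(p.response.sd_duration_months),
                         "sd_ongoing": _fmt(p.response.sd_ongoing),
                         "pfs_months": _fmt(p.survival.pfs_months),
                         "pfs_event": _fmt(p.survival.pfs_event),
                         "os_months": _fmt(p.survival.os_months),
                         "os_event": _fmt(p.survival.os_event)})
    columns = {
        "patients": ["patient_id", "tumor_type", "age", "sex", "treated"],
        "alterations": ["patient_id", "report_id", "gene", "alteration_class",
                        "impact_group", "pathogenicity"],
        "biomarkers": ["patient_id", "tmb_category", "msi_status", "pdl1_category",
                       "er_positive", "ar_positive"],
        "treatments": ["patient_id", "drug"],
        "outcomes": ["patient_id", "best_response", "sd_duration_months", "sd_ongoing",
                     "pfs_months", "pfs_event", "os_months", "os_event"],
    }
    data = {"patients": patients, "alterations": alts, "biomarkers": bios,
            "treatments": treats, "outcomes": outs}
    return {name: pd.DataFrame(data[name], columns=columns[name]) for name in TABLE_NAMES}


# ---------------------------------------------------------------------------
# scoring

def score_cohort(
    cohort: Cohort,
    kb: KnowledgeBase,
    dedupe_across_reports: bool = False,
) -> tuple[Cohort, list[dict]]:
    """Score every treated patient in place; untreated patients pass through.

    Per-patient failures (e.g. a drug missing from the knowledge base) are
    collected into the returned error report instead of aborting the batch.
    """
    errors = []
    for p in cohort.treated:
        try:
            p.breakdown = matching_score(p.alterations, p.biomarkers, p.treatment, kb,
                                         dedupe_across_reports=dedupe_across_reports)
            p.grade = assign_grade(p.breakdown.score)
        except Exception as exc:  # noqa: BLE001 - reported, not fatal to the batch
            errors.append({"patient_id": p.patient_id, "error": str(exc)})
    if errors:
        logger.warning("scoring failed for %d patient(s)", len(errors))
    return cohort, errors


def audit_table(cohort: Cohort) -> pd.DataFrame:
    """One row per countable unit across the scored cohort, for manual audit."""
    rows = []
    for p in cohort.treated:
        if p.breakdown is None:
            continue
        for u in p.breakdown.units:
            rows.append({
                "patient_id": p.patient_id, "gene": u.gene,
                "alteration_class": None if u.alteration_class is None else u.alteration_class.value,
                "impact_group": u.impact_group, "report_id": u.report_id,
                "n_collapsed": u.n_collapsed, "matched": u.matched, "weight": u.weight,
                "provenance": ";".join(f"{d}:{t}" for d, t in u.provenance),
                "io_component": p.breakdown.io_component.value,
                "score": float(p.breakdown.score),
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "gene", "alteration_class", "impact_group", "report_id",
        "n_collapsed", "matched", "weight", "provenance", "io_component", "score"])
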