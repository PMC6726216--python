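"""Patient-level cohort I/O, validation, exclusion filters and subgrouping.

A cohort is a list of :class:`PatientRecord` read from a headered CSV.  The
analysis population excludes ER+/PR+ tumours and patients older than 60, and
partitions the remainder into six subgroups: two age bands (20-39, 40-59)
crossed with three hormone-receptor classes (ER-/PR-, ER+/PR-, ER-/PR+).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

EVENT_DEATH = 1
EVENT_CENSORED = 0

#: logical column names expected in a cohort CSV (before column_map renaming)
REQUIRED_COLUMNS = (
    "patient_id",
    "age",
    "er_status",
    "pr_status",
    "arm",
    "followup_years",
    "event",
    "predicted_s15",
)

_POSITIVE_CODES = {"+", "pos", "positive", "1", "true", "p"}
_NEGATIVE_CODES = {"-", "−", "neg", "negative", "0", "false", "n"}


class CohortError(Exception):
    """Base class for cohort-handling failures."""


class ConfigError(CohortError):
    """A required column is missing or the column map is inconsistent."""


class EmptyCohortError(CohortError):
    """No usable records remain (empty file or everything excluded)."""


class ValidationError(CohortError):
    """One or more rows violate field constraints.

    ``rows`` holds the offending 1-based CSV data-row numbers.
    """

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


class SubgroupError(CohortError):
    """Record cannot be assigned to any analysis subgroup."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

AGE_BANDS = ("20-39", "40-59")
RECEPTOR_CLASSES = ("ER-/PR-", "ER+/PR-", "ER-/PR+")


@dataclass(frozen=True, order=True)
class Subgroup:
    """One of the six analysis subgroups: age band x receptor class."""

    age_band: str
    receptor_class: str

    def __post_init__(self) -> None:
        if self.age_band not in AGE_BANDS:
            raise SubgroupError(f"unknown age band {self.age_band!r}")
        if self.receptor_class not in RECEPTOR_CLASSES:
            raise SubgroupError(f"unknown receptor class {self.receptor_class!r}")

    def __str__(self) -> str:  # e.g. "20-39 ER-/PR-"
        return f"{self.age_band} {self.receptor_class}"


#: all six subgroups, younger band first, ER-/PR- first within a band
ALL_SUBGROUPS = tuple(
    Subgroup(band, rc) for band in AGE_BANDS for rc in RECEPTOR_CLASSES
)


@dataclass
class PatientRecord:
    """One trial participant with covariates, outcome and baseline prediction.

    ``predicted_s15`` is the baseline predictor's 15-year overall-survival
    probability for this patient (e.g. a nomogram output supplied as an input
    column); it may be ``None`` only when a pluggable predictor will fill it.
    """

    patient_id: str
    age: int
    er_status: str  # "positive" | "negative"
    pr_status: str
    arm: str
    followup_years: float
    event: int  # 1 = death, 0 = censored
    predicted_s15: float | None

    def validate(self) -> list[str]:
        """Return a list of constraint violations (empty if valid)."""
        problems = []
        if self.age < 0:
            problems.append(f"age {self.age} < 0")
        if self.followup_years < 0:
            problems.append(f"followup_years {self.followup_years} < 0")
        if self.event not in (EVENT_DEATH, EVENT_CENSORED):
            problems.append(f"event {self.event!r} not in {{0, 1}}")
        if self.er_status not in ("positive", "negative"):
            problems.append(f"er_status {self.er_status!r}")
        if self.pr_status not in ("positive", "negative"):
            problems.append(f"pr_status {self.pr_status!r}")
        if self.predicted_s15 is not None and not 0.0 <= self.predicted_s15 <= 1.0:
            problems.append(f"predicted_s15 {self.predicted_s15} outside [0, 1]")
        return problems


def parse_receptor_status(value: object) -> str:
    """Normalise an ER/PR coding (+/-, pos/neg, 1/0, ...) to positive/negative."""
    text = str(value).strip().lower()
    if text in _POSITIVE_CODES:
        return "positive"
    if text in _NEGATIVE_CODES:
        return "negative"
    raise ValueError(f"unrecognised receptor status {value!r}")


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def read_cohort(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    time_unit: str = "years",
    allow_missing_s15: bool = False,
) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row; lines starting with ``#`` are ignored.
    column_map
        Maps logical column names (:data:`REQUIRED_COLUMNS`) to the actual
        file headers, e.g. ``{"followup_years": "surv_time"}``.  Unmapped
        names are looked up verbatim.
    time_unit
        ``"years"`` (real-valued) or ``"days"`` (converted via /365.25).
    allow_missing_s15
        Accept empty ``predicted_s15`` cells (to be filled by a registered
        predictor downstream); by default such rows are rejected.

    Raises
    ------
    ConfigError, EmptyCohortError, ValidationError
    """
    if time_unit not in ("years", "days"):
        raise ConfigError(f"time_unit must be 'years' or 'days', got {time_unit!r}")
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    if frame.empty:
        raise EmptyCohortError(f"{path}: no data rows")

    resolved = {}
    for logical in REQUIRED_COLUMNS:
        actual = column_map.get(logical, logical)
        if actual not in frame.columns:
            raise ConfigError(
                f"{path}: required column {logical!r} (mapped to {actual!r}) not found"
            )
        resolved[logical] = actual

    records: list[PatientRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i in range(len(frame)):
        raw = {k: frame.iloc[i][v] for k, v in resolved.items()}
        try:
            s15_cell = raw["predicted_s15"]
            if pd.isna(s15_cell) or str(s15_cell).strip() == "":
                if not allow_missing_s15:
                    raise ValueError("predicted_s15 is missing")
                s15 = None
            else:
                s15 = float(s15_cell)
            followup = float(raw["followup_years"])
            if time_unit == "days":
                followup /= 365.25
            record = PatientRecord(
                patient_id=str(raw["patient_id"]),
                age=int(float(raw["age"])),
                er_status=parse_receptor_status(raw["er_status"]),
                pr_status=parse_receptor_status(raw["pr_status"]),
                arm=str(raw["arm"]),
                followup_years=followup,
                event=int(float(raw["event"])),
                predicted_s15=s15,
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append((i + 1, str(exc)))
            continue
        problems = record.validate()
        if problems:
            bad_rows.append((i + 1, "; ".join(problems)))
        else:
            records.append(record)

    if bad_rows:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad_rows[:20])
        raise ValidationError(
            f"{path}: {len(bad_rows)} invalid row(s): {detail}",
            rows=[r for r, _ in bad_rows],
        )
    if not records:
        raise EmptyCohortError(f"{path}: no valid records")
    return records


def cohort_to_frame(
    cohort: Iterable[PatientRecord], include_subgroup: bool = False
) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {
            "patient_id": rec.patient_id,
            "age": rec.age,
            "er_status": rec.er_status,
            "pr_status": rec.pr_status,
            "arm": rec.arm,
            "followup_years": rec.followup_years,
            "event": rec.event,
            "predicted_s15": rec.predicted_s15,
        }
        if include_subgroup:
            row["subgroup"] = str(assign_subgroup(rec))
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: Sequence[PatientRecord],
    path: str | Path,
    include_subgroup: bool = False,
    header_comments: Sequence[str] = (),
) -> None:
    """Write a cohort CSV (same schema as :func:`read_cohort` expects).

    ``header_comments`` are emitted as leading ``#`` lines (provenance).
    """
    frame = cohort_to_frame(cohort, include_subgroup=include_subgroup)
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Filtering and subgrouping
# ---------------------------------------------------------------------------

def apply_exclusions(
    cohort: Sequence[PatientRecord], max_age: int = 60
) -> list[PatientRecord]:
    """Drop ER+/PR+ records and records with age > ``max_age``.

    Order is preserved and the operation is idempotent.  The number of
    removed records is logged.  Age exactly ``max_age`` is retained (and
    later mapped into the upper age band); a warning is logged when such
    boundary records are present.
    """
    kept: list[PatientRecord] = []
    n_receptor = n_age = 0
    n_boundary = 0
    for rec in cohort:
        if rec.er_status == "positive" and rec.pr_status == "positive":
            n_receptor += 1
            continue
        if rec.age > max_age:
            n_age += 1
            continue
        if rec.age == max_age:
            n_boundary += 1
        kept.append(rec)
    logger.info(
        "exclusions: removed %d ER+/PR+ and %d aged > %d (of %d); %d retained",
        n_receptor, n_age, max_age, len(cohort), len(kept),
    )
    if n_boundary:
        logger.warning(
            "%d record(s) aged exactly %d retained and mapped to the %s band",
            n_boundary, max_age, AGE_BANDS[-1],
        )
    return kept


def assign_subgroup(record: PatientRecord) -> Subgroup:
    """Assign a filtered record to one of the six analysis subgroups.

    Ages 20-39 map to the younger band; 40-60 to the older band (age 60,
    retained by the default exclusion rule, receives the 40-59 band's
    correction).  ER+/PR+ records and ages outside [20, 60] must have been
    filtered out first and raise :class:`SubgroupError` here.
    """
    if record.er_status == "positive" and record.pr_status == "positive":
        raise SubgroupError(
            f"{record.patient_id}: ER+/PR+ records are outside the analysis population"
        )
    if not 20 <= record.age <= 60:
        raise SubgroupError(
            f"{record.patient_id}: age {record.age} outside [20, 60]"
        )
    band = AGE_BANDS[0] if record.age <= 39 else AGE_BANDS[1]
    er = "+" if record.er_status == "positive" else "-"
    pr = "+" if record.pr_status == "positive" else "-"
    return Subgroup(band, f"ER{er}/PR{pr}")


def subgroup_counts(cohort: Iterable[PatientRecord]) -> dict[Subgroup, int]:
    """Count filtered records per subgroup (all six keys always present)."""
    counts = {sg: 0 for sg in ALL_SUBGROUPS}
    for rec in cohort:
        counts[assign_subgroup(rec)] += 1
    return counts


def split_by_subgroup(
    cohort: Iterable[PatientRecord],
) -> dict[Subgroup, list[PatientRecord]]:
    groups: dict[Subgroup, list[PatientRecord]] = {sg: [] for sg in ALL_SUBGROUPS}
    for rec in cohort:
        groups[assign_subgroup(rec)].append(rec)
    return groups


def split_by_arm(cohort: Iterable[PatientRecord]) -> dict[str, list[PatientRecord]]:
    arms: dict[str, list[PatientRecord]] = {}
    for rec in cohort:
        arms.setdefault(rec.arm, []).append(rec)
    return arms


def with_prediction(record: PatientRecord, s15: float) -> PatientRecord:
    """Copy of ``record`` with ``predicted_s15`` replaced (pluggable predictors)."""
    return replace(record, predicted_s15=float(s15))
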