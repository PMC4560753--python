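"""Cohort input/output: read patient records, validate, score, write results.

Two on-disk representations are supported:

* ``delimited`` — UTF-8 comma-separated text with a header row, one patient
  per row, canonical snake_case column names (see :data:`ALL_COLUMNS`);
* ``structured_records`` — a JSON array, one object per patient with nested
  ``preoperative`` / ``perioperative`` objects mirroring the profile fields.

Parsing is total: a malformed row never crashes the reader — it either
becomes a validated :class:`CohortRecord` or a row-level
:class:`ValidationIssue` naming the row, field and reason.  ``strict`` mode
escalates any issue to a hard failure.  Booleans accept true/false, 1/0 and
yes/no (case-insensitive); enum levels accept the canonical token only, so
clinical semantics stay unambiguous.  Durations are plain minutes — no
"1h30"-style parsing, which could silently shift a patient across the
90-minute band boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
from pydantic import ValidationError

from .risk_model import (
    PERIOPERATIVE_FIELDS,
    PREOPERATIVE_FIELDS,
    PerioperativeProfile,
    PreoperativeProfile,
)
from .scoring import (
    DEFAULT_THRESHOLDS,
    ScoreResult,
    ThresholdTable,
    score_perioperative,
    score_preoperative,
    total_ars,
)

logger = logging.getLogger(__name__)

DELIMITED = "delimited"
STRUCTURED = "structured_records"
FORMATS = (DELIMITED, STRUCTURED)

#: canonical column dictionary for delimited cohorts.
ALL_COLUMNS = ("patient_id",) + PREOPERATIVE_FIELDS + PERIOPERATIVE_FIELDS

_PRE_BOOL_FIELDS = tuple(
    f for f in PREOPERATIVE_FIELDS
    if PreoperativeProfile.model_fields[f].annotation is bool
)
_PERI_BOOL_FIELDS = tuple(
    f for f in PERIOPERATIVE_FIELDS
    if PerioperativeProfile.model_fields[f].annotation is bool
)

_BOOL_TOKENS = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


class CohortFormatError(ValueError):
    """File-level problem: unreadable file, unknown column, bad format name."""


class CohortValidationError(ValueError):
    """Raised in strict mode when any record fails validation."""

    def __init__(self, issues: Sequence["ValidationIssue"]):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues[:5])
        more = "" if len(self.issues) <= 5 else f" (+{len(self.issues) - 5} more)"
        super().__init__(f"{len(self.issues)} invalid record(s): {lines}{more}")


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found in one record."""

    row: int | None
    patient_id: str | None
    field: str
    message: str

    def __str__(self) -> str:
        where = f"row {self.row}" if self.row is not None else "record"
        pid = f" (patient {self.patient_id})" if self.patient_id else ""
        return f"{where}{pid}: {self.field}: {self.message}"


@dataclass(frozen=True)
class CohortRecord:
    """One patient: identifier plus at least one validated profile."""

    patient_id: str
    preoperative: PreoperativeProfile | None = None
    perioperative: PerioperativeProfile | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.preoperative is None and self.perioperative is None:
            raise ValueError(f"patient {self.patient_id}: at least one profile required")


@dataclass(frozen=True)
class ScoredRecord:
    """Scoring output for one patient; ``total`` only when both sub-scores exist."""

    patient_id: str
    preoperative: ScoreResult | None = None
    perioperative: ScoreResult | None = None
    total: int | None = None
    record: CohortRecord | None = dc_field(default=None, compare=False)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _pydantic_issues(
    exc: ValidationError, prefix: str, row: int | None, patient_id: str | None
) -> list[ValidationIssue]:
    issues = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or prefix
        if err["loc"]:
            loc = f"{prefix}.{loc}"
        issues.append(ValidationIssue(row, patient_id, loc, err["msg"]))
    return issues


def validate_record(
    raw: Mapping[str, Any] | CohortRecord, row: int | None = None
) -> list[ValidationIssue]:
    """Validate one record; an empty report means the record is fully valid.

    Accepts either a raw mapping ``{"patient_id": ..., "preoperative":
    {...}, "perioperative": {...}}`` or an already-constructed
    :class:`CohortRecord` (whose report is always empty, since construction
    enforces the invariants).  Reports problems, never raises.
    """
    if isinstance(raw, CohortRecord):
        raw = {
            "patient_id": raw.patient_id,
            "preoperative": None if raw.preoperative is None
            else raw.preoperative.model_dump(),
            "perioperative": None if raw.perioperative is None
            else raw.perioperative.model_dump(),
        }
    issues: list[ValidationIssue] = []
    patient_id = raw.get("patient_id") or None
    if not patient_id:
        issues.append(ValidationIssue(row, None, "patient_id", "missing or empty"))
    pre, peri = raw.get("preoperative"), raw.get("perioperative")
    if pre is None and peri is None:
        issues.append(ValidationIssue(
            row, patient_id, "record",
            "at least one of preoperative/perioperative profile required",
        ))
    for prefix, cls, payload in (
        ("preoperative", PreoperativeProfile, pre),
        ("perioperative", PerioperativeProfile, peri),
    ):
        if payload is None:
            continue
        try:
            cls.model_validate(payload)
        except ValidationError as exc:
            issues.extend(_pydantic_issues(exc, prefix, row, patient_id))
    return issues


def _build_record(raw: Mapping[str, Any]) -> CohortRecord:
    pre = raw.get("preoperative")
    peri = raw.get("perioperative")
    return CohortRecord(
        patient_id=raw["patient_id"],
        preoperative=None if pre is None else PreoperativeProfile.model_validate(pre),
        perioperative=None if peri is None else PerioperativeProfile.model_validate(peri),
    )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_cell(field: str, value: str, bool_fields: tuple[str, ...]) -> Any:
    if field in bool_fields:
        token = value.strip().lower()
        if token not in _BOOL_TOKENS:
            raise ValueError(
                f"invalid boolean {value!r} (accepted: true/false, 1/0, yes/no)"
            )
        return _BOOL_TOKENS[token]
    return value.strip()


def _row_to_raw(
    row_cells: Mapping[str, str], row_no: int, patient_id: str | None
) -> tuple[dict[str, Any], list[ValidationIssue]]:
    """Turn one delimited row into a raw nested record, reporting bad cells."""
    issues: list[ValidationIssue] = []
    raw: dict[str, Any] = {"patient_id": patient_id}
    for key, fields, bool_fields in (
        ("preoperative", PREOPERATIVE_FIELDS, _PRE_BOOL_FIELDS),
        ("perioperative", PERIOPERATIVE_FIELDS, _PERI_BOOL_FIELDS),
    ):
        present = {f: row_cells[f] for f in fields if f in row_cells and row_cells[f].strip() != ""}
        if not present:
            raw[key] = None
            continue
        profile: dict[str, Any] = {}
        for f, cell in present.items():
            try:
                profile[f] = _parse_cell(f, cell, bool_fields)
            except ValueError as exc:
                issues.append(ValidationIssue(row_no, patient_id, f"{key}.{f}", str(exc)))
        missing_bools = [f for f in bool_fields if f not in present]
        if missing_bools:
            logger.warning(
                "row %d (patient %s): %s booleans %s missing, defaulting to false",
                row_no, patient_id, key, ", ".join(missing_bools),
            )
        raw[key] = profile
    return raw, issues


def read_cohort(
    path: str | Path,
    format: str = DELIMITED,
    strict: bool = False,
) -> tuple[list[CohortRecord], list[ValidationIssue]]:
    """Read a cohort file into validated records plus a list of row issues.

    Invalid rows are reported, not raised (unless ``strict``); a duplicated
    patient_id invalidates the later row.  File-level problems (missing
    file, unknown column, malformed JSON) raise :class:`CohortFormatError`.
    """
    path = Path(path)
    if format not in FORMATS:
        raise CohortFormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise CohortFormatError(f"no such file: {path}")

    if format == DELIMITED:
        rows = _read_delimited_rows(path)
    else:
        rows = _read_structured_rows(path)

    records: list[CohortRecord] = []
    issues: list[ValidationIssue] = []
    seen_ids: set[str] = set()
    for row_no, raw, row_issues in rows:
        row_issues = list(row_issues)
        pid = raw.get("patient_id")
        if pid and pid in seen_ids:
            row_issues.append(ValidationIssue(
                row_no, pid, "patient_id", "duplicate patient_id"
            ))
        row_issues.extend(validate_record(raw, row=row_no))
        if row_issues:
            issues.extend(row_issues)
            continue
        seen_ids.add(pid)
        records.append(_build_record(raw))
    if strict and issues:
        raise CohortValidationError(issues)
    return records, issues


def _read_delimited_rows(path: Path):
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=",", encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise CohortFormatError(f"cannot read {path}: {exc}") from exc
    unknown = set(df.columns) - set(ALL_COLUMNS)
    if unknown:
        raise CohortFormatError(
            f"unknown column(s) {sorted(unknown)}; expected a subset of {list(ALL_COLUMNS)}"
        )
    if "patient_id" not in df.columns:
        raise CohortFormatError("missing required column 'patient_id'")
    out = []
    for i, cells in enumerate(df.to_dict(orient="records")):
        row_no = i + 2  # 1-based with header row
        pid = (cells.get("patient_id") or "").strip() or None
        raw, row_issues = _row_to_raw(cells, row_no, pid)
        out.append((row_no, raw, row_issues))
    return out


def _read_structured_rows(path: Path):
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise CohortFormatError(f"cannot read {path}: {exc}") from exc
    if not isinstance(payload, list):
        raise CohortFormatError("structured_records file must be a JSON array")
    out = []
    for i, obj in enumerate(payload):
        row_no = i + 1
        if not isinstance(obj, Mapping):
            out.append((row_no, {}, [ValidationIssue(row_no, None, "record", "not an object")]))
            continue
        unknown = set(obj) - {"patient_id", "preoperative", "perioperative"}
        row_issues = [
            ValidationIssue(row_no, obj.get("patient_id"), k, "unknown field")
            for k in sorted(unknown)
        ]
        out.append((row_no, dict(obj), row_issues))
    return out


# ---------------------------------------------------------------------------
# Scoring and writing
# ---------------------------------------------------------------------------

def score_cohort(
    records: Iterable[CohortRecord],
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    sub_score: str = "both",
) -> list[ScoredRecord]:
    """Score every record; ``sub_score`` restricts to 'pre', 'peri' or 'both'."""
    if sub_score not in ("pre", "peri", "both"):
        raise ValueError("sub_score must be 'pre', 'peri' or 'both'")
    out = []
    for rec in records:
        pre = peri = None
        if sub_score in ("pre", "both") and rec.preoperative is not None:
            pre = score_preoperative(rec.preoperative, thresholds)
        if sub_score in ("peri", "both") and rec.perioperative is not None:
            peri = score_perioperative(rec.perioperative, thresholds)
        total = total_ars(pre, peri) if pre and peri else None
        out.append(ScoredRecord(rec.patient_id, pre, peri, total, record=rec))
    return out


#: stable output column order for delimited results.
RESULT_COLUMNS = (
    ["patient_id", "preoperative_score", "preoperative_risk",
     "perioperative_score", "perioperative_risk", "total_ars"]
    + [f"pre__{f}" for f in PREOPERATIVE_FIELDS]
    + [f"peri__{f}" for f in PERIOPERATIVE_FIELDS]
)


def _scored_to_flat(sr: ScoredRecord) -> dict[str, Any]:
    row: dict[str, Any] = {c: "" for c in RESULT_COLUMNS}
    row["patient_id"] = sr.patient_id
    if sr.preoperative:
        row["preoperative_score"] = sr.preoperative.score
        row["preoperative_risk"] = sr.preoperative.risk_category
        for f, pts in sr.preoperative.breakdown.items():
            row[f"pre__{f}"] = pts
    if sr.perioperative:
        row["perioperative_score"] = sr.perioperative.score
        row["perioperative_risk"] = sr.perioperative.risk_category
        for f, pts in sr.perioperative.breakdown.items():
            row[f"peri__{f}"] = pts
    if sr.total is not None:
        row["total_ars"] = sr.total
    return row


def write_results(
    scored: Sequence[ScoredRecord], path: str | Path, format: str = DELIMITED
) -> Path:
    """Write scored records with scores, categories, total ARS and breakdowns.

    Column order is stable; re-reading with :func:`read_scored` round-trips
    all values exactly.  An empty cohort produces a header-only file.
    """
    path = Path(path)
    if format == DELIMITED:
        df = pd.DataFrame([_scored_to_flat(sr) for sr in scored], columns=RESULT_COLUMNS)
        df.to_csv(path, index=False)
    elif format == STRUCTURED:
        def result_obj(res: ScoreResult | None):
            if res is None:
                return None
            return {
                "score": res.score,
                "risk_category": res.risk_category,
                "breakdown": dict(res.breakdown),
            }

        payload = [
            {
                "patient_id": sr.patient_id,
                "preoperative": result_obj(sr.preoperative),
                "perioperative": result_obj(sr.perioperative),
                "total_ars": sr.total,
            }
            for sr in scored
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        raise CohortFormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    return path


def read_scored(path: str | Path, format: str = DELIMITED) -> list[ScoredRecord]:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    out: list[ScoredRecord] = []
    if format == DELIMITED:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for cells in df.to_dict(orient="records"):
            pre = peri = None
            if cells.get("preoperative_score", "") != "":
                pre = ScoreResult(
                    "preoperative",
                    int(cells["preoperative_score"]),
                    {f: int(cells[f"pre__{f}"]) for f in PREOPERATIVE_FIELDS},
                    cells["preoperative_risk"],
                )
            if cells.get("perioperative_score", "") != "":
                peri = ScoreResult(
                    "perioperative",
                    int(cells["perioperative_score"]),
                    {f: int(cells[f"peri__{f}"]) for f in PERIOPERATIVE_FIELDS},
                    cells["perioperative_risk"],
                )
            total = int(cells["total_ars"]) if cells.get("total_ars", "") != "" else None
            out.append(ScoredRecord(cells["patient_id"], pre, peri, total))
    elif format == STRUCTURED:
        payload = json.loads(path.read_text(encoding="utf-8"))
        for obj in payload:
            def result_from(kind: str):
                o = obj.get(kind)
                if o is None:
                    return None
                return ScoreResult(kind, o["score"], o["breakdown"], o["risk_category"])

            out.append(ScoredRecord(
                obj["patient_id"],
                result_from("preoperative"),
                result_from("perioperative"),
                obj.get("total_ars"),
            ))
    else:
        raise CohortFormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    return out
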