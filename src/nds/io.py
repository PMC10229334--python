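"""File formats: JSON exam records, delimited score sheets and rating matrices.

Exam records travel as JSON (one object per assessment, nested sign sets);
score sheets and rating matrices as comma-delimited UTF-8 tables with a
header row, "." decimal and the empty string for missing cells. Every
writer's output is re-readable by the matching reader. Malformed records
are rejected with their subject ids, never silently skipped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from .agreement import RatingMatrix
from .records import NeuroExamRecord, Violation, validate_record
from .scale import BINARY_ITEMS, CATEGORIES, NDSScoreSheet

__all__ = [
    "ExamRecordError",
    "RunConfig",
    "read_exam_records",
    "write_exam_records",
    "exam_record_json_schema",
    "read_rating_matrix",
    "write_rating_matrix",
    "sheets_to_dataframe",
    "write_score_sheets",
    "read_score_sheets",
]

PathLike = Union[str, Path]


#: Fields every exam-record object in a file must carry explicitly. The
#: Python constructor defaults absent findings to normal for convenience, but
#: a record file omitting a clinical field is ambiguous (unexamined vs
#: normal) and is rejected. The pilot binary items and the SE flag default
#: to false when absent.
REQUIRED_RECORD_FIELDS = (
    "subject_id",
    "ambulatory",
    "cerebral_signs",
    "cerebellar",
    "brainstem_signs",
    "vision",
    "posture",
    "seizure_history_7d",
)


class ExamRecordError(ValueError):
    """One or more exam records failed schema validation or record invariants."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__(
            "invalid exam records:\n" + "\n".join(f"  - {p}" for p in problems)
        )


class RunConfig(BaseModel):
    """Defaults for a pipeline run, overridable from a JSON config file."""

    model_config = ConfigDict(extra="forbid")

    scale_version: str = "final7"
    kappa_scheme: str = "linear"
    icc_measure: str = "single"
    conf_level: float = 0.95
    seed: Optional[int] = None
    reps: int = 20


def exam_record_json_schema() -> dict:
    """JSON Schema for one exam-record object (also shipped under schemas/)."""
    schema = NeuroExamRecord.model_json_schema()
    schema["required"] = list(REQUIRED_RECORD_FIELDS)
    return schema


def write_exam_records(records: Sequence[NeuroExamRecord], path: PathLike) -> None:
    payload = [json.loads(r.model_dump_json()) for r in records]
    # Sets serialize in arbitrary order; sort for byte-stable output.
    for obj in payload:
        for key in ("cerebral_signs", "brainstem_signs", "posture"):
            obj[key] = sorted(obj[key])
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_exam_records(path: PathLike) -> List[NeuroExamRecord]:
    """Read and validate a JSON file of exam records.

    Raises :class:`ExamRecordError` naming every malformed record (schema
    violations and broken record invariants) with its subject id or
    position; returns the full record list otherwise.
    """
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ExamRecordError([f"not valid JSON: {exc}"]) from exc
    if not isinstance(raw, list):
        raise ExamRecordError(["top-level JSON value must be a list of records"])
    records: List[NeuroExamRecord] = []
    problems: List[str] = []
    for i, obj in enumerate(raw):
        ident = obj.get("subject_id", f"#{i}") if isinstance(obj, dict) else f"#{i}"
        if isinstance(obj, dict):
            missing = [f for f in REQUIRED_RECORD_FIELDS if f not in obj]
            if missing:
                problems.extend(f"{ident}: missing required field {f!r}" for f in missing)
                continue
        try:
            record = NeuroExamRecord.model_validate(obj)
        except ValidationError as exc:
            for err in exc.errors():
                loc = ".".join(str(p) for p in err["loc"]) or "<record>"
                problems.append(f"{ident}: {loc}: {err['msg']}")
            continue
        violations: List[Violation] = validate_record(record)
        if violations:
            problems.extend(f"{ident}: {v.code}: {v.message}" for v in violations)
            continue
        records.append(record)
    if problems:
        raise ExamRecordError(problems)
    return records


def read_rating_matrix(path: PathLike) -> RatingMatrix:
    """Read a delimited subjects x raters table.

    First column is the subject id; every remaining column is one rater.
    Empty cells become missing ratings; non-numeric cells and duplicate
    subject ids are errors.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError("rating matrix needs at least 2 rater columns")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate subject ids: {dupes}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == "":
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric rating {cell!r} for subject "
                    f"{df.index[i]!r}, rater {col!r}"
                ) from exc
    return RatingMatrix(list(df.index), list(df.columns), values)


def write_rating_matrix(matrix: RatingMatrix, path: PathLike) -> None:
    df = matrix.to_dataframe()
    df.index.name = "subject_id"
    df.to_csv(path, na_rep="")


def sheets_to_dataframe(sheets: Sequence[NDSScoreSheet]) -> pd.DataFrame:
    """Flat table: subject, rater, scale version, 7 rating columns
    (+2 binary columns for the pilot scale), total."""
    rows = []
    for s in sheets:
        row: Dict[str, object] = {
            "subject_id": s.subject_id,
            "rater_id": s.rater_id if s.rater_id is not None else "",
            "scale_version": s.scale_version,
        }
        row.update({cat: s.category_ratings[cat] for cat in CATEGORIES})
        if s.binary_items is not None:
            row.update({item: s.binary_items[item] for item in BINARY_ITEMS})
        row["total"] = s.total
        rows.append(row)
    return pd.DataFrame(rows)


def write_score_sheets(
    sheets: Sequence[NDSScoreSheet], path: PathLike, fmt: str = "csv"
) -> None:
    if fmt == "csv":
        sheets_to_dataframe(sheets).to_csv(path, index=False)
    elif fmt == "json":
        payload = [json.loads(s.model_dump_json()) for s in sheets]
        Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_score_sheets(path: PathLike) -> List[NDSScoreSheet]:
    """Read score sheets back from either the CSV or the JSON layout."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        return [NDSScoreSheet.model_validate(obj) for obj in raw]
    df = pd.read_csv(path, keep_default_na=False)
    sheets = []
    for _, row in df.iterrows():
        version = row["scale_version"]
        binary = None
        if version == "pilot9":
            binary = {item: int(row[item]) for item in BINARY_ITEMS}
        sheets.append(
            NDSScoreSheet(
                subject_id=str(row["subject_id"]),
                rater_id=str(row["rater_id"]) or None,
                scale_version=version,
                category_ratings={cat: int(row[cat]) for cat in CATEGORIES},
                binary_items=binary,
                total=int(row["total"]),
            )
        )
    return sheets
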