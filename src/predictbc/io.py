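"""Cohort CSV and model JSON input/output.

Cohort files are RFC-4180 CSV, UTF-8, '.' decimal separator, with columns
age, size_mm, nodes, grade, screen, er, chemo, hormone, time_years, event.
Booleans are coded {0,1}, ER status {pos,neg}, event {breast,other,censored}.
Invalid rows are reported with their file line number.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .model import COHORT_COLUMNS, ModelCoefficients

__all__ = [
    "CohortSchema",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_model",
    "write_model",
    "model_sha256",
]


@dataclass(frozen=True)
class CohortSchema:
    """Column names and admissible values for a cohort CSV."""

    columns: tuple[str, ...] = COHORT_COLUMNS
    er_values: tuple[str, ...] = ("pos", "neg")
    event_values: tuple[str, ...] = ("breast", "other", "censored")
    na_token: str = ""


class CohortValidationError(SchemaError):
    """Raised when rows fail validation; carries the rejection report."""

    def __init__(self, report: pd.DataFrame):
        self.report = report
        lines = "; ".join(
            f"line {int(r.line)}: {r.field} {r.reason}" for r in report.head(5).itertuples()
        )
        more = "" if len(report) <= 5 else f" (+{len(report) - 5} more)"
        super().__init__(f"{len(report)} invalid row(s): {lines}{more}")


def _row_checks(df: pd.DataFrame, schema: CohortSchema):
    """Yield (mask_of_bad_rows, field, reason) tuples."""
    num = {c: pd.to_numeric(df[c], errors="coerce") for c in
           ("age", "size_mm", "nodes", "grade", "screen", "chemo", "hormone", "time_years")}
    yield ~np.isfinite(num["age"]) | (num["age"] <= 0), "age", "must be a positive number"
    yield ~np.isfinite(num["size_mm"]) | (num["size_mm"] < 1), "size_mm", "must be >= 1 mm"
    nodes = num["nodes"]
    yield ~np.isfinite(nodes) | (nodes < 0) | (nodes != nodes.round()), "nodes", "must be a non-negative integer"
    yield ~num["grade"].isin([1, 2, 3]), "grade", "must be 1, 2 or 3"
    for flag in ("screen", "chemo", "hormone"):
        yield ~num[flag].isin([0, 1]), flag, "must be 0 or 1"
    yield ~df["er"].astype(str).isin(schema.er_values), "er", f"must be one of {schema.er_values}"
    yield ~df["event"].astype(str).isin(schema.event_values), "event", f"must be one of {schema.event_values}"
    time = num["time_years"]
    yield (~np.isfinite(time) | (time < 0)) & ~time.isna(), "time_years", "must be >= 0"


def read_cohort(
    source,
    schema: CohortSchema | None = None,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`CohortValidationError` (with a line/field/reason report)
    if any row is invalid, unless ``skip_invalid`` is set, in which case the
    offending rows are dropped.  Missing required columns raise SchemaError.
    """
    schema = schema or CohortSchema()
    try:
        df = pd.read_csv(source, na_values=[schema.na_token], keep_default_na=True)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse cohort CSV: {exc}") from exc
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing required column(s): {', '.join(missing)}")
    df = df[list(schema.columns)]
    rejects = []
    bad_any = np.zeros(len(df), dtype=bool)
    for mask, fieldname, reason in _row_checks(df, schema):
        mask = np.asarray(mask, dtype=bool)
        for pos in np.flatnonzero(mask):
            rejects.append({"line": int(pos) + 2, "field": fieldname, "reason": reason})
        bad_any |= mask
    if rejects:
        report = pd.DataFrame(rejects).sort_values("line", kind="stable").reset_index(drop=True)
        if not skip_invalid:
            raise CohortValidationError(report)
        df = df.loc[~bad_any]
    out = df.reset_index(drop=True)
    for c in ("nodes", "grade", "screen", "chemo", "hormone"):
        out[c] = out[c].astype(int)
    for c in ("age", "size_mm", "time_years"):
        out[c] = out[c].astype(float)
    out["er"] = out["er"].astype(str)
    out["event"] = out["event"].astype(str)
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, lineterminator="\n")


def read_model(path) -> ModelCoefficients:
    text = Path(path).read_text(encoding="utf-8")
    return ModelCoefficients.from_json(text)


def write_model(model: ModelCoefficients, path) -> None:
    Path(path).write_text(model.to_json() + "\n", encoding="utf-8")


def model_sha256(model: ModelCoefficients) -> str:
    """Digest of the canonical JSON serialization (logged in every report)."""
    return hashlib.sha256(model.to_json().encode("utf-8")).hexdigest()[:16]
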