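"""TSV readers/writers with schema validation.

All tabular inputs and outputs use one dialect: UTF-8, tab-delimited, one
header row, '.' decimal separator. Validation errors name the offending
row (1-based, excluding the header) and column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

__all__ = ["TableSchema", "TableValidationError", "SCHEMAS", "read_table", "write_table"]


class TableValidationError(ValueError):
    pass


def _fraction(x: float) -> bool:
    return 0.0 <= x <= 1.0


def _percent(x: float) -> bool:
    return 0.0 <= x <= 100.0


def _nonneg(x: float) -> bool:
    return x >= 0


def _positive(x: float) -> bool:
    return x > 0


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict[str, type]  # required columns and their dtypes
    checks: dict[str, tuple[Callable[[float], bool], str]] = None  # column -> (check, message)
    primary_key: tuple[str, ...] = ()
    optional: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    "coverage": TableSchema(
        name="coverage",
        columns={
            "sample_id": str,
            "mag_id": str,
            "breadth": float,
            "n_reads": float,
            "read_length": float,
            "mag_length": float,
        },
        checks={
            "breadth": (_fraction, "breadth must be a fraction in [0, 1]"),
            "n_reads": (_nonneg, "n_reads must be ≥ 0"),
            "mag_length": (_positive, "mag_length must be positive"),
        },
        primary_key=("sample_id", "mag_id"),
        optional=("depth",),
    ),
    "quality": TableSchema(
        name="quality",
        columns={"mag_id": str, "completeness": float, "contamination": float, "domain": str},
        checks={
            "completeness": (_percent, "completeness must be a percent in [0, 100]"),
            "contamination": (_nonneg, "contamination must be ≥ 0"),
        },
        primary_key=("mag_id",),
        optional=("role",),
    ),
    "taxonomy": TableSchema(
        name="taxonomy",
        columns={
            "mag_id": str,
            "domain": str,
            "phylum": str,
            "class": str,
            "order": str,
            "family": str,
            "genus": str,
            "species": str,
        },
        primary_key=("mag_id",),
    ),
    "ko": TableSchema(
        name="ko",
        columns={"genome_id": str, "ko": str},
        primary_key=("genome_id", "ko"),
    ),
    "rrna": TableSchema(
        name="rrna",
        columns={"sample_id": str, "mag_id": str, "assembly_rrna": int, "read_rrna": int},
        primary_key=("sample_id", "mag_id"),
    ),
    "manifest": TableSchema(
        name="manifest",
        columns={"sample_id": str, "declared_lfs_name": str, "total_depth_bp": float},
        checks={"total_depth_bp": (_positive, "total_depth_bp must be positive")},
        primary_key=("sample_id",),
        optional=("read_length", "duplicate_of", "misidentified"),
    ),
    "ani": TableSchema(
        name="ani",
        columns={"mag_a": str, "mag_b": str, "ani": float, "af": float},
        checks={
            "ani": (_percent, "ANI must be a percent in [0, 100]"),
            "af": (_percent, "AF must be a percent in [0, 100]"),
        },
    ),
    "modules": TableSchema(
        name="modules",
        columns={"module_id": str, "name": str, "definition": str},
        primary_key=("module_id",),
    ),
}


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Raises :class:`TableValidationError` naming the first offending cell.
    """
    if isinstance(schema, str):
        try:
            schema = SCHEMAS[schema]
        except KeyError:
            raise KeyError(f"unknown table schema {schema!r}") from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in schema.columns if c not in frame.columns]
    if missing:
        raise TableValidationError(
            f"{schema.name} table {path.name}: missing column(s) {missing}"
        )
    for column, dtype in schema.columns.items():
        if dtype in (float, int):
            converted = pd.to_numeric(frame[column], errors="coerce")
            bad = converted.isna() & (frame[column] != "")
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise TableValidationError(
                    f"{schema.name} table {path.name}: row {row}, column {column!r}: "
                    f"malformed number {frame[column][bad.idxmax()]!r}"
                )
            frame[column] = converted
    for column in schema.optional:
        if column in frame.columns:
            converted = pd.to_numeric(frame[column], errors="coerce")
            if not converted.isna().any():
                frame[column] = converted
    for column, (check, message) in (schema.checks or {}).items():
        values = frame[column]
        ok = values.map(lambda v: bool(check(v)))
        if not ok.all():
            row = int((~ok).idxmax()) + 1
            raise TableValidationError(
                f"{schema.name} table {path.name}: row {row}, column {column!r}: "
                f"value {values[(~ok).idxmax()]!r} invalid — {message}"
            )
    if schema.primary_key:
        dup = frame.duplicated(subset=list(schema.primary_key))
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise TableValidationError(
                f"{schema.name} table {path.name}: row {row}: duplicate primary key "
                f"{tuple(frame.loc[dup.idxmax(), list(schema.primary_key)])}"
            )
    return frame


def write_table(frame: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a TSV table, optionally with sorted rows for byte-stable output."""
    out = frame
    if sort_by:
        out = frame.sort_values(sort_by).reset_index(drop=True)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False)
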