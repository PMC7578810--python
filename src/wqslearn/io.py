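"""Validated readers/writers for the cohort CSV schemas and JSON results.

Single source of truth for column names, units and categorical level sets.
CSV files are RFC-4180 with a header row, UTF-8, '.' decimal.  Units are
schema metadata, never encoded in column names: blood/urine/saliva
concentrations are ug/L, hair/nails ug/g.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import COMPONENTS, MATRICES, OUTCOMES, SES_LEVELS, VIDEOGAME_LEVELS
from .errors import SchemaError

UNITS = {mat: ("ug/g" if mat in ("hair", "nails") else "ug/L") for mat in MATRICES}


@dataclass
class ColumnSpec:
    name: str
    dtype: str                       # 'str', 'float', 'int', 'category'
    levels: tuple = ()
    minimum: float | None = None
    maximum: float | None = None
    strict_min: bool = False
    units: str | None = None


@dataclass
class SchemaSpec:
    """Ordered column specification for one table."""

    name: str
    columns: tuple = field(default_factory=tuple)

    def column_names(self) -> list:
        return [c.name for c in self.columns]


SUBJECTS_SCHEMA = SchemaSpec("subjects", (
    ColumnSpec("subject_id", "str"),
    ColumnSpec("sex", "category", levels=("girl", "boy")),
    ColumnSpec("age", "float", minimum=10.0, maximum=14.0, units="years"),
    ColumnSpec("ses", "category", levels=SES_LEVELS),
    ColumnSpec("videogames", "category", levels=VIDEOGAME_LEVELS),
    ColumnSpec("iq", "float", minimum=0.0, strict_min=True),
))

EXPOSURES_SCHEMA = SchemaSpec("exposures", (
    (ColumnSpec("subject_id", "str"),)
    + tuple(ColumnSpec(c, "float", minimum=0.0, strict_min=True,
                       units=UNITS[c.split("_")[0]]) for c in COMPONENTS)
))

TRIALS_SCHEMA = SchemaSpec("trials", (
    ColumnSpec("subject_id", "str"),
    ColumnSpec("trial", "int", minimum=1, maximum=8),
    ColumnSpec("time_s", "float", minimum=0.0, maximum=180.0, strict_min=True,
               units="s"),
    ColumnSpec("distance", "float", minimum=0.0, strict_min=True,
               units="digital units"),
    ColumnSpec("wm_errors", "int", minimum=0),
    ColumnSpec("rm_errors", "int", minimum=0),
))

CURVES_SCHEMA = SchemaSpec("curves", (
    ColumnSpec("subject_id", "str"),
    ColumnSpec("outcome", "category", levels=OUTCOMES),
    ColumnSpec("slope", "float"),
    ColumnSpec("slope_se", "float", minimum=0.0),
))

SCHEMAS = {s.name: s for s in
           (SUBJECTS_SCHEMA, EXPOSURES_SCHEMA, TRIALS_SCHEMA, CURVES_SCHEMA)}


def _check_column(table: pd.DataFrame, spec: ColumnSpec, table_name: str) -> pd.Series:
    col = table[spec.name]
    if spec.dtype == "str":
        return col.astype(str)
    if spec.dtype == "category":
        bad = ~col.astype(str).isin(spec.levels)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{table_name}: row {row}, column {spec.name!r}: "
                f"unknown level {col.iloc[row]!r} (allowed: {spec.levels})")
        return col.astype(str)
    numeric = pd.to_numeric(col, errors="coerce")
    bad = numeric.isna() & col.notna()
    if numeric.isna().any():
        row = int(np.flatnonzero(numeric.isna())[0])
        raise SchemaError(f"{table_name}: row {row}, column {spec.name!r}: "
                          f"missing or non-numeric value {col.iloc[row]!r}")
    if spec.dtype == "int" and (numeric != numeric.round()).any():
        row = int(np.flatnonzero(numeric != numeric.round())[0])
        raise SchemaError(f"{table_name}: row {row}, column {spec.name!r}: "
                          f"non-integer value {col.iloc[row]!r}")
    if spec.minimum is not None:
        viol = numeric < spec.minimum if not spec.strict_min else numeric <= spec.minimum
        if viol.any():
            row = int(np.flatnonzero(viol)[0])
            raise SchemaError(f"{table_name}: row {row}, column {spec.name!r}: "
                              f"value {numeric.iloc[row]} below the allowed minimum")
    if spec.maximum is not None and (numeric > spec.maximum).any():
        row = int(np.flatnonzero(numeric > spec.maximum)[0])
        raise SchemaError(f"{table_name}: row {row}, column {spec.name!r}: "
                          f"value {numeric.iloc[row]} above the allowed maximum")
    return numeric.astype(int if spec.dtype == "int" else float)


def read_table(path, schema: SchemaSpec | str) -> pd.DataFrame:
    """Read and validate one CSV table against its schema.

    Raises SchemaError (never a bare parser crash) naming the first offending
    row and column.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{schema.name}: cannot parse {path}: {exc}") from exc
    missing = [c for c in schema.column_names() if c not in table.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing columns {missing}")
    out = pd.DataFrame({spec.name: _check_column(table, spec, schema.name)
                        for spec in schema.columns})
    return out


def validate_cohort(subjects: pd.DataFrame, exposures: pd.DataFrame | None = None,
                    trials: pd.DataFrame | None = None) -> None:
    """Cross-reference subject ids across the linked tables."""
    ids = set(subjects["subject_id"])
    if len(ids) != len(subjects):
        raise SchemaError("subjects: duplicate subject_id values")
    for name, tab in (("exposures", exposures), ("trials", trials)):
        if tab is None:
            continue
        orphan = set(tab["subject_id"]) - ids
        if orphan:
            raise SchemaError(f"{name}: unknown subject ids {sorted(orphan)[:5]}")


def write_tables(tables: dict, out_dir) -> dict:
    """Write the cohort tables as CSV; returns {name: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def _jsonable(obj, path="result"):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, f"{path}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, f"{path}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v, path) for v in obj.tolist()]
    if isinstance(obj, (str, int, bool)) or obj is None:
        return obj
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return obj
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict(), path)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"), path)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__}, path)
    raise SchemaError(f"unserializable field at {path}: {type(obj).__name__}")


def write_results(record, path) -> None:
    """Serialise a result record to JSON, round-tripping numeric fields at
    full double precision (json uses repr, which is exact for floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(record), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
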