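"""Reading and writing measurement tables and analysis reports.

The canonical input is a long-format CSV (RFC-4180, header row required):
one row per measurement, default header
``subject_id,subject_index,eye,plane,value_mm,sex``.  Column names are
remappable through :class:`CsvSchema`.  A wide-format convenience reader
(one row per subject, one column per site) is provided for spreadsheets
laid out the way clinical data often arrive.

Chronological order is load-bearing for the learning curve, so the subject
index must be an explicit column; ``infer_order=True`` opts in to "row
order is chronological order" for files that lack one.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import DuplicateRecordError, RowError, SchemaError
from .records import DEFAULT_SITES, SEXES, MeasurementRecord

PathLike = Union[str, Path]


@dataclass(frozen=True)
class CsvSchema:
    """Mapping from logical fields to CSV column names.

    ``site_columns`` may list several columns (default ``eye`` and
    ``plane``); their values are joined with ``_`` into one site label.
    """

    subject_id: str = "subject_id"
    subject_index: str = "subject_index"
    site_columns: Sequence[str] = ("eye", "plane")
    value: str = "value_mm"
    sex: Optional[str] = "sex"


DEFAULT_SCHEMA = CsvSchema()


def _parse_sex(raw: Optional[str]) -> Optional[str]:
    if raw is None:
        return None
    raw = raw.strip().lower()
    if raw in ("", "na", "nan", "none"):
        return None
    if raw in ("m",):
        return "male"
    if raw in ("f",):
        return "female"
    if raw in SEXES:
        return raw
    return "unknown"


def read_measurements(
    path: PathLike,
    schema: CsvSchema = DEFAULT_SCHEMA,
    infer_order: bool = False,
) -> list[MeasurementRecord]:
    """Read a long-format measurement CSV into validated records.

    Parameters
    ----------
    path : path
        CSV file with a header row.
    schema : CsvSchema
        Column-name mapping.
    infer_order : bool
        When True and the subject-index column is absent, subjects are
        numbered 1, 2, ... in order of first appearance.  Off by default:
        silent order inference would corrupt the learning-curve abscissa.

    Returns
    -------
    list of MeasurementRecord, sorted by (subject_index, subject_id, site);
    the row count of the file is preserved.

    Raises
    ------
    SchemaError, RowError, DuplicateRecordError
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        required = [schema.subject_id, schema.value, *schema.site_columns]
        have_index = schema.subject_index in header
        if not have_index and not infer_order:
            required.append(schema.subject_index)
        for col in required:
            if col not in header:
                raise SchemaError(f"missing required column {col!r} in {path}")
        have_sex = schema.sex is not None and schema.sex in header

        records: list[MeasurementRecord] = []
        order: dict[str, int] = {}  # subject_id -> index (inferred or checked)
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            sid = (row[schema.subject_id] or "").strip()
            if not sid:
                raise RowError(lineno, "empty subject id")
            raw_value = (row[schema.value] or "").strip()
            try:
                value = float(raw_value)
            except ValueError:
                raise RowError(lineno, f"non-numeric value {raw_value!r}") from None
            if not value > 0:
                raise RowError(lineno, f"value must be positive, got {value}")
            if have_index:
                raw_idx = (row[schema.subject_index] or "").strip()
                try:
                    idx = int(raw_idx)
                except ValueError:
                    raise RowError(lineno, f"non-integer subject index {raw_idx!r}") from None
                if idx < 1:
                    raise RowError(lineno, f"subject index must be >= 1, got {idx}")
                if order.setdefault(sid, idx) != idx:
                    raise RowError(
                        lineno,
                        f"subject {sid!r} appears with indices {order[sid]} and {idx}",
                    )
            else:
                idx = order.setdefault(sid, len(order) + 1)
            site = "_".join((row[c] or "").strip() for c in schema.site_columns)
            key = (sid, site)
            if key in seen:
                raise DuplicateRecordError(
                    f"duplicate measurement for subject {sid!r} at site {site!r} (line {lineno})"
                )
            seen.add(key)
            sex = _parse_sex(row.get(schema.sex)) if have_sex else None
            records.append(
                MeasurementRecord(
                    subject_index=idx, subject_id=sid, site=site, value=value, sex=sex
                )
            )
    records.sort(key=lambda r: (r.subject_index, r.subject_id, r.site))
    return records


def write_measurements(
    records: Sequence[MeasurementRecord],
    path: PathLike,
    schema: CsvSchema = DEFAULT_SCHEMA,
) -> None:
    """Write records to CSV in the canonical long format (inverse of
    :func:`read_measurements` up to row order)."""
    path = Path(path)
    n_site_cols = len(schema.site_columns)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        header = [schema.subject_id, schema.subject_index, *schema.site_columns, schema.value]
        if schema.sex is not None:
            header.append(schema.sex)
        writer.writerow(header)
        for rec in records:
            parts = rec.site.split("_", n_site_cols - 1)
            if len(parts) != n_site_cols:
                parts = [rec.site] + [""] * (n_site_cols - 1)
            row = [rec.subject_id, rec.subject_index, *parts, repr(rec.value)]
            if schema.sex is not None:
                row.append(rec.sex if rec.sex is not None else "")
            writer.writerow(row)


def read_measurements_wide(
    path: PathLike,
    value_columns: Sequence[str] = DEFAULT_SITES,
    subject_id: str = "subject_id",
    subject_index: str = "subject_index",
    sex: Optional[str] = "sex",
    infer_order: bool = False,
) -> list[MeasurementRecord]:
    """Convenience converter for wide files: one row per subject, one value
    column per site.  Melts to long form and applies the same validation."""
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in value_columns:
        if col not in frame.columns:
            raise SchemaError(f"missing site column {col!r} in {path}")
    if subject_id not in frame.columns:
        raise SchemaError(f"missing required column {subject_id!r} in {path}")
    records = []
    order: dict[str, int] = {}
    for pos, row in frame.iterrows():
        sid = str(row[subject_id])
        if subject_index in frame.columns:
            idx = int(row[subject_index])
        elif infer_order:
            idx = order.setdefault(sid, len(order) + 1)
        else:
            raise SchemaError(
                f"missing required column {subject_index!r} (pass infer_order=True "
                "to number subjects by row order)"
            )
        sx = _parse_sex(str(row[sex])) if sex in frame.columns else None
        for site in value_columns:
            value = float(row[site])
            if not value > 0:
                raise RowError(int(pos) + 2, f"value must be positive, got {value}")
            records.append(
                MeasurementRecord(
                    subject_index=idx, subject_id=sid, site=site, value=value, sex=sx
                )
            )
    records.sort(key=lambda r: (r.subject_index, r.subject_id, r.site))
    return records


def write_report(report, path: PathLike, curve_path: Optional[PathLike] = None) -> None:
    """Write an analysis report as JSON plus the fitted-curve CSV.

    ``curve_path`` defaults to the JSON path with a ``_curve.csv`` suffix.
    The curve table has one row per subject: index, observed within-subject
    variance, fitted value, residual.
    """
    path = Path(path)
    if curve_path is None:
        curve_path = path.with_name(path.stem + "_curve.csv")
    with path.open("w") as handle:
        json.dump(report.to_dict(), handle, indent=2)
        handle.write("\n")
    report.curve.to_csv(curve_path, index=False)


def read_report(path: PathLike) -> dict:
    """Parse a JSON report written by :func:`write_report`."""
    with Path(path).open() as handle:
        return json.load(handle)
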