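"""The per-sample CSF record schema and validated CSV / JSON-lines IO.

One :class:`CSFRecord` holds the laboratory panel of a single lumbar
puncture: energy analytes (mmol/L), blood-CSF-barrier analytes (total
protein in mg/L, albumin in CSF and serum in matching units so only their
ratio matters), beta-2-microglobulin (mg/L), cytology (counts per µL,
differential fractions, malignant-cell flag) and the three
intrathecal-synthesis percentages.  Optional analytes are ``None``.

Files are comma-separated UTF-8 with a header, "." decimal by default; a
locale option accepts "," decimals.  Unknown columns are ignored with a
warning; malformed rows are collected with their row numbers and either
skipped (with a log entry) or escalated, per configuration.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_FRACTION_SUM_TOL = 1e-9


@dataclass
class CSFRecord:
    record_id: str
    age_years: float
    lactate_csf: Optional[float] = None
    glucose_csf: Optional[float] = None
    glucose_serum: Optional[float] = None
    tp_csf: Optional[float] = None
    albumin_csf: Optional[float] = None
    albumin_serum: Optional[float] = None
    beta2m_csf: Optional[float] = None
    leukocytes: Optional[float] = None
    erythrocytes: Optional[float] = None
    fraction_lymphocyte: Optional[float] = None
    fraction_monocyte: Optional[float] = None
    fraction_granulocyte: Optional[float] = None
    malignant_cells_present: bool = False
    it_igg: Optional[float] = None
    it_iga: Optional[float] = None
    it_igm: Optional[float] = None

    def validate(self) -> None:
        """Raise ValueError on a physically impossible record."""
        if self.age_years < 0:
            raise ValueError(f"negative age: {self.age_years}")
        for name in (
            "lactate_csf", "glucose_csf", "glucose_serum", "tp_csf",
            "albumin_csf", "albumin_serum", "beta2m_csf",
            "leukocytes", "erythrocytes", "it_igg", "it_iga", "it_igm",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"negative {name}: {value}")
        fracs = [
            self.fraction_lymphocyte, self.fraction_monocyte, self.fraction_granulocyte,
        ]
        present = [f for f in fracs if f is not None]
        for f in present:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"cytology fraction outside [0, 1]: {f}")
        if present and sum(present) > 1.0 + _FRACTION_SUM_TOL:
            raise ValueError(f"cytology fractions sum to {sum(present)} > 1")


_FLOAT_FIELDS = tuple(
    f.name for f in dc_fields(CSFRecord)
    if f.name not in ("record_id", "malignant_cells_present")
)
COLUMNS = tuple(f.name for f in dc_fields(CSFRecord))

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


class RecordReadError(ValueError):
    """Raised on malformed input; carries per-row error details."""

    def __init__(self, message: str, row_errors: Optional[list[tuple[int, str]]] = None):
        super().__init__(message)
        self.row_errors = row_errors or []


def _parse_float(text: str, decimal: str) -> Optional[float]:
    text = text.strip()
    if text in ("", "NA", "NaN", "nan", "None"):
        return None
    if decimal == ",":
        text = text.replace(",", ".")
    return float(text)


def _record_from_mapping(raw: dict, decimal: str = ".") -> CSFRecord:
    kwargs: dict = {}
    for name in _FLOAT_FIELDS:
        if name in raw and raw[name] is not None:
            value = raw[name]
            kwargs[name] = _parse_float(value, decimal) if isinstance(value, str) else float(value)
    flag = raw.get("malignant_cells_present", False)
    if isinstance(flag, str):
        lowered = flag.strip().lower()
        if lowered in _TRUE:
            flag = True
        elif lowered in _FALSE:
            flag = False
        else:
            raise ValueError(f"unparseable boolean: {flag!r}")
    kwargs["malignant_cells_present"] = bool(flag)
    if "record_id" not in raw or raw["record_id"] in (None, ""):
        raise ValueError("missing record_id")
    if kwargs.get("age_years") is None:
        raise ValueError("missing age_years")
    record = CSFRecord(record_id=str(raw["record_id"]), **kwargs)
    record.validate()
    return record


def read_records(
    path: str | Path,
    fmt: Optional[str] = None,
    *,
    decimal: str = ".",
    on_row_error: str = "raise",
) -> list[CSFRecord]:
    """Read validated records from a CSV or JSON-lines file.

    ``fmt`` is "csv" or "jsonl" (inferred from the suffix when omitted).
    ``on_row_error`` is "raise" (default) or "skip"; skipped rows are logged
    with their 1-based row number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson", ".json") else "csv"
    if on_row_error not in ("raise", "skip"):
        raise ValueError(f"on_row_error must be 'raise' or 'skip', got {on_row_error!r}")

    records: list[CSFRecord] = []
    errors: list[tuple[int, str]] = []

    if fmt == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise RecordReadError(f"{path}: empty file (no header)")
            unknown = set(reader.fieldnames) - set(COLUMNS)
            if "record_id" not in reader.fieldnames or "age_years" not in reader.fieldnames:
                raise RecordReadError(
                    f"{path}: malformed header (record_id and age_years required), "
                    f"got {reader.fieldnames}"
                )
            if unknown:
                log.warning("%s: ignoring unknown columns %s", path, sorted(unknown))
            for i, row in enumerate(reader, start=2):
                try:
                    records.append(_record_from_mapping(
                        {k: v for k, v in row.items() if k in COLUMNS}, decimal))
                except (ValueError, TypeError) as exc:
                    errors.append((i, str(exc)))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    raw = json.loads(line)
                    records.append(_record_from_mapping(
                        {k: v for k, v in raw.items() if k in COLUMNS}, decimal))
                except (ValueError, TypeError) as exc:
                    errors.append((i, str(exc)))

    if errors:
        if on_row_error == "raise":
            detail = "; ".join(f"row {i}: {msg}" for i, msg in errors[:5])
            raise RecordReadError(f"{path}: {len(errors)} malformed row(s): {detail}", errors)
        for i, msg in errors:
            log.warning("%s: skipping row %d: %s", path, i, msg)
    log.info("%s: read %d record(s), %d skipped", path, len(records), len(errors))
    return records


def write_records(records: Iterable[CSFRecord], path: str | Path, fmt: Optional[str] = None) -> None:
    """Write records as CSV or JSON-lines (schema columns, "." decimal)."""
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson", ".json") else "csv"
    rows = [{name: getattr(r, name) for name in COLUMNS} for r in records]
    if fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMNS)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")


def records_to_frame(records: Iterable[CSFRecord]) -> pd.DataFrame:
    """Tabulate records into a DataFrame with the schema's column order."""
    return pd.DataFrame([{name: getattr(r, name) for name in COLUMNS} for r in records],
                        columns=list(COLUMNS))


def frame_to_records(frame: pd.DataFrame) -> list[CSFRecord]:
    """Convert a schema-conformant DataFrame back to validated records."""
    out = []
    for raw in frame.to_dict(orient="records"):
        clean = {k: v for k, v in raw.items()
                 if k in COLUMNS and not (isinstance(v, float) and math.isnan(v))}
        out.append(_record_from_mapping(clean))
    return out
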