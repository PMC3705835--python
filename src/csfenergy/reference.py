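"""Age-stratified reference ranges for the basic CSF examination panel.

The table covers the analytes whose reference status enters the control
definition: the glucose quotient Q_glu, CSF lactate, leukocyte count, CSF
total protein (age-bracketed), the albumin quotient Q_alb (age-bracketed,
stored as a dimensionless ratio), CSF beta-2-microglobulin and the three
intrathecal-synthesis percentages (reference value exactly 0 %).

Ranges are inclusive at both limits.  Infant brackets are resolved in days;
year-labelled brackets contain the ages whose floor year lies inside the
printed label, and ages above the oldest printed bracket reuse that bracket.
The table ships as a versioned YAML file so a laboratory can substitute its
own decision limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

import yaml

DAYS_PER_YEAR = 365.25


class Flag(str, Enum):
    LOW = "LOW"
    IN_RANGE = "IN_RANGE"
    HIGH = "HIGH"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class RangeEntry:
    """One parameter/bracket row: limits plus an optional age bracket."""

    low: float
    high: float
    age_days: Optional[tuple[float, float]] = None   # [lo, hi] in days, < 1 y
    age_years: Optional[tuple[int, int]] = None      # [lo, hi] whole years

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low {self.low} > high {self.high}")

    def contains_age(self, age_years: float) -> bool:
        if self.age_days is None and self.age_years is None:
            return True
        if age_years < 1.0:
            if self.age_days is None:
                return False
            lo, hi = self.age_days
            return lo <= age_years * DAYS_PER_YEAR <= hi
        if self.age_years is None:
            return False
        lo_y, hi_y = self.age_years
        return lo_y <= math.floor(age_years) <= hi_y


@dataclass
class ReferenceRangeTable:
    """All reference ranges, keyed by parameter id."""

    version: int
    entries: dict[str, list[RangeEntry]]
    units: dict[str, str] = field(default_factory=dict)

    def lookup_range(self, parameter: str, age_years: float = math.nan) -> tuple[float, float]:
        """Return the (low, high) limits applying to ``parameter`` at ``age_years``.

        Age-independent parameters ignore the age.  Ages above the oldest
        printed bracket fall back to that bracket.
        """
        try:
            rows = self.entries[parameter]
        except KeyError:
            raise KeyError(f"unknown reference parameter: {parameter!r}") from None
        age_dependent = any(r.age_days or r.age_years for r in rows)
        if not age_dependent:
            row = rows[0]
            return row.low, row.high
        if math.isnan(age_years) or age_years < 0:
            raise ValueError(f"age required for age-bracketed parameter {parameter!r}")
        for row in rows:
            if row.contains_age(age_years):
                return row.low, row.high
        # above the oldest bracket: reuse it
        oldest = max((r for r in rows if r.age_years), key=lambda r: r.age_years[1])
        if math.floor(age_years) > oldest.age_years[1]:
            return oldest.low, oldest.high
        raise ValueError(f"no {parameter!r} bracket covers age {age_years}")

    def flag(self, parameter: str, value: Optional[float], age_years: float = math.nan) -> Flag:
        """Flag one analyte value against its age-resolved range."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return Flag.NOT_EVALUABLE
        low, high = self.lookup_range(parameter, age_years)
        if value < low:
            return Flag.LOW
        if value > high:
            return Flag.HIGH
        return Flag.IN_RANGE


def _parse(raw: dict) -> ReferenceRangeTable:
    entries: dict[str, list[RangeEntry]] = {}
    units: dict[str, str] = {}
    for name, spec in raw["parameters"].items():
        scale = float(spec.get("scale", 1.0))
        units[name] = spec.get("units", "")
        rows = []
        for r in spec["ranges"]:
            rows.append(
                RangeEntry(
                    low=float(r["low"]) * scale,
                    high=float(r["high"]) * scale,
                    age_days=tuple(r["age_days"]) if "age_days" in r else None,
                    age_years=tuple(r["age_years"]) if "age_years" in r else None,
                )
            )
        entries[name] = rows
    return ReferenceRangeTable(version=int(raw["version"]), entries=entries, units=units)


def load_reference_table(path: Optional[str] = None) -> ReferenceRangeTable:
    """Load the reference table from ``path`` or from the packaged default."""
    if path is None:
        text = resources.files("csfenergy.data").joinpath("reference_ranges.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _parse(yaml.safe_load(text))


def dump_reference_table(table: ReferenceRangeTable) -> str:
    """Serialise a table back to YAML (load/dump round-trips exactly)."""
    params: dict = {}
    for name, rows in table.entries.items():
        ranges = []
        for r in rows:
            d: dict = {}
            if r.age_days is not None:
                d["age_days"] = list(r.age_days)
            if r.age_years is not None:
                d["age_years"] = list(r.age_years)
            d["low"] = r.low
            d["high"] = r.high
            ranges.append(d)
        params[name] = {"units": table.units.get(name, ""), "ranges": ranges}
    return yaml.safe_dump({"version": table.version, "parameters": params}, sort_keys=False)


# Parameters whose reference status enters record-level flagging.
FLAGGED_PARAMETERS = (
    "q_glu",
    "lactate_csf",
    "leukocytes",
    "tp_csf",
    "q_alb",
    "beta2m_csf",
    "it_igg",
    "it_iga",
    "it_igm",
)


def flag_record(record, table: Optional[ReferenceRangeTable] = None) -> dict[str, Flag]:
    """Flag every evaluable analyte of a :class:`~csfenergy.records.CSFRecord`.

    Missing analytes (including quotients whose denominator is missing) are
    NOT_EVALUABLE.  The result is a plain dict keyed by parameter id; it is
    idempotent and independent of analyte order.
    """
    if table is None:
        table = load_reference_table()
    age = record.age_years

    q_glu = None
    if record.glucose_serum not in (None, 0) and record.glucose_csf is not None:
        q_glu = record.glucose_csf / record.glucose_serum
    q_alb = None
    if record.albumin_serum not in (None, 0) and record.albumin_csf is not None:
        q_alb = record.albumin_csf / record.albumin_serum

    values = {
        "q_glu": q_glu,
        "lactate_csf": record.lactate_csf,
        "leukocytes": record.leukocytes,
        "tp_csf": record.tp_csf,
        "q_alb": q_alb,
        "beta2m_csf": record.beta2m_csf,
        "it_igg": record.it_igg,
        "it_iga": record.it_iga,
        "it_igm": record.it_igm,
    }
    return {name: table.flag(name, values[name], age) for name in FLAGGED_PARAMETERS}
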