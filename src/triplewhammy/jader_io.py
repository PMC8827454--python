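"""Reading, validating and joining spontaneous-report tables.

Spontaneous-report databases in the JADER lineage ship as delimited tables:
``DEMO`` (one row per case: sex, age band, reporting year), ``DRUG`` (one row
per reported drug exposure) and ``REAC`` (one row per reported adverse
reaction, coded as a MedDRA Preferred Term). This module parses those tables
into typed records and joins them into case-level :class:`ReportCase` objects.

Real releases vary in delimiter, text encoding and column naming, so all three
are carried by a :class:`TableDialect`; the defaults match the CSV fixtures
written by :mod:`triplewhammy.synthetic`. Enum-like columns map unrecognised
values to ``"unknown"`` rather than failing: a spontaneous-report row is never
silently dropped at ingestion.

Dates may be complete (``YYYYMMDD``), partial (``YYYYMM`` — retained but
flagged incomplete) or absent. Downstream duration arithmetic treats partial
dates as unknown, because time-to-onset needs day resolution.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .defaults import DEFAULT_TOPICAL_KEYWORDS, normalize_name
from .errors import SchemaError, ValidationError

Schema = Literal["demo", "drug", "reac"]

_SEX_MAP = {
    "male": "male", "m": "male", "男性": "male", "男": "male",
    "female": "female", "f": "female", "女性": "female", "女": "female",
}

_INVOLVEMENT_MAP = {
    "suspect": "suspect", "suspect drug": "suspect", "被疑薬": "suspect",
    "concomitant": "concomitant", "concomitant drug": "concomitant",
    "併用薬": "concomitant",
    "interaction": "interaction", "相互作用": "interaction",
}

_OUTCOME_SET = {"recovered", "remission", "unrecovered", "death", "with sequelae"}

#: schema -> (mandatory fields, optional fields), in canonical column order
SCHEMA_FIELDS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "demo": (("case_id", "sex", "age"), ("report_year",)),
    "drug": (("case_id", "drug_name"), ("involvement", "route", "start_date")),
    "reac": (("case_id", "pt"), ("onset_date", "outcome")),
}


@dataclass(frozen=True)
class TableDialect:
    """How a physical table maps onto a schema.

    ``columns`` maps schema field names to source column headers; unmapped
    fields use the field name itself as the header. ``topical_keywords`` is the
    dosage-form keyword list used to derive the systemic/topical route.
    """

    delimiter: str = ","
    encoding: str = "utf-8"
    columns: Mapping[str, str] = field(default_factory=dict)
    topical_keywords: tuple[str, ...] = DEFAULT_TOPICAL_KEYWORDS

    def column_for(self, field_name: str) -> str:
        return self.columns.get(field_name, field_name)


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: str = "unknown"  # male | female | unknown
    age_band: str = "unknown"  # "20s", "70s", ... or "unknown"
    report_year: int | None = None


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    involvement: str = "unknown"  # suspect | concomitant | interaction | unknown
    route: str = "unknown"  # systemic | topical | unknown
    start_date: dt.date | None = None
    start_date_incomplete: bool = False  # year-month only: kept, unusable for durations


@dataclass(frozen=True)
class ReacRecord:
    case_id: str
    pt: str
    onset_date: dt.date | None = None
    onset_date_incomplete: bool = False
    outcome: str = "unknown"


@dataclass(frozen=True)
class ReportCase:
    """One spontaneous-report case: demographics plus all drug and reaction rows."""

    demo: DemoRecord
    drugs: tuple[DrugRecord, ...] = ()
    reactions: tuple[ReacRecord, ...] = ()

    @property
    def case_id(self) -> str:
        return self.demo.case_id


@dataclass(frozen=True)
class OrphanReport:
    """Drug/reaction rows whose case id is absent from DEMO."""

    drug_case_ids: tuple[str, ...] = ()
    reac_case_ids: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return not self.drug_case_ids and not self.reac_case_ids


_DATE_RE = re.compile(r"^(\d{4})(?:[-/]?(\d{2})(?:[-/]?(\d{2}))?)?$")


def parse_report_date(raw: str) -> tuple[dt.date | None, bool]:
    """Parse ``YYYYMMDD`` / ``YYYY-MM-DD`` style dates.

    Returns ``(date, False)`` for a complete date, ``(None, True)`` for a
    partial year or year-month value, and ``(None, False)`` for blank or
    unparseable input.
    """
    raw = raw.strip()
    if not raw:
        return None, False
    m = _DATE_RE.match(raw)
    if m is None:
        return None, False
    year, month, day = m.groups()
    if day is None:
        return None, True  # partial: year or year-month only
    try:
        return dt.date(int(year), int(month), int(day)), False
    except ValueError:
        return None, False


def _fmt_date(date: dt.date | None, incomplete: bool) -> str:
    if date is not None:
        return date.strftime("%Y%m%d")
    return "190001" if incomplete else ""


def derive_route(raw: str, topical_keywords: Sequence[str]) -> str:
    """Map a free-text route / dosage-form value to systemic|topical|unknown.

    Blank means unknown; a topical keyword match means topical; anything else
    is systemic (oral, injection, unrecognised forms alike).
    """
    raw = normalize_name(raw)
    if not raw:
        return "unknown"
    if raw in {"systemic", "topical"}:
        return raw
    for kw in topical_keywords:
        if kw in raw:
            return "topical"
    return "systemic"


def _row_to_demo(row: Mapping[str, str]) -> DemoRecord:
    year_raw = row.get("report_year", "").strip()
    try:
        year: int | None = int(year_raw)
    except ValueError:
        year = None
    age = row.get("age", "").strip()
    return DemoRecord(
        case_id=row["case_id"].strip(),
        sex=_SEX_MAP.get(normalize_name(row.get("sex", "")), "unknown"),
        age_band=age if age else "unknown",
        report_year=year,
    )


def _row_to_drug(row: Mapping[str, str], dialect: TableDialect) -> DrugRecord:
    date, incomplete = parse_report_date(row.get("start_date", ""))
    return DrugRecord(
        case_id=row["case_id"].strip(),
        drug_name=row["drug_name"].strip(),
        involvement=_INVOLVEMENT_MAP.get(
            normalize_name(row.get("involvement", "")), "unknown"
        ),
        route=derive_route(row.get("route", ""), dialect.topical_keywords),
        start_date=date,
        start_date_incomplete=incomplete,
    )


def _row_to_reac(row: Mapping[str, str]) -> ReacRecord:
    date, incomplete = parse_report_date(row.get("onset_date", ""))
    outcome = row.get("outcome", "").strip()
    if normalize_name(outcome) not in _OUTCOME_SET:
        outcome = "unknown"
    return ReacRecord(
        case_id=row["case_id"].strip(),
        pt=row["pt"].strip(),
        onset_date=date,
        onset_date_incomplete=incomplete,
        outcome=outcome,
    )


def frame_to_records(frame: pd.DataFrame, schema: Schema, dialect: TableDialect | None = None):
    """Convert a raw string DataFrame into typed records (header-keyed).

    Raises :class:`SchemaError` naming the first missing mandatory column.
    Exactly one record is produced per input row.
    """
    dialect = dialect or TableDialect()
    mandatory, optional = SCHEMA_FIELDS[schema]
    colmap: dict[str, str] = {}
    for f in mandatory:
        col = dialect.column_for(f)
        if col not in frame.columns:
            raise SchemaError(f"{schema} table is missing mandatory column {col!r}")
        colmap[f] = col
    for f in optional:
        col = dialect.column_for(f)
        if col in frame.columns:
            colmap[f] = col

    fields = list(colmap)
    columns = [
        ["" if pd.isna(v) else str(v) for v in frame[colmap[f]].tolist()] for f in fields
    ]
    records = []
    for values in zip(*columns):
        row = dict(zip(fields, values))
        if schema == "demo":
            records.append(_row_to_demo(row))
        elif schema == "drug":
            records.append(_row_to_drug(row, dialect))
        else:
            records.append(_row_to_reac(row))
    return records


def read_table(path: str | Path, schema: Schema, dialect: TableDialect | None = None):
    """Read one delimited table into a list of typed records."""
    dialect = dialect or TableDialect()
    try:
        frame = pd.read_csv(
            path,
            sep=dialect.delimiter,
            encoding=dialect.encoding,
            dtype=str,
            keep_default_na=False,
        )
    except UnicodeDecodeError as exc:
        raise OSError(
            f"cannot decode {path} with encoding {dialect.encoding!r}: {exc}"
        ) from exc
    return frame_to_records(frame, schema, dialect)


def records_to_frame(records: Iterable, schema: Schema, dialect: TableDialect | None = None) -> pd.DataFrame:
    """Normalized records back to a table using the dialect's column names."""
    dialect = dialect or TableDialect()
    mandatory, optional = SCHEMA_FIELDS[schema]
    fields = mandatory + optional
    rows = []
    for rec in records:
        if schema == "demo":
            values = {
                "case_id": rec.case_id,
                "sex": rec.sex,
                "age": rec.age_band if rec.age_band != "unknown" else "",
                "report_year": "" if rec.report_year is None else str(rec.report_year),
            }
        elif schema == "drug":
            values = {
                "case_id": rec.case_id,
                "drug_name": rec.drug_name,
                "involvement": rec.involvement if rec.involvement != "unknown" else "",
                "route": rec.route if rec.route != "unknown" else "",
                "start_date": _fmt_date(rec.start_date, rec.start_date_incomplete),
            }
        else:
            values = {
                "case_id": rec.case_id,
                "pt": rec.pt,
                "onset_date": _fmt_date(rec.onset_date, rec.onset_date_incomplete),
                "outcome": rec.outcome if rec.outcome != "unknown" else "",
            }
        rows.append({dialect.column_for(f): values[f] for f in fields})
    columns = [dialect.column_for(f) for f in fields]
    return pd.DataFrame(rows, columns=columns)


def write_table(records: Iterable, path: str | Path, schema: Schema,
                dialect: TableDialect | None = None) -> None:
    dialect = dialect or TableDialect()
    frame = records_to_frame(records, schema, dialect)
    frame.to_csv(
        path,
        sep=dialect.delimiter,
        encoding=dialect.encoding,
        index=False,
        quoting=csv.QUOTE_MINIMAL,
        lineterminator="\n",
    )


def join_cases(
    demo: Sequence[DemoRecord],
    drug: Sequence[DrugRecord] = (),
    reac: Sequence[ReacRecord] = (),
) -> tuple[list[ReportCase], OrphanReport]:
    """Join the three tables into one :class:`ReportCase` per demo case id.

    Drug/reaction rows whose case id does not appear in DEMO are returned in
    the :class:`OrphanReport` instead of being dropped silently. Duplicate
    case ids in DEMO raise :class:`ValidationError` (one row per case is the
    deduplication contract of the ingested release).
    """
    seen: set[str] = set()
    dups: list[str] = []
    for rec in demo:
        if not rec.case_id:
            raise ValidationError("demo record with empty case_id")
        if rec.case_id in seen:
            dups.append(rec.case_id)
        seen.add(rec.case_id)
    if dups:
        raise ValidationError(f"duplicate case ids in demo table: {sorted(set(dups))}")

    drugs_by_case: dict[str, list[DrugRecord]] = {}
    orphan_drugs: list[str] = []
    for rec in drug:
        if rec.case_id in seen:
            drugs_by_case.setdefault(rec.case_id, []).append(rec)
        else:
            orphan_drugs.append(rec.case_id)
    reac_by_case: dict[str, list[ReacRecord]] = {}
    orphan_reacs: list[str] = []
    for rec in reac:
        if rec.case_id in seen:
            reac_by_case.setdefault(rec.case_id, []).append(rec)
        else:
            orphan_reacs.append(rec.case_id)

    cases = [
        ReportCase(
            demo=d,
            drugs=tuple(drugs_by_case.get(d.case_id, ())),
            reactions=tuple(reac_by_case.get(d.case_id, ())),
        )
        for d in demo
    ]
    return cases, OrphanReport(tuple(orphan_drugs), tuple(orphan_reacs))


# ---------------------------------------------------------------------------
# Deposited time-to-onset dataset (supplementary-style XLSX/CSV)

_S9_ALIASES = {
    "case_id": ("case", "id", "no"),
    "pattern": ("pattern", "combination", "group"),
    "order": ("order", "sequence", "last"),
    "duration_days": ("duration", "day", "time"),
}


def load_onset_dataset(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a deposited per-case time-to-onset dataset (XLSX or CSV).

    Expected content: one row per target case with a case identifier, the TW
    combination pattern, the start-order label, and the duration to AKI onset
    in days. Column headers are matched case-insensitively against common
    aliases unless ``column_map`` binds them explicitly.

    Returns a DataFrame with columns ``case_id``, ``pattern``, ``order``,
    ``duration_days`` (float days; missing pattern/order become "unknown").
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        raw = pd.read_excel(path, dtype=str)
    else:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    resolved: dict[str, str] = {}
    lowered = {str(c).strip().lower(): c for c in raw.columns}
    for fld, aliases in _S9_ALIASES.items():
        if column_map and fld in column_map:
            if column_map[fld] not in raw.columns:
                raise SchemaError(f"onset dataset missing mapped column {column_map[fld]!r}")
            resolved[fld] = column_map[fld]
            continue
        for low, orig in lowered.items():
            if any(a in low for a in aliases):
                resolved[fld] = orig
                break
    if "duration_days" not in resolved:
        raise SchemaError("onset dataset: could not identify a duration column")

    out = pd.DataFrame()
    n = len(raw)
    out["case_id"] = (
        raw[resolved["case_id"]].astype(str)
        if "case_id" in resolved
        else [str(i + 1) for i in range(n)]
    )
    for fld in ("pattern", "order"):
        if fld in resolved:
            out[fld] = raw[resolved[fld]].astype(str).str.strip().replace("", "unknown")
        else:
            out[fld] = "unknown"
    out["duration_days"] = pd.to_numeric(raw[resolved["duration_days"]], errors="coerce")
    return out


__all__ = [
    "TableDialect",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "ReportCase",
    "OrphanReport",
    "parse_report_date",
    "derive_route",
    "read_table",
    "frame_to_records",
    "records_to_frame",
    "write_table",
    "join_cases",
    "load_onset_dataset",
    "replace",
]
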