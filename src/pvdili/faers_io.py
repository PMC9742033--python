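"""Reading, validation and deduplication of FAERS-style quarterly ASCII tables.

The public FAERS quarterly data files are dollar-delimited text tables with a
single header row.  This module parses the six table kinds used by the
analysis (DEMO, DRUG, REAC, OUTC, THER, INDI), assembles per-report
:class:`CaseReport` objects and applies the case-level deduplication rule
(keep the highest case version; ties broken by latest received date, then by
largest primary id).

Rows with the wrong number of fields are never silently dropped: they are
counted per table and surfaced in the parse report.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

DELIMITER = "$"

#: The single FAERS dialect accepted by :func:`parse_quarter`.  Column-name
#: aliases from other eras (e.g. the pre-2012 ISR schema) are out of scope.
SCHEMA_VERSION = "faers_ascii_2014"

AGE_UNITS = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
SEX_CODES = frozenset({"F", "M", "UNK"})
OCCUPATION_CODES = frozenset({"MD", "PH", "CN", "OT"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


class SchemaError(ValueError):
    """A table is missing a mandatory column or uses an unknown schema."""


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialDate:
    """A calendar date of possibly reduced precision.

    ``precision`` is one of ``"day"``, ``"month"``, ``"year"`` or
    ``"absent"``; components below the stated precision are ``None``.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None
    precision: str = "absent"

    @property
    def is_absent(self) -> bool:
        return self.precision == "absent"

    def sort_key(self) -> tuple[int, int, int]:
        """Total-order key; absent components compare lowest."""
        return (self.year or 0, self.month or 0, self.day or 0)

    def to_date(self) -> _dt.date:
        if self.precision != "day":
            raise ValueError(f"date has precision {self.precision!r}, not 'day'")
        return _dt.date(self.year, self.month, self.day)

    def quarter(self) -> str | None:
        """Quarter label like ``"2020Q2"``, or None below month precision."""
        if self.precision in ("day", "month"):
            return f"{self.year}Q{(self.month - 1) // 3 + 1}"
        return None

    def raw(self) -> str:
        """The FAERS string form (``YYYYMMDD``/``YYYYMM``/``YYYY``/``""``)."""
        if self.precision == "day":
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.precision == "month":
            return f"{self.year:04d}{self.month:02d}"
        if self.precision == "year":
            return f"{self.year:04d}"
        return ""


ABSENT_DATE = PartialDate()


def parse_partial_date(raw: str | None) -> PartialDate:
    """Parse a FAERS date string into a :class:`PartialDate`.

    ``YYYYMMDD`` gives day precision, ``YYYYMM`` month, ``YYYY`` year; empty
    or invalid input gives the absent date.  No imputation is performed.
    Never raises, regardless of input.
    """
    if raw is None:
        return ABSENT_DATE
    raw = raw.strip()
    if not raw:
        return ABSENT_DATE
    if not raw.isdigit():
        log.warning("non-numeric date field %r treated as absent", raw)
        return ABSENT_DATE
    if len(raw) == 4:
        year = int(raw)
        if year < 1900 or year > 2100:
            return ABSENT_DATE
        return PartialDate(year=year, precision="year")
    if len(raw) == 6:
        year, month = int(raw[:4]), int(raw[4:6])
        if year < 1900 or year > 2100 or not 1 <= month <= 12:
            return ABSENT_DATE
        return PartialDate(year=year, month=month, precision="month")
    if len(raw) == 8:
        year, month, day = int(raw[:4]), int(raw[4:6]), int(raw[6:8])
        if year < 1900 or year > 2100:
            return ABSENT_DATE
        try:
            _dt.date(year, month, day)
        except ValueError:
            return ABSENT_DATE
        return PartialDate(year=year, month=month, day=day, precision="day")
    return ABSENT_DATE


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographicRecord:
    primary_id: str
    case_id: str
    case_version: int
    fda_date: PartialDate
    event_date: PartialDate
    age_value: float | None
    age_unit: str | None
    sex: str | None
    reporter_occupation: str | None
    reporter_country: str | None


@dataclass(frozen=True)
class DrugEntry:
    primary_id: str
    drug_seq: int
    drug_name: str
    active_ingredient: str | None
    role_code: str
    start_date: PartialDate


@dataclass(frozen=True)
class ReactionEntry:
    primary_id: str
    preferred_term: str


@dataclass(frozen=True)
class OutcomeEntry:
    primary_id: str
    outcome_code: str


@dataclass(frozen=True)
class TherapyEntry:
    primary_id: str
    drug_seq: int
    start_date: PartialDate


@dataclass(frozen=True)
class IndicationEntry:
    primary_id: str
    drug_seq: int
    indication_term: str


@dataclass
class CaseReport:
    """One safety report: a demographic record joined with its children."""

    demo: DemographicRecord
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReactionEntry] = field(default_factory=list)
    outcomes: list[OutcomeEntry] = field(default_factory=list)
    therapies: list[TherapyEntry] = field(default_factory=list)
    indications: list[IndicationEntry] = field(default_factory=list)

    @property
    def primary_id(self) -> str:
        return self.demo.primary_id

    @property
    def case_id(self) -> str:
        return self.demo.case_id

    @property
    def case_version(self) -> int:
        return self.demo.case_version


# ---------------------------------------------------------------------------
# Table schemas
# ---------------------------------------------------------------------------

TABLE_COLUMNS: Mapping[str, Sequence[str]] = {
    "demo": ("primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
             "age", "age_cod", "sex", "occp_cod", "reporter_country"),
    "drug": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname",
             "prod_ai", "start_dt"),
    "reac": ("primaryid", "caseid", "pt"),
    "outc": ("primaryid", "caseid", "outc_cod"),
    "ther": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
}

TABLE_FILE_PREFIX = {
    "demo": "DEMO", "drug": "DRUG", "reac": "REAC",
    "outc": "OUTC", "ther": "THER", "indi": "INDI",
}


@dataclass
class TableData:
    """One parsed table: header, verbatim valid rows, typed records, rejects."""

    kind: str
    header: list[str]
    rows: list[list[str]]
    records: list
    n_rejected: int = 0
    rejected_lines: list[int] = field(default_factory=list)


@dataclass
class ParsedQuarter:
    """The six parsed tables of one FAERS-style quarter."""

    tables: dict[str, TableData]
    schema_version: str = SCHEMA_VERSION

    def __getattr__(self, name: str) -> TableData:
        try:
            return self.tables[name]
        except KeyError:
            raise AttributeError(name) from None

    def parse_report(self) -> dict:
        """Machine-readable row/reject counts per table."""
        return {
            "schema_version": self.schema_version,
            "tables": {
                kind: {"rows": len(t.records), "rejected": t.n_rejected}
                for kind, t in self.tables.items()
            },
        }

    def write_parse_report(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.parse_report(), indent=2, sort_keys=True))


def _opt(value: str) -> str | None:
    value = value.strip()
    return value or None


def _code(value: str, allowed: frozenset[str], what: str, primary_id: str) -> str | None:
    value = value.strip().upper()
    if not value:
        return None
    if value not in allowed:
        log.warning("report %s: unknown %s code %r treated as absent", primary_id, what, value)
        return None
    return value


def _typed_record(kind: str, row: Mapping[str, str]):
    """Build the typed record for one row; raise ValueError on invariant breach."""
    pid = row["primaryid"].strip()
    if not pid:
        raise ValueError("empty primaryid")
    if kind == "demo":
        version_raw = row["caseversion"].strip()
        version = int(version_raw) if version_raw else 1
        if version < 1:
            raise ValueError(f"caseversion {version} < 1")
        age_raw = row["age"].strip()
        age_value = float(age_raw) if age_raw else None
        if age_value is not None and age_value < 0:
            raise ValueError(f"negative age {age_value}")
        return DemographicRecord(
            primary_id=pid,
            case_id=row["caseid"].strip() or pid,
            case_version=version,
            fda_date=parse_partial_date(row["fda_dt"]),
            event_date=parse_partial_date(row["event_dt"]),
            age_value=age_value,
            age_unit=_code(row["age_cod"], AGE_UNITS, "age unit", pid),
            sex=_code(row["sex"], SEX_CODES, "sex", pid),
            reporter_occupation=_code(row["occp_cod"], OCCUPATION_CODES, "occupation", pid),
            reporter_country=_opt(row["reporter_country"]),
        )
    if kind == "drug":
        role = row["role_cod"].strip().upper()
        if role not in ROLE_CODES:
            raise ValueError(f"invalid role_cod {role!r}")
        return DrugEntry(
            primary_id=pid,
            drug_seq=int(row["drug_seq"]),
            drug_name=row["drugname"].strip(),
            active_ingredient=_opt(row["prod_ai"]),
            role_code=role,
            start_date=parse_partial_date(row["start_dt"]),
        )
    if kind == "reac":
        pt = row["pt"].strip()
        if not pt:
            raise ValueError("empty preferred term")
        return ReactionEntry(primary_id=pid, preferred_term=pt)
    if kind == "outc":
        code = row["outc_cod"].strip().upper()
        if code not in OUTCOME_CODES:
            raise ValueError(f"invalid outc_cod {code!r}")
        return OutcomeEntry(primary_id=pid, outcome_code=code)
    if kind == "ther":
        return TherapyEntry(
            primary_id=pid,
            drug_seq=int(row["dsg_drug_seq"]),
            start_date=parse_partial_date(row["start_dt"]),
        )
    if kind == "indi":
        term = row["indi_pt"].strip()
        if not term:
            raise ValueError("empty indication term")
        return IndicationEntry(
            primary_id=pid,
            drug_seq=int(row["indi_drug_seq"]),
            indication_term=term,
        )
    raise KeyError(kind)


def parse_table(path: str | Path, kind: str) -> TableData:
    """Parse one dollar-delimited table file.

    Missing mandatory columns raise :class:`SchemaError`; an empty file gives
    an empty table.  Malformed rows (wrong field count, invariant breach) are
    counted and logged, never silently dropped.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        return TableData(kind=kind, header=list(TABLE_COLUMNS[kind]), rows=[], records=[])
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    for col in TABLE_COLUMNS[kind]:
        if col not in header:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    table = TableData(kind=kind, header=header, rows=[], records=[])
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) != len(header):
            log.warning("%s line %d: expected %d fields, got %d — rejected",
                        path.name, lineno, len(header), len(fields))
            table.n_rejected += 1
            table.rejected_lines.append(lineno)
            continue
        row = dict(zip(header, fields))
        try:
            record = _typed_record(kind, row)
        except (ValueError, KeyError) as exc:
            log.warning("%s line %d: %s — rejected", path.name, lineno, exc)
            table.n_rejected += 1
            table.rejected_lines.append(lineno)
            continue
        table.rows.append(fields)
        table.records.append(record)
    return table


def _locate_files(source) -> dict[str, Path]:
    """Map table kind -> file from a directory or an iterable of paths."""
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).iterdir())
    else:
        paths = [Path(p) for p in (source if isinstance(source, Iterable) and
                                   not isinstance(source, (str, Path)) else [source])]
    out: dict[str, Path] = {}
    for kind, prefix in TABLE_FILE_PREFIX.items():
        matches = [p for p in paths
                   if p.name.upper().startswith(prefix) and p.suffix.lower() == ".txt"]
        if matches:
            out[kind] = matches[0]
    return out


def parse_quarter(source, schema_version: str = SCHEMA_VERSION) -> ParsedQuarter:
    """Parse a FAERS-style quarter from a directory or explicit file paths.

    Parameters
    ----------
    source
        A directory containing ``DEMO*.txt`` .. ``INDI*.txt``, or an iterable
        of file paths.
    schema_version
        Must equal :data:`SCHEMA_VERSION`; only one dialect is supported.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {schema_version!r}; "
                          f"expected {SCHEMA_VERSION!r}")
    files = _locate_files(source)
    if "demo" not in files:
        raise FileNotFoundError(f"no DEMO table found in {source}")
    tables: dict[str, TableData] = {}
    for kind in TABLE_COLUMNS:
        if kind in files:
            tables[kind] = parse_table(files[kind], kind)
        else:
            tables[kind] = TableData(kind=kind, header=list(TABLE_COLUMNS[kind]),
                                     rows=[], records=[])
    # primaryid uniqueness within the parsed quarter
    seen: set[str] = set()
    for rec in tables["demo"].records:
        if rec.primary_id in seen:
            log.warning("duplicate primaryid %s within quarter", rec.primary_id)
        seen.add(rec.primary_id)
    return ParsedQuarter(tables=tables, schema_version=schema_version)


def write_quarter(quarter: ParsedQuarter, outdir: str | Path) -> dict[str, Path]:
    """Write the quarter back as dollar-delimited files (valid rows verbatim)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, table in quarter.tables.items():
        path = outdir / f"{TABLE_FILE_PREFIX[kind]}.txt"
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(DELIMITER.join(table.header) + "\n")
            for row in table.rows:
                fh.write(DELIMITER.join(row) + "\n")
        paths[kind] = path
    return paths


# ---------------------------------------------------------------------------
# Report assembly and deduplication
# ---------------------------------------------------------------------------

def assemble_reports(quarter: ParsedQuarter) -> list[CaseReport]:
    """Join child tables onto demographics by primaryid."""
    reports = {d.primary_id: CaseReport(demo=d) for d in quarter.tables["demo"].records}
    attach = (("drug", "drugs"), ("reac", "reactions"), ("outc", "outcomes"),
              ("ther", "therapies"), ("indi", "indications"))
    for kind, attr in attach:
        for rec in quarter.tables[kind].records:
            report = reports.get(rec.primary_id)
            if report is None:
                log.warning("%s row for unknown primaryid %s ignored", kind, rec.primary_id)
                continue
            getattr(report, attr).append(rec)
    return list(reports.values())


def deduplicate(reports: Iterable[CaseReport]) -> list[CaseReport]:
    """Keep one report per case id.

    The survivor is the report with the highest case version; ties are broken
    by the most recent received date, then by the lexicographically largest
    primary id.  Idempotent; the output has exactly one report per distinct
    case id, in first-seen case order.
    """
    best: dict[str, CaseReport] = {}
    order: list[str] = []
    for report in reports:
        key = (report.case_version, report.demo.fda_date.sort_key(), report.primary_id)
        incumbent = best.get(report.case_id)
        if incumbent is None:
            best[report.case_id] = report
            order.append(report.case_id)
        else:
            inc_key = (incumbent.case_version, incumbent.demo.fda_date.sort_key(),
                       incumbent.primary_id)
            if key > inc_key:
                best[report.case_id] = report
    return [best[cid] for cid in order]
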