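"""Case selection and descriptive stratification.

Applies the study's selection rules to deduplicated reports — study window,
COVID-19 context via keyword matching, suspect-drug identification through a
synonym dictionary, and a fixed preferred-term event definition — and builds
descriptive tables (age band, sex, reporter occupation, report quarter,
region, outcome) with half-up percentage formatting.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_io import CaseReport, DrugEntry

log = logging.getLogger(__name__)

COVID_KEYWORDS = ("COVID-19", "2019-Ncov", "SARS-Cov-2")
DEFAULT_WINDOW = ("2020Q2", "2021Q4")
DEFAULT_SUSPECT_ROLES = frozenset({"PS", "SS"})

AGE_BAND_LABELS = ("<18", "18–44", "45–64", "65–74", "75–84", "≥85", "Unknown")
_AGE_EDGES = (18, 45, 65, 75, 85)

OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization-initial or prolonged",
    "DS": "Disability",
    "CA": "Congenital anomaly",
    "RI": "Required intervention to prevent permanent impairment",
    "OT": "Other serious/important medical events",
}
OCCUPATION_LABELS = {"MD": "Physician", "PH": "Pharmacist",
                     "CN": "Consumer", "OT": "Other health-professional"}
SEX_LABELS = {"F": "Female", "M": "Male"}

DIMENSIONS = ("age", "sex", "occupation", "quarter", "region", "outcome")

_AGE_UNIT_TO_YEARS = {"DEC": 10.0, "YR": 1.0, "MON": 1.0 / 12.0,
                      "WK": 1.0 / 52.1775, "DY": 1.0 / 365.25, "HR": 1.0 / 8766.0}


def _load_resource(name: str):
    with resources.files("pvdili.data").joinpath(name).open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Drug dictionary and event definition
# ---------------------------------------------------------------------------

class DrugDictionary:
    """Canonical drug name -> synonym set, matched case-insensitively on
    word boundaries (tolerant of dosage suffixes like ``"KEVZARA 200MG"``)."""

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.synonyms: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for canonical, syns in entries.items():
            normed = frozenset(s.strip().lower() for s in syns if s.strip())
            if not normed:
                raise ValueError(f"drug {canonical!r} has an empty synonym set")
            for s in normed:
                if s in seen:
                    raise ValueError(
                        f"synonym {s!r} shared by {seen[s]!r} and {canonical!r}")
                seen[s] = canonical
            self.synonyms[canonical] = normed
        self._patterns = {
            canonical: re.compile(
                r"\b(?:" + "|".join(re.escape(s) for s in sorted(syns)) + r")\b")
            for canonical, syns in self.synonyms.items()}

    @classmethod
    def default(cls) -> "DrugDictionary":
        return cls(_load_resource("drug_dictionary.json"))

    @classmethod
    def from_file(cls, path: str | Path) -> "DrugDictionary":
        import yaml
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(data)

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.synonyms

    def __iter__(self):
        return iter(self.synonyms)

    def match_name(self, text: str | None) -> str | None:
        if not text:
            return None
        lowered = text.lower()
        for canonical, pattern in self._patterns.items():
            if pattern.search(lowered):
                return canonical
        return None


class DiliDefinition:
    """An exact-match (case-insensitive) preferred-term set defining the
    event of interest.  Matching is on whole normalized PT strings, never
    substrings."""

    def __init__(self, terms: Iterable[str]):
        self.terms = tuple(dict.fromkeys(t.strip() for t in terms if t.strip()))
        if not self.terms:
            raise ValueError("event definition must contain at least one term")
        self._normalized = frozenset(t.lower() for t in self.terms)

    @classmethod
    def default(cls) -> "DiliDefinition":
        return cls(_load_resource("dili_terms.json"))

    @classmethod
    def from_file(cls, path: str | Path) -> "DiliDefinition":
        import yaml
        return cls(yaml.safe_load(Path(path).read_text()))

    def __len__(self) -> int:
        return len(self.terms)

    def matches(self, preferred_term: str) -> bool:
        return preferred_term.strip().lower() in self._normalized


# ---------------------------------------------------------------------------
# Matching operations
# ---------------------------------------------------------------------------

def match_drug(drug_entries: Iterable[DrugEntry], dictionary: DrugDictionary,
               roles: frozenset[str] = DEFAULT_SUSPECT_ROLES) -> tuple[str, ...]:
    """Canonical names of dictionary drugs present with a qualifying role.

    Both the verbatim drug name and the active-ingredient string are
    searched.  Returns a sorted tuple — empty when no drug matches, possibly
    more than one when several dictionary drugs appear on the report.
    """
    found: set[str] = set()
    for entry in drug_entries:
        if entry.role_code not in roles:
            continue
        for text in (entry.drug_name, entry.active_ingredient):
            canonical = dictionary.match_name(text)
            if canonical:
                found.add(canonical)
    return tuple(sorted(found))


def _normalize_covid(text: str) -> str:
    return re.sub(r"[\s\-]+", "", text.lower())


def is_covid_case(report: CaseReport,
                  keywords: Sequence[str] = COVID_KEYWORDS) -> bool:
    """True iff any indication term or reaction PT contains a keyword,
    case-insensitive and hyphen/space-insensitive."""
    normed = [_normalize_covid(k) for k in keywords]
    texts = [i.indication_term for i in report.indications]
    texts += [r.preferred_term for r in report.reactions]
    for text in texts:
        ntext = _normalize_covid(text)
        if any(k in ntext for k in normed):
            return True
    return False


def has_dili_event(report: CaseReport, definition: DiliDefinition) -> bool:
    return any(definition.matches(r.preferred_term) for r in report.reactions)


def age_in_years(age_value: float | None, age_unit: str | None) -> float | None:
    """Convert an (age value, unit code) pair to years; None when absent or
    the unit is unknown (logged)."""
    if age_value is None:
        return None
    if age_unit is None:
        return None
    factor = _AGE_UNIT_TO_YEARS.get(age_unit)
    if factor is None:
        log.warning("unknown age unit %r treated as absent", age_unit)
        return None
    return age_value * factor


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def parse_quarter_label(label: str) -> tuple[int, int]:
    m = re.fullmatch(r"(\d{4})Q([1-4])", label.strip())
    if not m:
        raise ValueError(f"bad quarter label {label!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass
class CohortRecord:
    """One annotated report inside the study universe."""

    report: CaseReport
    exposed_drugs: tuple[str, ...]
    has_dili: bool
    is_covid: bool
    quarter: str | None
    age_years: float | None

    @property
    def primary_id(self) -> str:
        return self.report.primary_id


@dataclass
class StudyCohort:
    """COVID-context reports in the study window, annotated for analysis.

    ``records`` is the analysis universe (in-window, COVID context);
    ``background`` additionally keeps the in-window non-COVID reports so a
    whole-database comparator can be requested.
    """

    records: list[CohortRecord]
    background: list[CohortRecord]
    dictionary: DrugDictionary
    definition: DiliDefinition
    window: tuple[str, str]
    selection_flow: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def cases(self, drug: str) -> list[CohortRecord]:
        """The drug's event cases: exposed to ``drug`` and showing the event."""
        if drug not in self.dictionary:
            raise KeyError(f"drug {drug!r} not in dictionary")
        return [r for r in self.records if drug in r.exposed_drugs and r.has_dili]


def build_cohort(reports: Iterable[CaseReport],
                 dictionary: DrugDictionary | None = None,
                 definition: DiliDefinition | None = None,
                 window: tuple[str, str] = DEFAULT_WINDOW,
                 keywords: Sequence[str] = COVID_KEYWORDS,
                 roles: frozenset[str] = DEFAULT_SUSPECT_ROLES) -> StudyCohort:
    """Filter deduplicated reports to the study window and COVID context and
    annotate drug exposure and event status.

    A selection-flow count is recorded at every filter step so the funnel can
    be reported; counts are non-increasing along the chain.
    """
    dictionary = dictionary or DrugDictionary.default()
    definition = definition or DiliDefinition.default()
    lo = parse_quarter_label(window[0])
    hi = parse_quarter_label(window[1])
    if lo > hi:
        raise ValueError(f"window start {window[0]} after end {window[1]}")

    flow: dict[str, int] = {}
    reports = list(reports)
    flow["total_reports"] = len(reports)

    in_window: list[CaseReport] = []
    for report in reports:
        q = report.demo.fda_date.quarter()
        if q is None:
            continue
        yq = parse_quarter_label(q)
        if lo <= yq <= hi:
            in_window.append(report)
    flow["in_window"] = len(in_window)

    background: list[CohortRecord] = []
    records: list[CohortRecord] = []
    for report in in_window:
        rec = CohortRecord(
            report=report,
            exposed_drugs=match_drug(report.drugs, dictionary, roles),
            has_dili=has_dili_event(report, definition),
            is_covid=is_covid_case(report, keywords),
            quarter=report.demo.fda_date.quarter(),
            age_years=age_in_years(report.demo.age_value, report.demo.age_unit),
        )
        background.append(rec)
        if rec.is_covid:
            records.append(rec)
    flow["covid_context"] = len(records)
    for drug in dictionary:
        exposed = [r for r in records if drug in r.exposed_drugs]
        flow[f"exposed_{drug}"] = len(exposed)
        flow[f"cases_{drug}"] = sum(1 for r in exposed if r.has_dili)
    log.info("selection flow: %s", flow)
    return StudyCohort(records=records, background=background,
                       dictionary=dictionary, definition=definition,
                       window=window, selection_flow=flow)


# ---------------------------------------------------------------------------
# Descriptive tables
# ---------------------------------------------------------------------------

def format_percent(count: int, denominator: int) -> str:
    """``count/denominator`` as a percentage string, half-up to 2 decimals."""
    if denominator == 0:
        return "NA"
    pct = Decimal(count) * 100 / Decimal(denominator)
    return f"{pct.quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


def age_band(years: float | None) -> str:
    if years is None:
        return "Unknown"
    if years < _AGE_EDGES[0]:
        return AGE_BAND_LABELS[0]
    for edge, label in zip(_AGE_EDGES[1:], AGE_BAND_LABELS[1:-1]):
        if years < edge:
            return label
    return AGE_BAND_LABELS[-2]


@dataclass
class DescriptiveTable:
    dimension: str
    rows: list[tuple[str, int, str]]
    denominator: int

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows, columns=["stratum", "count", "percentage"])


def _region_map() -> dict[str, str]:
    return _load_resource("continents.json")


def _quarter_labels(window: tuple[str, str]) -> list[str]:
    (y0, q0), (y1, q1) = parse_quarter_label(window[0]), parse_quarter_label(window[1])
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


def stratify(records: Sequence[CohortRecord], dimension: str,
             window: tuple[str, str] = DEFAULT_WINDOW) -> DescriptiveTable:
    """Count records per stratum of one dimension with formatted percentages.

    All dimensions except ``outcome`` partition the record set, so counts sum
    to ``len(records)``.  A report may carry several outcome codes, so the
    outcome dimension is not a partition; its percentage denominator is the
    number of records with at least one outcome code.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")

    counts: dict[str, int] = {}

    def bump(label: str) -> None:
        counts[label] = counts.get(label, 0) + 1

    if dimension == "age":
        labels = list(AGE_BAND_LABELS)
        for rec in records:
            bump(age_band(rec.age_years))
    elif dimension == "sex":
        labels = ["Female", "Male", "Unknown"]
        for rec in records:
            bump(SEX_LABELS.get(rec.report.demo.sex or "", "Unknown"))
    elif dimension == "occupation":
        labels = ["Consumer", "Pharmacist", "Physician",
                  "Other health-professional", "Unknown"]
        for rec in records:
            bump(OCCUPATION_LABELS.get(rec.report.demo.reporter_occupation or "",
                                       "Unknown"))
    elif dimension == "quarter":
        labels = _quarter_labels(window)
        for rec in records:
            bump(rec.quarter if rec.quarter in labels else "Other")
        if "Other" in counts:
            labels.append("Other")
    elif dimension == "region":
        region_of = _region_map()
        labels = ["Africa", "Asian", "Europe", "North America",
                  "South America", "Oceania", "Unknown"]
        for rec in records:
            country = (rec.report.demo.reporter_country or "").upper()
            bump(region_of.get(country, "Unknown"))
    else:  # outcome
        labels = [OUTCOME_LABELS[c] for c in
                  ("CA", "DE", "DS", "HO", "LT", "OT", "RI")]
        denominator = 0
        for rec in records:
            codes = {o.outcome_code for o in rec.report.outcomes}
            if codes:
                denominator += 1
            for code in codes:
                bump(OUTCOME_LABELS[code])
        rows = [(label, counts.get(label, 0),
                 format_percent(counts.get(label, 0), denominator))
                for label in labels]
        return DescriptiveTable(dimension=dimension, rows=rows,
                                denominator=denominator)

    denominator = len(records)
    rows = [(label, counts.get(label, 0),
             format_percent(counts.get(label, 0), denominator))
            for label in labels]
    return DescriptiveTable(dimension=dimension, rows=rows, denominator=denominator)
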