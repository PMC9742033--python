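"""FAERS-like synthetic data with planted statistical structure.

Generates the six quarterly ASCII tables that :mod:`pvdili.faers_io` reads,
with configurable true reporting odds ratios between drugs and event sets,
duplicate case versions, missing demographics and partial dates — plus a
ground-truth sidecar so downstream stages can be tested without any download.

Generative law (per report, all draws independent across reports):

* each configured drug is taken with its marginal probability;
* for a planted ``(drug, event set, theta)`` association the event set occurs
  with probability ``q1`` when the drug is taken and ``q0`` otherwise, where
  ``q0`` is the configured event-set probability and
  ``odds(q1) = theta * odds(q0)``;
* unplanted events occur independently at their configured probabilities.

Under this law the expected 2x2 cells for a pair have the closed form
implemented by :func:`expected_contingency`, and a report falls into the four
cells with multinomial probabilities — :func:`sample_contingency` exploits
this for fast replicate studies.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .faers_io import (DELIMITER, TABLE_COLUMNS, TABLE_FILE_PREFIX, PartialDate,
                       parse_partial_date)

COVID_INDICATION_TERMS = ("COVID-19", "2019-Ncov", "SARS-Cov-2")

#: Non-study reactions used as background noise / fillers.
FILLER_PTS = ("PYREXIA", "HEADACHE", "NAUSEA", "DYSPNOEA", "FATIGUE")
FILLER_DRUG = "PARACETAMOL"

_COUNTRIES = ("US", "US", "US", "CA", "FR", "DE", "IT", "GB", "ES", "JP",
              "CN", "IN", "BR", "AR", "ZA", "EG", "AU", "MX", "RU", "TR")
_OUTCOME_ORDER = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class DrugSpec:
    name: str
    synonyms: tuple[str, ...]
    prob: float


@dataclass(frozen=True)
class EventSpec:
    term: str
    prob: float


@dataclass(frozen=True)
class PlantedAssociation:
    drug: str
    events: tuple[str, ...]
    theta: float


@dataclass
class GeneratorConfig:
    n_reports: int
    drugs: list[DrugSpec]
    events: list[EventSpec]
    planted_associations: list[PlantedAssociation] = field(default_factory=list)
    covid_fraction: float = 1.0
    duplicate_rate: float = 0.0
    missing_age_rate: float = 0.2
    missing_sex_rate: float = 0.2
    date_window: tuple[str, str] = ("20200401", "20211231")
    partial_date_rate: float = 0.0
    outcome_profile: dict[str, float] = field(default_factory=lambda: {
        "DE": 0.1, "LT": 0.05, "HO": 0.2, "DS": 0.02, "CA": 0.01,
        "RI": 0.02, "OT": 0.6})
    onset_law: tuple[str, dict] = ("geometric", {"p": 0.25})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        for name in ("covid_fraction", "duplicate_rate", "missing_age_rate",
                     "missing_sex_rate", "partial_date_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for d in self.drugs:
            if not 0.0 <= d.prob <= 1.0:
                raise ConfigError(f"drugs[{d.name}].prob must be in [0, 1]")
        for e in self.events:
            if not 0.0 <= e.prob <= 1.0:
                raise ConfigError(f"events[{e.term}].prob must be in [0, 1]")
        drug_names = {d.name for d in self.drugs}
        event_terms = {e.term for e in self.events}
        claimed: dict[str, str] = {}
        for assoc in self.planted_associations:
            if assoc.theta <= 0:
                raise ConfigError("planted_associations.theta must be > 0")
            if assoc.drug not in drug_names:
                raise ConfigError(f"planted_associations references unknown drug {assoc.drug!r}")
            for term in assoc.events:
                if term not in event_terms:
                    raise ConfigError(
                        f"planted_associations references unknown event {term!r}")
                if term in claimed and claimed[term] != assoc.drug:
                    raise ConfigError(
                        f"planted_associations: event {term!r} planted for both "
                        f"{claimed[term]!r} and {assoc.drug!r}; sets must be disjoint")
                claimed[term] = assoc.drug
        total = sum(self.outcome_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"outcome_profile must sum to 1 (got {total})")
        if set(self.outcome_profile) - set(_OUTCOME_ORDER):
            raise ConfigError("outcome_profile has unknown outcome codes")
        start, end = (parse_partial_date(d) for d in self.date_window)
        if start.is_absent or end.is_absent or start.sort_key() > end.sort_key():
            raise ConfigError("date_window must be two ordered YYYYMMDD dates")
        name, params = self.onset_law
        if name != "geometric":
            raise ConfigError(f"onset_law {name!r} not supported")
        if not 0.0 < params.get("p", 0) <= 1.0:
            raise ConfigError("onset_law geometric p must be in (0, 1]")

    @classmethod
    def from_mapping(cls, raw: dict) -> "GeneratorConfig":
        raw = dict(raw)
        raw["drugs"] = [DrugSpec(d["name"], tuple(d["synonyms"]), d["prob"])
                        for d in raw.get("drugs", [])]
        raw["events"] = [EventSpec(e["term"], e["prob"]) for e in raw.get("events", [])]
        raw["planted_associations"] = [
            PlantedAssociation(a["drug"], tuple(a["events"]), a["theta"])
            for a in raw.get("planted_associations", [])]
        if "date_window" in raw:
            raw["date_window"] = tuple(raw["date_window"])
        if "onset_law" in raw:
            name, params = raw["onset_law"]
            raw["onset_law"] = (name, dict(params))
        return cls(**raw)


def default_config(n_reports: int = 5000, seed: int = 0,
                   theta_tocilizumab: float = 1.3,
                   theta_sarilumab: float = 8.0,
                   **overrides) -> GeneratorConfig:
    """A study-shaped configuration: two IL-6 antagonists, a liver-injury
    event set with a strong planted signal for one drug and a weak one for
    the other, plus an unassociated null drug."""
    kwargs = dict(
        n_reports=n_reports,
        seed=seed,
        drugs=[
            DrugSpec("tocilizumab", ("TOCILIZUMAB", "ACTEMRA", "ROACTEMRA"), 0.12),
            DrugSpec("sarilumab", ("SARILUMAB", "KEVZARA"), 0.08),
            DrugSpec("remdesivir", ("REMDESIVIR", "VEKLURY"), 0.15),
        ],
        events=[
            EventSpec("HEPATOTOXICITY", 0.03),
            EventSpec("LIVER INJURY", 0.03),
            EventSpec("CHOLESTASIS", 0.02),
            EventSpec("HEPATIC FAILURE", 0.02),
            EventSpec("RASH", 0.10),
        ],
        planted_associations=[
            PlantedAssociation("tocilizumab",
                               ("HEPATOTOXICITY", "LIVER INJURY"),
                               theta_tocilizumab),
            PlantedAssociation("sarilumab",
                               ("CHOLESTASIS", "HEPATIC FAILURE"),
                               theta_sarilumab),
        ],
        covid_fraction=1.0,
        duplicate_rate=0.05,
        partial_date_rate=0.05,
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------

def _set_q0(config: GeneratorConfig, events: Sequence[str]) -> float:
    """Baseline probability that any event in the set occurs (unexposed)."""
    probs = {e.term: e.prob for e in config.events}
    missing = [t for t in events if t not in probs]
    if missing:
        raise KeyError(f"unknown events {missing}")
    q0 = 1.0
    for term in events:
        q0 *= 1.0 - probs[term]
    return 1.0 - q0


def odds_shift(q0: float, theta: float) -> float:
    """The probability whose odds are ``theta`` times the odds of ``q0``."""
    if q0 in (0.0, 1.0):
        return q0
    o = theta * q0 / (1.0 - q0)
    return o / (1.0 + o)


def _pair_probs(config: GeneratorConfig, drug: str, events: Sequence[str]
                ) -> tuple[float, float, float]:
    """(p_drug, q1, q0) for a (drug, event set) pair under the config."""
    try:
        p_drug = next(d.prob for d in config.drugs if d.name == drug)
    except StopIteration:
        raise KeyError(f"unknown drug {drug!r}") from None
    q0 = _set_q0(config, events)
    theta = 1.0
    for assoc in config.planted_associations:
        if assoc.drug == drug and set(assoc.events) == set(events):
            theta = assoc.theta
            break
    return p_drug, odds_shift(q0, theta), q0


def expected_contingency(config: GeneratorConfig, drug: str,
                         events: Sequence[str]) -> tuple[float, float, float, float]:
    """Expected (a, b, c, d) counts for a pair; sums to ``n_reports``."""
    n = config.n_reports
    p, q1, q0 = _pair_probs(config, drug, events)
    return (n * p * q1, n * p * (1.0 - q1),
            n * (1.0 - p) * q0, n * (1.0 - p) * (1.0 - q0))


def solve_baseline_for_marginal(theta: float, p_drug: float,
                                marginal: float) -> tuple[float, float]:
    """Find (q0, q1) with odds(q1) = theta*odds(q0) and the requested
    marginal event probability ``p_drug*q1 + (1-p_drug)*q0``."""
    if not 0.0 < marginal < 1.0:
        raise ValueError("marginal must be in (0, 1)")

    def f(q0: float) -> float:
        return p_drug * odds_shift(q0, theta) + (1.0 - p_drug) * q0 - marginal

    return (q0 := brentq(f, 1e-12, 1.0 - 1e-12)), odds_shift(q0, theta)


def sample_contingency(config: GeneratorConfig, drug: str, events: Sequence[str],
                       rng: np.random.Generator) -> tuple[int, int, int, int]:
    """Draw (a, b, c, d) directly from the per-report multinomial cell law.

    Exact shortcut of running :func:`generate` and counting — the per-report
    cell membership is iid multinomial with the expected-cell probabilities.
    """
    expected = np.asarray(expected_contingency(config, drug, events))
    counts = rng.multinomial(config.n_reports, expected / config.n_reports)
    return tuple(int(x) for x in counts)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    n_reports: int
    distinct_case_count: int
    expected_cells: dict[str, tuple[float, float, float, float]]
    onset_days: dict[str, int]
    covid_case_count: int

    @staticmethod
    def pair_key(drug: str, events: Sequence[str]) -> str:
        return drug + "|" + ",".join(sorted(events))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reports": self.n_reports,
            "distinct_case_count": self.distinct_case_count,
            "expected_cells": {k: list(v) for k, v in self.expected_cells.items()},
            "onset_days": self.onset_days,
            "covid_case_count": self.covid_case_count,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["expected_cells"] = {
            k: tuple(v) for k, v in payload["expected_cells"].items()}
        return cls(**payload)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_onset(config: GeneratorConfig, rng: np.random.Generator) -> int:
    p = config.onset_law[1]["p"]
    return int(rng.geometric(p) - 1)  # support {0, 1, 2, ...}


def _maybe_truncate(date: PartialDate, config: GeneratorConfig,
                    rng: np.random.Generator) -> PartialDate:
    if date.precision == "day" and rng.random() < config.partial_date_rate:
        if rng.random() < 0.5:
            return PartialDate(year=date.year, month=date.month, precision="month")
        return PartialDate(year=date.year, precision="year")
    return date


def generate(config: GeneratorConfig, outdir: str | Path
             ) -> tuple[dict[str, Path], GroundTruth]:
    """Write a synthetic quarter (six ASCII tables + ``groundtruth.json``).

    Deterministic: identical configs (including seed) give byte-identical
    files.  Returns the file map and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    start = parse_partial_date(config.date_window[0]).to_date()
    end = parse_partial_date(config.date_window[1]).to_date()
    span = (end - start).days

    planted_by_drug = {a.drug: a for a in config.planted_associations}
    planted_terms: set[str] = set()
    for assoc in config.planted_associations:
        planted_terms.update(assoc.events)
    event_probs = {e.term: e.prob for e in config.events}
    outcome_p = np.array([config.outcome_profile.get(c, 0.0) for c in _OUTCOME_ORDER])

    rows: dict[str, list[list[str]]] = {k: [] for k in TABLE_COLUMNS}
    onset_days: dict[str, int] = {}
    covid_cases = 0

    def fmt(date: PartialDate) -> str:
        return date.raw()

    for i in range(config.n_reports):
        case_id = str(100000 + i)
        fda = start + _dt.timedelta(days=int(rng.integers(0, span + 1)))
        fda_date = PartialDate(fda.year, fda.month, fda.day, "day")

        exposures = [d for d in config.drugs if rng.random() < d.prob]
        exposed_names = {d.name for d in exposures}

        # planted event sets: one occurrence draw per association
        # (config validation guarantees the sets are disjoint)
        reactions: list[str] = []
        for assoc in config.planted_associations:
            q0 = _set_q0(config, assoc.events)
            q = odds_shift(q0, assoc.theta) if assoc.drug in exposed_names else q0
            if rng.random() < q:
                reactions.append(assoc.events[int(rng.integers(0, len(assoc.events)))])
        for term, prob in event_probs.items():
            if term in planted_terms:
                continue
            if rng.random() < prob:
                reactions.append(term)
        if not reactions:
            reactions.append(FILLER_PTS[int(rng.integers(0, len(FILLER_PTS)))])

        # demographics
        age = "" if rng.random() < config.missing_age_rate else str(int(rng.integers(18, 91)))
        age_cod = "YR" if age else ""
        sex = "" if rng.random() < config.missing_sex_rate else ("F" if rng.random() < 0.5 else "M")
        occp = ("MD", "PH", "CN", "OT")[int(rng.integers(0, 4))]
        country = _COUNTRIES[int(rng.integers(0, len(_COUNTRIES)))]
        is_covid = rng.random() < config.covid_fraction
        if is_covid:
            covid_cases += 1

        # drug rows: exposures as suspect drugs, plus a concomitant filler
        drug_rows: list[tuple[int, str, str, str, PartialDate]] = []
        therapy_start: PartialDate | None = None
        for seq, spec in enumerate(exposures, start=1):
            syn = spec.synonyms[int(rng.integers(0, len(spec.synonyms)))]
            name = syn if rng.random() < 0.7 else f"{syn} {int(rng.integers(1, 9)) * 100}MG"
            role = "PS" if rng.random() < 0.8 else "SS"
            sdate = fda - _dt.timedelta(days=int(rng.integers(5, 61)))
            pdate = PartialDate(sdate.year, sdate.month, sdate.day, "day")
            drug_rows.append((seq, name, spec.name.upper(), role, pdate))
            if therapy_start is None:
                therapy_start = pdate
        filler_seq = len(drug_rows) + 1
        drug_rows.append((filler_seq, FILLER_DRUG, FILLER_DRUG, "C", PartialDate()))

        # event date: suspect-drug start + onset for exposed reports
        true_onset = _draw_onset(config, rng)
        if therapy_start is not None:
            event = therapy_start.to_date() + _dt.timedelta(days=true_onset)
            event_date = PartialDate(event.year, event.month, event.day, "day")
        else:
            ev = fda - _dt.timedelta(days=int(rng.integers(0, 31)))
            event_date = PartialDate(ev.year, ev.month, ev.day, "day")

        outcome = _OUTCOME_ORDER[int(rng.choice(len(_OUTCOME_ORDER), p=outcome_p))]

        versions = [1]
        if rng.random() < config.duplicate_rate:
            versions.append(2)
        for version in versions:
            pid = f"{case_id}{version}"
            if version == 1:
                vfda = fda_date
            else:
                later = min(fda + _dt.timedelta(days=30), end)  # keep inside window
                vfda = PartialDate(later.year, later.month, later.day, "day")
            ev_out = _maybe_truncate(event_date, config, rng)
            rows["demo"].append([pid, case_id, str(version), fmt(vfda), fmt(ev_out),
                                 age, age_cod, sex, occp, country])
            for seq, name, ai, role, sdate in drug_rows:
                s_out = _maybe_truncate(sdate, config, rng)
                rows["drug"].append([pid, case_id, str(seq), role, name, ai, fmt(s_out)])
                if role in ("PS", "SS") and not s_out.is_absent:
                    rows["ther"].append([pid, case_id, str(seq), fmt(s_out)])
            for pt in reactions:
                rows["reac"].append([pid, case_id, pt])
            rows["outc"].append([pid, case_id, outcome])
            if is_covid:
                term = COVID_INDICATION_TERMS[int(rng.integers(0, len(COVID_INDICATION_TERMS)))]
                rows["indi"].append([pid, case_id, str(filler_seq), term])
            if version == 1 and therapy_start is not None:
                onset_days[case_id] = true_onset  # keyed by case id: survives dedup

    paths: dict[str, Path] = {}
    for kind, cols in TABLE_COLUMNS.items():
        path = outdir / f"{TABLE_FILE_PREFIX[kind]}.txt"
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(DELIMITER.join(cols) + "\n")
            for r in rows[kind]:
                fh.write(DELIMITER.join(r) + "\n")
        paths[kind] = path

    expected_cells = {}
    for assoc in config.planted_associations:
        key = GroundTruth.pair_key(assoc.drug, assoc.events)
        expected_cells[key] = expected_contingency(config, assoc.drug, assoc.events)
    truth = GroundTruth(
        n_reports=config.n_reports,
        distinct_case_count=config.n_reports,
        expected_cells=expected_cells,
        onset_days=onset_days,
        covid_case_count=covid_cases,
    )
    truth.to_json(outdir / "groundtruth.json")
    paths["groundtruth"] = outdir / "groundtruth.json"
    return paths, truth
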