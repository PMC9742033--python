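"""Time-to-onset, outcome profiles and between-group comparisons.

Onset is the number of days between the earliest suspect-drug start date and
the adverse-event onset date within one report.  Reports are excluded (with
a recorded reason) when either date is absent, coarser than day precision,
or the interval is negative — no partial-date imputation is performed.
Therapy-record start dates are preferred, falling back to the drug entry's
own start date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .cohort import CohortRecord, StudyCohort, format_percent
from .faers_io import PartialDate

log = logging.getLogger(__name__)

EXCLUSION_REASONS = ("missing_event_date", "imprecise_event_date",
                     "missing_start_date", "imprecise_start_date", "negative_interval")


@dataclass(frozen=True)
class OnsetRecord:
    primary_id: str
    drug: str
    interval_days: int


@dataclass
class OnsetSummary:
    n: int
    median: float
    iqr: tuple[float, float]
    range: tuple[int, int]
    histogram: dict[int, int]


@dataclass
class OnsetResult:
    records: list[OnsetRecord]
    exclusions: dict[str, int]

    @property
    def n_candidates(self) -> int:
        return len(self.records) + sum(self.exclusions.values())

    def intervals(self) -> list[int]:
        return [r.interval_days for r in self.records]


def onset_interval(event_date: PartialDate,
                   start_dates: Sequence[PartialDate]) -> tuple[int | None, str | None]:
    """Interval in days between the earliest start date and the event date.

    Returns ``(days, None)`` when computable, ``(None, reason)`` otherwise.
    Both dates must carry day precision; negative intervals are excluded.
    """
    if event_date.is_absent:
        return None, "missing_event_date"
    if event_date.precision != "day":
        return None, "imprecise_event_date"
    usable = [d for d in start_dates if not d.is_absent]
    if not usable:
        return None, "missing_start_date"
    day_precision = [d for d in usable if d.precision == "day"]
    if not day_precision:
        return None, "imprecise_start_date"
    earliest = min(day_precision, key=PartialDate.sort_key)
    days = (event_date.to_date() - earliest.to_date()).days
    if days < 0:
        return None, "negative_interval"
    return days, None


def collect_onsets(cohort: StudyCohort, drug: str,
                   prefer_therapy: bool = True) -> OnsetResult:
    """Onset records for the drug's event cases, with exclusion accounting.

    Start dates come from therapy records for the matching suspect drug
    sequences when available, otherwise from the drug entries themselves.
    ``n_included + sum(n_excluded by reason)`` always equals the number of
    candidate case reports.
    """
    records: list[OnsetRecord] = []
    exclusions = {reason: 0 for reason in EXCLUSION_REASONS}
    for rec in cohort.cases(drug):
        report = rec.report
        suspect_seqs = {
            e.drug_seq for e in report.drugs
            if e.role_code in ("PS", "SS")
            and (cohort.dictionary.match_name(e.drug_name) == drug
                 or cohort.dictionary.match_name(e.active_ingredient) == drug)}
        starts: list[PartialDate] = []
        if prefer_therapy:
            starts = [t.start_date for t in report.therapies
                      if t.drug_seq in suspect_seqs and not t.start_date.is_absent]
        if not starts:
            starts = [e.start_date for e in report.drugs
                      if e.drug_seq in suspect_seqs and not e.start_date.is_absent]
        days, reason = onset_interval(report.demo.event_date, starts)
        if reason is not None:
            exclusions[reason] += 1
        else:
            records.append(OnsetRecord(primary_id=report.primary_id, drug=drug,
                                       interval_days=days))
    log.info("onset %s: %d included, exclusions %s", drug, len(records),
             {k: v for k, v in exclusions.items() if v})
    return OnsetResult(records=records, exclusions=exclusions)


def summarize_onset(records: Iterable[OnsetRecord] | Sequence[int]) -> OnsetSummary:
    """Median (midpoint convention for even n), IQR, min–max range and a
    per-day histogram."""
    values = [r.interval_days if isinstance(r, OnsetRecord) else int(r)
              for r in records]
    if not values:
        raise ValueError("cannot summarize an empty onset collection")
    arr = np.asarray(values)
    q1, q3 = np.percentile(arr, [25, 75])
    hist: dict[int, int] = {}
    for v in sorted(values):
        hist[v] = hist.get(v, 0) + 1
    return OnsetSummary(
        n=len(values),
        median=float(np.median(arr)),
        iqr=(float(q1), float(q3)),
        range=(int(arr.min()), int(arr.max())),
        histogram=hist,
    )


def cumulative_share(records: Iterable[OnsetRecord] | Sequence[int],
                     horizon_days: int) -> float:
    """Share of onsets occurring within ``horizon_days`` (inclusive)."""
    values = [r.interval_days if isinstance(r, OnsetRecord) else int(r)
              for r in records]
    if not values:
        raise ValueError("cannot compute a share of an empty collection")
    return sum(1 for v in values if v <= horizon_days) / len(values)


def compare_onset(group_a: Sequence[float], group_b: Sequence[float],
                  welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise ValueError("degenerate variance: both groups are constant")
    t, p = _sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) against the chi-squared reference."""
    if len(groups) < 3:
        raise ValueError("Kruskal–Wallis here requires at least 3 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least 1 observation")
    flat = {float(v) for g in groups for v in g}
    if len(flat) == 1:
        return 0.0, 1.0
    h, p = _sps.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

@dataclass
class OutcomeProfile:
    drug: str
    counts: dict[str, int]
    denominator: int
    denominator_rule: str
    proportions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        denom = self.denominator
        self.proportions = {code: (count / denom if denom else 0.0)
                            for code, count in self.counts.items()}
        if denom == 0:
            log.warning("outcome profile for %s has a zero denominator", self.drug)

    @property
    def fatality_rate(self) -> float:
        return self.proportions.get("DE", 0.0)

    def formatted(self) -> dict[str, str]:
        return {code: format_percent(count, self.denominator)
                for code, count in self.counts.items()}


def outcome_profile(cohort: StudyCohort, drug: str,
                    denominator_rule: str = "outcome_reports") -> OutcomeProfile:
    """Outcome-code counts and proportions for the drug's event cases.

    ``denominator_rule`` is ``"outcome_reports"`` (reports carrying at least
    one outcome code — outcome codes are not mutually exclusive, so this is
    the not-a-partition denominator) or ``"cases"`` (all event cases).
    """
    cases = cohort.cases(drug)
    counts = {code: 0 for code in ("DE", "LT", "HO", "DS", "CA", "RI", "OT")}
    with_outcome = 0
    for rec in cases:
        codes = {o.outcome_code for o in rec.report.outcomes}
        if codes:
            with_outcome += 1
        for code in codes:
            counts[code] += 1
    if denominator_rule == "outcome_reports":
        denominator = with_outcome
    elif denominator_rule == "cases":
        denominator = len(cases)
    else:
        raise ValueError(f"unknown denominator rule {denominator_rule!r}")
    return OutcomeProfile(drug=drug, counts=counts, denominator=denominator,
                          denominator_rule=denominator_rule)


def compare_proportions(events_a: int, total_a: int, events_b: int, total_b: int,
                        method: str = "chi2") -> tuple[float, float]:
    """Compare two proportions on the implied 2x2 table.

    ``method``: ``"chi2"`` (Pearson, no continuity correction — the default),
    ``"yates"`` (continuity-corrected chi-squared) or ``"fisher"`` (exact;
    the first return value is then the odds ratio, not a chi-squared).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if events_a > total_a or events_b > total_b:
        raise ValueError("events cannot exceed totals")
    a, b = events_a, total_a - events_a
    c, d = events_b, total_b - events_b
    if method == "fisher":
        odds, p = _sps.fisher_exact([[a, b], [c, d]])
        return float(odds), float(p)
    n = a + b + c + d
    dev = abs(a * d - b * c)
    if method == "yates":
        dev = max(dev - n / 2.0, 0.0)
    elif method != "chi2":
        raise ValueError(f"unknown method {method!r}")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0 or dev == 0:
        return 0.0, 1.0
    chi2 = n * dev * dev / denom
    return float(chi2), float(_sps.chi2.sf(chi2, df=1))
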