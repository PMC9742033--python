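"""2x2 contingency tables and disproportionality statistics.

Implements the reporting odds ratio (ROR) with a 95% Wald interval, the
proportional reporting ratio (PRR) with an uncorrected Pearson chi-squared,
the information component (IC, bits) and the relative reporting ratio here
called EBGM, together with their lower bounds and the usual signal criteria:

* ROR: lower 95% bound > 1 and a >= 2
* PRR: PRR >= 2, chi2 >= 4 and a >= 3
* IC:  IC025 > 0
* EBGM: EBGM05 > 2 and a > 0

IC and EBGM share the core expression ``a*N / ((a+b)(a+c))`` — IC is its
log2, so ``ic == log2(ebgm)`` identically.  The default IC025/EBGM05 bounds
are *multiplicative* on the point estimate, ``exp(ln(x) - z*s)`` with
``s = sqrt(1/a + 1/b + 1/c + 1/d)`` (z = 1.96 two-sided for IC, 1.64
one-sided for EBGM).  This is not the conventional BCPNN credible bound nor
an MGPS posterior — no empirical-Bayes shrinkage is applied; a delta-method
additive IC bound is available via ``method="additive"`` and is labelled as
such in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

log = __import__("logging").getLogger(__name__)

Z_TWO_SIDED_95 = 1.96
Z_ONE_SIDED_95 = 1.64
LN2 = math.log(2.0)

ZeroCellPolicy = Literal["strict", "haldane"]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this table under the strict zero-cell policy."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of deduplicated reports: a = drug & event, b = drug only,
    c = event only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self, policy: ZeroCellPolicy = "strict") -> tuple[float, float, float, float]:
        """The four cells under the zero-cell policy.

        ``strict`` raises when any cell is zero; ``haldane`` applies the
        Haldane–Anscombe correction (adds 0.5 to every cell).
        """
        cells = (self.a, self.b, self.c, self.d)
        if self.n < 1:
            raise UndefinedStatisticError("statistics undefined on an empty table")
        if 0 in cells:
            if policy == "strict":
                raise UndefinedStatisticError(
                    f"zero cell in table {cells}; use the haldane policy or a larger universe")
            return tuple(x + 0.5 for x in cells)
        return tuple(float(x) for x in cells)


def log_se(a: float, b: float, c: float, d: float) -> float:
    """s = sqrt(1/a + 1/b + 1/c + 1/d)."""
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def derive_log_se(point: float, lower: float, z: float = Z_TWO_SIDED_95) -> float:
    """Back out s from a point estimate and the lower limit of its Wald CI."""
    if point <= 0 or lower <= 0:
        raise ValueError("point and lower bound must be positive")
    return (math.log(point) - math.log(lower)) / z


def ror_with_ci(t: ContingencyTable, policy: ZeroCellPolicy = "strict"
                ) -> tuple[float, float, float, float]:
    """ROR = (a·d)/(b·c) with its two-sided 95% Wald interval.

    Returns (ror, ci_low, ci_high, s) where s = sqrt(1/a+1/b+1/c+1/d).
    """
    a, b, c, d = t.cells(policy)
    ror = (a * d) / (b * c)
    s = log_se(a, b, c, d)
    low = math.exp(math.log(ror) - Z_TWO_SIDED_95 * s)
    high = math.exp(math.log(ror) + Z_TWO_SIDED_95 * s)
    return ror, low, high, s


def prr_with_chi2(t: ContingencyTable, policy: ZeroCellPolicy = "strict",
                  yates: bool = False) -> tuple[float, float]:
    """PRR = (a/(a+b)) / (c/(c+d)) and the Pearson chi-squared statistic.

    No continuity correction by default; ``yates=True`` applies Yates'
    correction to the chi-squared only.
    """
    a, b, c, d = t.cells(policy)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2.0, 0.0)
    chi2 = n * dev * dev / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def relative_reporting_ratio(t: ContingencyTable,
                             policy: ZeroCellPolicy = "strict") -> float:
    """The shared IC/EBGM core: a·N / ((a+b)(a+c))."""
    a, b, c, d = t.cells(policy)
    n = a + b + c + d
    return a * n / ((a + b) * (a + c))


def ic_bound_from_point(ic: float, s: float, z: float = Z_TWO_SIDED_95) -> float:
    """Multiplicative lower bound exp(ln(IC) − z·s); NaN when IC <= 0."""
    if ic <= 0:
        log.warning("IC = %g <= 0: multiplicative IC025 undefined", ic)
        return math.nan
    return math.exp(math.log(ic) - z * s)


def ebgm_bound_from_point(ebgm: float, s: float, z: float = Z_ONE_SIDED_95) -> float:
    """Lower one-sided bound exp(ln(EBGM) − z·s)."""
    return math.exp(math.log(ebgm) - z * s)


def ic_with_bound(t: ContingencyTable, policy: ZeroCellPolicy = "strict",
                  method: Literal["ratio", "additive"] = "ratio"
                  ) -> tuple[float, float]:
    """IC = log2(a·N/((a+b)(a+c))) and its lower 95% bound.

    ``method="ratio"`` (default) is the multiplicative bound on the IC point
    value; ``"additive"`` is the delta-method bound IC − 1.96·s/ln 2.
    """
    a, b, c, d = t.cells(policy)
    s = log_se(a, b, c, d)
    ic = math.log2(a * (a + b + c + d) / ((a + b) * (a + c)))
    if method == "additive":
        return ic, ic - Z_TWO_SIDED_95 * s / LN2
    return ic, ic_bound_from_point(ic, s)


def ebgm_with_bound(t: ContingencyTable, policy: ZeroCellPolicy = "strict"
                    ) -> tuple[float, float]:
    """EBGM = a·N/((a+b)(a+c)) (unshrunk) and EBGM05 = exp(ln EBGM − 1.64·s)."""
    a, b, c, d = t.cells(policy)
    s = log_se(a, b, c, d)
    ebgm = a * (a + b + c + d) / ((a + b) * (a + c))
    return ebgm, ebgm_bound_from_point(ebgm, s)


@dataclass(frozen=True)
class SignalStatistics:
    table: ContingencyTable
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    se_log: float
    n_events: int

    @property
    def flags(self) -> dict[str, bool]:
        return signal_flags(self)

    def to_dict(self) -> dict:
        t = self.table
        out = {"a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.n,
               "ror": self.ror, "ror_low": self.ror_low, "ror_high": self.ror_high,
               "prr": self.prr, "chi2": self.chi2, "ic": self.ic,
               "ic025": self.ic025, "ebgm": self.ebgm, "ebgm05": self.ebgm05,
               "se_log": self.se_log, "n_events": self.n_events}
        out.update(self.flags)
        return out


def signal_flags(stats: SignalStatistics) -> dict[str, bool]:
    """Per-criterion signal booleans (see module docstring)."""
    a = stats.n_events
    return {
        "ror_signal": bool(stats.ror_low > 1.0 and a >= 2),
        "prr_signal": bool(stats.prr >= 2.0 and stats.chi2 >= 4.0 and a >= 3),
        "ic_signal": bool(not math.isnan(stats.ic025) and stats.ic025 > 0.0),
        "ebgm_signal": bool(stats.ebgm05 > 2.0 and a > 0),
    }


def compute_signal_statistics(t: ContingencyTable,
                              policy: ZeroCellPolicy = "strict",
                              ic_method: Literal["ratio", "additive"] = "ratio",
                              yates: bool = False) -> SignalStatistics:
    """All four statistics with bounds for one table."""
    ror, low, high, s = ror_with_ci(t, policy)
    prr, chi2 = prr_with_chi2(t, policy, yates=yates)
    ic, ic025 = ic_with_bound(t, policy, method=ic_method)
    ebgm, ebgm05 = ebgm_with_bound(t, policy)
    return SignalStatistics(table=t, ror=ror, ror_low=low, ror_high=high,
                            prr=prr, chi2=chi2, ic=ic, ic025=ic025,
                            ebgm=ebgm, ebgm05=ebgm05, se_log=s, n_events=t.a)


# ---------------------------------------------------------------------------
# From cohorts
# ---------------------------------------------------------------------------

def build_contingency(cohort, drug: str, definition=None,
                      universe: Literal["covid_cohort", "full_database"] = "covid_cohort"
                      ) -> ContingencyTable:
    """Count the 2x2 table for (drug, event definition) over a comparator
    universe of deduplicated reports (each report lands in exactly one cell).

    ``covid_cohort`` compares within the COVID-context study universe;
    ``full_database`` uses every in-window report the cohort retained.
    """
    if drug not in cohort.dictionary:
        raise KeyError(f"drug {drug!r} not in dictionary")
    records = cohort.records if universe == "covid_cohort" else cohort.background
    if definition is None:
        flags = [(drug in r.exposed_drugs, r.has_dili) for r in records]
    else:
        from .cohort import has_dili_event
        flags = [(drug in r.exposed_drugs, has_dili_event(r.report, definition))
                 for r in records]
    a = sum(1 for e, v in flags if e and v)
    b = sum(1 for e, v in flags if e and not v)
    c = sum(1 for e, v in flags if not e and v)
    d = sum(1 for e, v in flags if not e and not v)
    return ContingencyTable(a, b, c, d)


def signal_table(cohort, drugs: Sequence[str] | None = None,
                 policy: ZeroCellPolicy = "strict",
                 universe: Literal["covid_cohort", "full_database"] = "covid_cohort"):
    """One row of counts, statistics, bounds and flags per drug (DataFrame)."""
    import pandas as pd
    drugs = list(drugs) if drugs is not None else list(cohort.dictionary)
    rows = []
    for drug in drugs:
        t = build_contingency(cohort, drug, universe=universe)
        row: dict = {"drug": drug}
        try:
            row.update(compute_signal_statistics(t, policy=policy).to_dict())
        except UndefinedStatisticError as exc:
            row.update({"a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.n,
                        "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows)
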