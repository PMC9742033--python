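import math

import numpy as np
import pytest
from scipy import stats as sps

from pvdili.cohort import build_cohort
from pvdili.faers_io import parse_partial_date
from pvdili.onset_outcomes import (OnsetRecord, collect_onsets, compare_onset,
                                   compare_proportions, cumulative_share,
                                   kruskal_wallis, onset_interval,
                                   outcome_profile, summarize_onset)

from conftest import make_report


def pd_(raw):
    return parse_partial_date(raw)


class TestOnsetInterval:
    def test_one_day(self):
        days, reason = onset_interval(pd_("20200705"), [pd_("20200704")])
        assert (days, reason) == (1, None)

    def test_negative_excluded(self):
        days, reason = onset_interval(pd_("20200701"), [pd_("20200703")])
        assert days is None and reason == "negative_interval"

    def test_month_precision_start_excluded(self):
        days, reason = onset_interval(pd_("20200715"), [pd_("202007")])
        assert days is None and reason == "imprecise_start_date"

    def test_imprecise_event_excluded(self):
        days, reason = onset_interval(pd_("202007"), [pd_("20200701")])
        assert days is None and reason == "imprecise_event_date"

    def test_missing_dates_excluded(self):
        assert onset_interval(pd_(""), [pd_("20200701")])[1] == "missing_event_date"
        assert onset_interval(pd_("20200701"), [])[1] == "missing_start_date"
        assert onset_interval(pd_("20200701"), [pd_("")])[1] == "missing_start_date"

    def test_earliest_start_used(self):
        days, _ = onset_interval(pd_("20200710"),
                                 [pd_("20200708"), pd_("20200701")])
        assert days == 9


class TestCollectOnsets:
    def make_cohort(self):
        reports = [
            # therapy start preferred: 3 days
            make_report("1", fda_dt="20200901", event_dt="20200704",
                        drugs=[("ACTEMRA", "PS", "20200601")],
                        therapy_starts=[(1, "20200701")],
                        reactions=["HEPATOTOXICITY"], indications=["COVID-19"]),
            # fallback to drug start: 2 days
            make_report("2", fda_dt="20200901", event_dt="20200603",
                        drugs=[("ACTEMRA", "PS", "20200601")],
                        reactions=["HEPATOTOXICITY"], indications=["COVID-19"]),
            # negative: excluded
            make_report("3", fda_dt="20200901", event_dt="20200530",
                        drugs=[("ACTEMRA", "PS", "20200601")],
                        reactions=["HEPATOTOXICITY"], indications=["COVID-19"]),
            # no start date anywhere: excluded
            make_report("4", fda_dt="20200901", event_dt="20200603",
                        drugs=[("ACTEMRA", "PS")],
                        reactions=["HEPATOTOXICITY"], indications=["COVID-19"]),
        ]
        return build_cohort(reports)

    def test_intervals_and_accounting(self):
        result = collect_onsets(self.make_cohort(), "tocilizumab")
        assert sorted(r.interval_days for r in result.records) == [2, 3]
        assert result.exclusions["negative_interval"] == 1
        assert result.exclusions["missing_start_date"] == 1
        assert result.n_candidates == 4

    def test_exclusion_accounting_on_synthetic(self, synthetic_quarter):
        from pvdili.faers_io import assemble_reports, deduplicate, parse_quarter
        outdir, _, _ = synthetic_quarter
        cohort = build_cohort(deduplicate(assemble_reports(parse_quarter(outdir))))
        for drug in ("tocilizumab", "sarilumab"):
            result = collect_onsets(cohort, drug)
            assert result.n_candidates == len(cohort.cases(drug))


class TestSummaries:
    def test_odd_n(self):
        s = summarize_onset([0, 1, 2])
        assert s.median == 1 and s.range == (0, 2) and s.n == 3

    def test_even_n_midpoint(self):
        assert summarize_onset([3, 4]).median == 3.5

    def test_histogram_sums_to_n(self):
        s = summarize_onset([0, 0, 1, 5, 5, 5])
        assert sum(s.histogram.values()) == s.n == 6
        assert s.histogram[5] == 3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_onset([])

    def test_geometric_median_matches_law(self):
        # geometric(p = 0.5) on {0,1,...} has its median at 0/1
        rng = np.random.default_rng(0)
        draws = rng.geometric(0.5, size=10_000) - 1
        s = summarize_onset([int(x) for x in draws])
        assert s.median in (0.0, 0.5, 1.0)

    def test_accepts_onset_records(self):
        recs = [OnsetRecord("1", "d", 4), OnsetRecord("2", "d", 6)]
        assert summarize_onset(recs).median == 5.0


class TestCumulativeShare:
    def test_counting(self):
        assert cumulative_share([0, 1, 5, 9], 4) == pytest.approx(0.5)

    def test_saturation(self):
        assert cumulative_share([0, 0, 0], 0) == 1.0
        assert cumulative_share([0, 0, 0], 10) == 1.0

    def test_non_decreasing_and_reaches_one(self):
        values = [0, 2, 2, 7, 11]
        shares = [cumulative_share(values, h) for h in range(12)]
        assert shares == sorted(shares)
        assert shares[-1] == 1.0

    def test_geometric_closed_form(self):
        # share within horizon h is within 3 SE of 1 - (1-p)^(h+1)
        p, h, n = 0.3, 4, 20_000
        rng = np.random.default_rng(1)
        draws = [int(x) for x in rng.geometric(p, size=n) - 1]
        expected = 1 - (1 - p) ** (h + 1)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(cumulative_share(draws, h) - expected) <= 3 * se


class TestCompareOnset:
    def test_identical_groups(self):
        t, p = compare_onset([0, 1, 2], [0, 1, 2])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_oracle(self):
        # A=[0,0,1,1], B=[10,10,11,11]: pooled sp2=1/3, se=sqrt(1/6), t=-10/se
        t, p = compare_onset([0, 0, 1, 1], [10, 10, 11, 11])
        assert t == pytest.approx(-10 / math.sqrt(1 / 6), rel=1e-12)
        assert p < 0.01

    def test_welch_flag(self):
        a, b = [0.0, 1, 2, 3, 9], [5.0, 5.1, 5.2, 4.9]
        t_pooled, _ = compare_onset(a, b)
        t_welch, _ = compare_onset(a, b, welch=True)
        assert t_pooled != t_welch

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            compare_onset([1, 1], [1, 1])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_onset([1], [1, 2])

    def test_type_one_error_rate(self):
        # two samples from the same law: ~5% rejections at alpha = 0.05
        rng = np.random.default_rng(7)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            a = rng.normal(size=25)
            b = rng.normal(size=25)
            _, p = compare_onset(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 1], [1, 1], [1, 1]])
        assert h == 0.0 and p == 1.0

    def test_rank_arithmetic_oracle(self):
        # groups [1,2,3],[4,5,6],[7,8,9]: no ties, rank sums 6/15/24
        # H = 12/(9*10) * (36+225+576)/3 - 3*10 = 7.2
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(11)
        reps = 1000
        rejections = 0
        for _ in range(reps):
            groups = [rng.exponential(size=15) for _ in range(3)]
            _, p = kruskal_wallis(groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestOutcomeProfile:
    def make_cohort(self, n_cases=5, de=2, no_outcome=1):
        reports = []
        for i in range(n_cases):
            if i < no_outcome:
                outcomes = ()
            elif i < no_outcome + de:
                outcomes = ("DE",)
            else:
                outcomes = ("HO", "OT")
            reports.append(make_report(
                str(i), fda_dt="20200901", drugs=[("KEVZARA", "PS")],
                reactions=["HEPATOTOXICITY"], outcomes=outcomes,
                indications=["COVID-19"]))
        return build_cohort(reports)

    def test_denominator_rules(self):
        cohort = self.make_cohort()
        p1 = outcome_profile(cohort, "sarilumab")
        assert p1.denominator == 4  # outcome-bearing reports
        assert p1.counts["DE"] == 2
        assert p1.fatality_rate == pytest.approx(0.5)
        p2 = outcome_profile(cohort, "sarilumab", denominator_rule="cases")
        assert p2.denominator == 5

    def test_printed_fatality_formatting(self):
        # 30 deaths over an 82-report outcome denominator formats to 36.59%
        from pvdili.cohort import format_percent
        assert format_percent(30, 82) == "36.59%"

    def test_empty_profile_flagged(self):
        cohort = self.make_cohort(n_cases=1, de=0, no_outcome=1)
        profile = outcome_profile(cohort, "sarilumab")
        assert profile.denominator == 0
        assert profile.fatality_rate == 0.0


class TestCompareProportions:
    def test_hand_evaluated(self):
        chi2, p = compare_proportions(30, 175, 30, 82)
        a, b, c, d = 30, 145, 30, 52
        n = a + b + c + d
        oracle = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(oracle)
        assert chi2 == pytest.approx(11.8, abs=0.05)
        assert p < 0.001

    def test_matches_scipy_on_nondegenerate(self):
        observed = sps.chi2_contingency([[30, 145], [30, 52]], correction=False)
        chi2, p = compare_proportions(30, 175, 30, 82)
        assert chi2 == pytest.approx(float(observed.statistic))
        assert p == pytest.approx(float(observed.pvalue))

    def test_equal_proportions_zero(self):
        chi2, p = compare_proportions(10, 100, 20, 200)
        assert chi2 == 0.0 and p == 1.0

    def test_degenerate_equality(self):
        chi2, p = compare_proportions(0, 10, 0, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_fisher_and_yates_variants(self):
        odds, p_f = compare_proportions(30, 175, 30, 82, method="fisher")
        chi2_y, p_y = compare_proportions(30, 175, 30, 82, method="yates")
        chi2, _ = compare_proportions(30, 175, 30, 82)
        assert chi2_y < chi2
        assert 0 < p_f < 0.01

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 1, 10)
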