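# pvdili

Pharmacovigilance analysis of drug-induced liver injury (DILI) on
FAERS-style spontaneous reporting data, focused on the IL-6 receptor
antagonists tocilizumab and sarilumab in a COVID-19 context.

The package provides:

- **`pvdili.faers_io`** — parser for dollar-delimited FAERS-style quarterly
  ASCII tables (DEMO/DRUG/REAC/OUTC/THER/INDI) with partial-date handling,
  per-table reject accounting, report assembly and case-level deduplication
  (highest case version; ties by latest received date, then largest primary
  id).
- **`pvdili.synthetic_faers`** — a generator of FAERS-like quarters with
  planted structure: true reporting odds ratios between drugs and event
  sets, duplicate case versions, missing demographics, partial dates and a
  configurable onset-interval law, plus a ground-truth sidecar
  (`groundtruth.json`) with closed-form expected 2×2 cells.
- **`pvdili.cohort`** — case selection (study window, COVID-19 keyword
  matching, drug-synonym dictionary, 17-term preferred-term DILI
  definition) and descriptive stratification by age band, sex, reporter
  occupation, report quarter, region and outcome, with half-up percentage
  formatting.
- **`pvdili.disproportionality`** — 2×2 contingency tables and the four
  signal statistics: ROR with 95% Wald CI, PRR with uncorrected Pearson
  χ², IC (bits) and the unshrunk relative reporting ratio ("EBGM"), with
  multiplicative lower bounds `exp(ln x − z·s)` and the standard signal
  criteria. Zero-cell policy is strict by default (Haldane–Anscombe +0.5
  optional); a delta-method additive IC bound is available behind a flag.
- **`pvdili.onset_outcomes`** — time-to-onset intervals with exclusion
  accounting (missing/imprecise dates, negative intervals), onset
  summaries and cumulative shares, outcome profiles and fatality rates,
  two-sample t-test, Kruskal–Wallis and two-proportion comparisons.
- **`pvdili.cli`** — a `pvdili` command with `generate`, `parse`,
  `signals`, `onset`, `study` and `report` subcommands.

## CLI

Run the full analysis on synthetic data with planted signals (demo mode):

```sh
pvdili study --demo --seed 7 --n 4000 --out results/demo
```

or on an existing FAERS-like directory:

```sh
pvdili generate --n 5000 --seed 1 --out data/quarter
pvdili study --in data/quarter --out results/run --plots
pvdili signals --in data/quarter
pvdili onset --in data/quarter
```

The study bundle contains selection-flow counts, per-drug descriptive
tables (CSV), the signal table (CSV/JSON), onset summaries, outcome
tables, a mortality comparison and a provenance log; `--plots` (or the
`report` subcommand) adds an onset histogram and a fatality-rate figure.
`pvdili study --config study.yaml` accepts a YAML file whose keys mirror
the CLI options.

## Notes

- The IC025/EBGM05 bounds are deliberately the *multiplicative* form on the
  point estimate; this is not the conventional BCPNN credible interval, and
  the "EBGM" here carries no empirical-Bayes (MGPS) shrinkage.
- Outcome codes are not mutually exclusive, so outcome percentages use the
  number of outcome-bearing reports as denominator by default
  (`--denominator-rule cases` switches to all event cases).
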