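# opencohort

Automated point-prevalence and period-incidence time series for **open
cohorts** — datasets where people enter and exit follow-up at different
calendar dates (as in electronic-health-record extracts). The package
implements an explicit, boundary-exact counting ruleset over per-person
observation intervals, computes person-time denominators in exact integer
days (divided by 365.25 to give person-years), attaches Byar's-method
confidence intervals, stratifies by arbitrary categorical subgroups, and
ships a synthetic-cohort generator with closed-form ground truth plus
brute-force oracles so every rule is verifiable without any licensed
dataset.

## Input format

One CSV row per observation with ISO-8601 dates:

| column       | meaning                                             |
|--------------|-----------------------------------------------------|
| `start_date` | date study participation starts                     |
| `end_date`   | date study participation ends                       |
| `event_date` | date of first recorded event, or empty/`NA`         |
| `record_id`  | optional opaque identifier                          |
| *(others)*   | categorical stratifiers (e.g. ethnicity, region)    |

Column names are remappable (`--column-map role=name`), the date format
is configurable (`--date-format`), and rows with `end_date < start_date`
or unparseable dates are rejected with a per-row report. Records whose
event date falls outside the follow-up interval are kept and processed
verbatim by the rules (a validation warning counts them; `--strict`
drops them instead).

## The rules, in brief

For a half-open analysis period `[period_start, period_end)`:

- **Point prevalence** (anchored at `period_start`): numerator counts
  records with `start_date <= period_start`, `end_date >= period_start`
  and `event_date <= period_start`; the denominator drops the event
  condition. All comparisons are boundary-inclusive.
- **Period incidence**: numerator counts records with
  `period_start <= event_date < period_end` (strict at the period end)
  whose follow-up overlaps the period. The denominator is person-time:
  days from `max(start_date, period_start)` to
  `min(end_date, event_date, period_end)` — missing events are
  non-binding — provided follow-up overlaps the period and the event,
  when present, is on/after the period start and strictly after entry.
  Days are summed as integers and divided by 365.25 once per record.
- **Period prevalence** (optional extension metric): persons with an
  event before the period end among persons whose follow-up overlaps
  the period.

Confidence intervals use Byar's cube-root normal approximation to the
exact Poisson limits, applied to the numerator count and scaled by the
denominator and reporting multiplier (default per 100,000). A Wilson
score interval for proportions is available for sensitivity checks.

## CLI

```sh
# analyse the packaged example cohort, annual 2006-2021, all metrics
opencohort compute --output results.csv

# a real analysis, stratified by ethnicity, incidence only
opencohort compute --input cohort.csv --output results.csv \
    --metric incidence --start-year 2006 --end-year 2021 \
    --group-by ethnicity --multiplier 100000 --ci-level 0.95

# remap columns and date dialect
opencohort compute --input extract.csv --output results.csv \
    --column-map start_date=entry --column-map end_date=exit \
    --column-map event_date=diagnosis --date-format %d/%m/%Y

# generate a synthetic cohort with known parameters
opencohort synth --n 10000 --hazard 0.02 --entry uniform \
    --followup exponential:3 --seed 7 \
    --strata 'ethnicity=white:0.6:1.0,black:0.2:1.4,asian:0.2:0.8' \
    --output synthetic.csv
```

`compute` also accepts `--config analysis.yaml` (YAML or JSON mapping of
`AnalysisConfig` fields); explicit flags override the file. Results are
written as a long-format CSV (one row per metric × period × stratum,
overall rows included); logging goes to stderr so the tool composes in
pipelines. Exit codes: 0 success, 1 data error, 2 usage error.

## Package layout

- `opencohort.cohort` — domain types, validation, CSV readers/writers
- `opencohort.prevalence` — point-prevalence indicators and estimate
- `opencohort.incidence` — incidence indicator, person-time, estimate
- `opencohort.uncertainty` — Byar / exact-Poisson / Wilson intervals
- `opencohort.timeseries` — period grids, orchestration, stratification
- `opencohort.synthetic` — cohort generator, closed forms, oracles
- `opencohort.cli` — `opencohort compute` / `opencohort synth`
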