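# headachediary

Analysis toolkit for electronic headache-diary data: a rule-based attack
classifier (migraine / tension-type / other), calendar-day expansion and
28-day monthly outcome aggregation, diagnosis subgrouping, daily-use cohort
selection, baseline-vs-follow-up statistics, and a synthetic diary generator
so the whole pipeline can be exercised without any real user data.

## What it does

* **Diary model & I/O** (`headachediary.model`, `headachediary.io`) — four
  CSV tables (users, attacks, medications, daily entries) with strict
  validation: ISO-8601 timestamps, 0–10 intensity, non-overlapping attacks
  per user, referential integrity; missing demographics are preserved.
* **Attack classifier** (`headachediary.classifier`) — labels each attack
  MIGRAINE / TTH / OTHER. Migraine: ≥4 h duration with pain-feature
  criterion A (≥2 of unilateral, throbbing, moderate/severe intensity,
  aggravation by activity) and associated-symptom criterion B (nausea,
  vomiting, or photophobia *and* phonophobia); aura or an attributable
  triptan intake overrides everything. Attacks meeting both TTH and
  probable-migraine criteria count as migraine for users with a prior
  migraine diagnosis and as TTH otherwise. Every decision path is recorded
  in a rule trace.
* **Aggregation** (`headachediary.aggregate`) — monthly headache days
  (MHD), monthly migraine days (MMD), monthly acute-medication days (AMD)
  and mean intensities per user × 28-day month; episodic/chronic-migraine
  grouping from the first 90 days; selection of users with an entry on
  every day for *k* months.
* **Statistics** (`headachediary.stats`) — paired-samples t tests with 95%
  CIs (oriented baseline − follow-up), one-way repeated-measures ANOVA,
  and demographic summaries whose percentages always use available-data
  denominators.
* **Simulation** (`headachediary.simulate`) — per-user daily Bernoulli
  attack hazards with a multiplicative per-month decline, migraine-like vs
  tension-like symptom profiles, medication behaviour, full daily
  adherence, partially missing demographics, and closed-form expectations
  (`expected_mhd`) for testing.
* **Pipeline & CLI** (`headachediary.pipeline`, `headachediary.cli`) — a
  `headachediary` command with `simulate | classify | aggregate | analyze |
  run` subcommands, YAML configuration, and TSV/JSON reports.

## CLI quick start

```sh
# generate a synthetic 7-month cohort (four CSVs + ground_truth.tsv)
headachediary simulate --n-users 200 --months 7 --seed 1 --out-dir data/

# full pipeline: classify, aggregate, group, select cohort, analyze
headachediary run \
    --users data/users.csv --attacks data/attacks.csv \
    --medications data/medications.csv --entries data/entries.csv \
    --out-dir report/ --followup-month 7 --seed 1
```

`report/` then contains `monthly_outcomes.tsv`, `diagnosis_groups.tsv`,
`demographics.json`, `outcome_table.{tsv,json}`, `anova.json` and
`run_log.json` (config hash + seed). Individual stages are available as
`classify`, `aggregate` and `analyze` subcommands; classifier thresholds,
diagnosis thresholds and analysis settings are configurable via
`--config config.yaml` (unknown keys are rejected).

## Notes on design

* A "month" is 28 days anchored at each user's first day of app use;
  month 1 is baseline.
* Chronic migraine is assessed on 90-day totals (≥45 headache days with
  ≥24 migraine days); episodic migraine needs ≥5 migraine attacks in the
  first 90 days. Both are configurable.
* The default simulator confines each attack to one calendar day so that
  monthly day counts are exactly Binomial(28, hazard) and test
  expectations are closed-form; multi-day attacks are available behind
  `allow_multiday` for day-expansion stress tests.
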