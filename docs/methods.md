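# Methods

## Surveillance model

`ehrsentry` models an always-on hospital surveillance loop in three stages.

**1. Phenotype assembly.** The computational phenotype is a dated version
history of keyword and ICD-10-CM code patterns. The active rule set as of a
date is the union of all additions effective on or before that date, minus
removals, with duplicates collapsed by canonical key (tokenized phrase +
sex scope for keywords; normalized code for codes). Effective dates are
inclusive; each version's additions apply before its removals, so a phrase
can be introduced and simultaneously narrowed out of one sex scope in the
same version. A sex-scoped removal of an all-sex pattern narrows it to the
opposite scope rather than deleting it. The packaged default history
(`data/table1_default.yaml`) spans 2019 Q3 through 2021 Q2: a baseline
vocabulary of abuse/neglect/trauma terms and trafficking-specific codes, a
large 2019 Q4 expansion (wildcards such as `traffic%`, `force%`, `psych%`),
a 2020 Q1 male-specific list (adds male anatomy terms, subtracts phrases
that are nonspecific for male patients — "black eye" is carried as the
exemplar of those phrases), the 2020 Q2 sexual-assault cluster including the
deliberate misspelling "rapped", 2020 Q4 intimate-partner-violence phrases,
and "safe house" in 2021 Q2.

**2. Sentry scanning.** Encounters arrive in micro-batches (15-minute
windows by default; the examples use daily batches). Each batch is scanned
with the rule set assembled at the batch timestamp — late-arriving
encounters are scanned with the *current* ruleset, mirroring a live feed;
`retrospective_scan` exists for fixed-vintage analyses. An encounter yields
at most one alert aggregating every distinct (pattern, source) hit with
character spans, because the downstream unit of work is the case, not the
pattern hit. Alert ids are deterministic hashes of (encounter id, batch
time), so re-runs are reproducible and re-running a batch never duplicates
alerts.

**3. Navigator triage.** A single navigator reviews alerts earliest-first
within each calendar month up to a monthly capacity; the rest of the
month's queue expires (period-level review fractions in practice vary too
much for back-filling to be plausible). The highly-suspicious determination
is a Bernoulli draw with a configurable propensity, reflecting that the
real decision is subjective; no deterministic screening rule is invented.
Two RNG draws are consumed per review (disposition, then contact), in queue
order, from one seeded `numpy` generator.

## Matching semantics and their rationale

Text is lowercased and split on non-alphanumeric boundaries; the matching
unit is the whole word token. The vocabulary itself forces this choice: it
lists both *abuse* and *abusive*, and both *Transgender* and *Transsexual*,
which would be redundant under substring matching, and substring matching
would make *anal* fire on *analysis*. Hyphens are token boundaries, so
`trans-sexual` is a two-token phrase and also matches "trans sexual". `%` is
the only wildcard (SQL-LIKE, any run of ≥0 characters within one token);
a pattern token consisting only of `%` is rejected as it would match
everything. The compiled matcher is indexed by first literal token
(dictionary lookup for single literals, bucketed scan for phrases, linear
scan only for wildcard-first patterns) and is property-tested against a
brute-force character-level LIKE expansion.

The "code searches simplified to key phrase" behavior change is modeled as
a dated switch (default 2019-10-01) from which code patterns additionally
match their description phrase against diagnosis description text. The
mechanics of the original simplification are not documented anywhere we
can consult, so both behaviors are kept testable behind the switch.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `batch_minutes` | 15 | micro-batch window (min); daily batches = 1440 |
| `utilization_threshold` | 4 ED visits | utilization alert trigger |
| `utilization_window_days` | 90 days | look-back for ED visit counting |
| `longitudinal_followup` | on | re-alert every visit of a previously alerted patient |
| `monthly_capacity` / `default_capacity` | — / unbounded | navigator reviews per month (0 = month diverted) |
| `suspicion_rate` | user input | Bernoulli screened-in propensity |
| `daily_volume` | 440/day | Poisson mean encounter arrivals |
| `trigger_prevalence` | 0.008 | probability an encounter carries planted triggers |
| `repeat_visit_rate` | 0.2 | probability a trigger patient returns within ~3 weeks |
| `truth_fraction` | 0.4 | share of trigger encounters labeled true cases |

The ED-utilization threshold is an artifact default: increased utilization
is a recognized risk marker, but no published cutoff exists, so the value
is a documented knob rather than a claim. The trigger prevalence is
calibrated once so that at 440 encounters/day the sentry fires a handful of
alerts per day (the observed operating band is roughly 1–8/day); with
follow-up re-alerts the default configuration lands near 4/day.

## What the synthetic generator does and does not emulate

The generator reproduces the *structure* of a hospital feed: Poisson daily
arrivals, a sex mix, benign clinical boilerplate (including deliberate
near-miss confounders — *analysis*, *therapist*, *assessment*,
*transportation* — to exercise token boundaries), trigger encounters that
embed 1–3 realized patterns (wildcards completed, e.g. `traffic%` →
*trafficking*) and/or an active code, and return visits of flagged
patients. Benign text is rejection-sampled against the generating ruleset
(bounded attempts, then an error), so benign purity holds by construction
and sensitivity on the generator's own ruleset is 1.0 by design. Patterns
are sampled uniformly — no per-pattern frequency data exists to calibrate
against. It does **not** emulate realistic clinical language, negation,
misspellings beyond the vocabulary's own traps, demographic structure
beyond sex, or any real trafficking prevalence; passing tests therefore
demonstrate the correctness of the machinery, not field performance on
real notes.

## Numerical and design choices

- Timestamps are ISO-8601; naive inputs are taken as UTC and all
  comparisons are in UTC (unambiguous 15-minute windows). Serialization is
  to the second.
- Funnel percentages: half-up rounding to 2 decimals via `decimal`;
  undefined ratios (zero denominator) are `None`/empty, never 0. Total-row
  percentages are recomputed from summed integers, never averaged.
- The baseline comparison annualizes: `(12·suspicious/months) /
  baseline_per_year`.
- Unknown note types map to `other` with a logged warning (real feeds
  vary); structurally invalid records are hard errors naming the line.
- The desk-scale end-to-end reproduction in the test suite runs 40
  encounters/day over the 23-month reporting window with trigger prevalence
  0.055 — sized so the synthetic alert total (~1.8k) is comparable to the
  reported funnel while the whole suite stays fast — with monthly navigator
  capacity derived from the per-period review fractions and the per-period
  screened-in propensities taken from the published counts.

## Known limitations

- The published vocabulary is the general (female-applicable) list plus a
  described male delta; a fully enumerated female-specific list and the
  region-specific social-determinants attributes are not publicly
  available and are not represented.
- Any "inference logic" beyond lexical keyword/code matching is not
  specified in the public record; none is invented here.
- Reported review rates contain an internal inconsistency (a 47.3% figure
  alongside table arithmetic giving 43.17%); this package reproduces the
  table's arithmetic.
- Alert deduplication is per encounter, not per patient-day; whether the
  original system collapsed same-day alerts is unknown.
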