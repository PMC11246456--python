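# Methods

This note documents the statistical procedures, defaults and design
choices behind `pvsignal`, and what its synthetic-data tests do and do
not demonstrate about real spontaneous-report data.

## Data model and cleaning

A FAERS *case* is one safety report assembled from the seven quarterly
tables by `primaryid` equality; a `caseid` may carry several report
versions.  The cleaning sequence is the standard one for
disproportionality studies:

* **Deduplication.** One version per `caseid`: the survivor maximises
  `fda_dt`, ties broken by the higher numeric `primaryid`
  (lexicographic fallback for non-numeric ids, logged).  The operation
  is a deterministic function of the input *set* — output is sorted by
  caseid — and idempotent.
* **Suspect-drug selection.** A case qualifies when any drug row has
  the required role code (default `PS`, primary suspect) and its
  `drugname`/`prod_ai` contains a configured generic name, or
  `drugname` contains a trade name, as a case-insensitive substring.
  Substring matching is deliberate: FAERS verbatim names carry dose
  and formulation suffixes ("lacosamide 50mg tab").
* **Background definition.** The comparator ("all other drugs") is
  every case in which the target drug appears in *no* role.  Cases
  naming the drug in a non-required role only (e.g. concomitant) are
  excluded from both sides, so a partially-exposed report can neither
  dilute nor inflate the contrast.
* **Exclusions.** PTs in configurable administrative classes
  (off-label use, product issues, medication errors,
  indication-disease terms) are removed from reaction lists; a case
  whose list empties is dropped from the cohort denominator.  A case
  is dropped as a data-entry error when its event date and the suspect
  drug's earliest therapy start date are both known to day precision
  and the event precedes the start.  Partial dates (YYYY or YYYYMM)
  are carried with an explicit precision tag; they are never treated
  as evidence of error and never imputed.
* **Units.** Ages convert to years by DEC×10, YR×1, MON÷12, WK÷52.18,
  DY÷365.25, HR÷8766; weights to kg (LBS×0.4536; other codes dropped
  with a warning).  Age bands <18 / 18–64 / >64 years; weight bands
  <80 / 80–100 / >100 kg.  All percentages use available (non-missing)
  denominators.

## Disproportionality screen

Counting is **event-level**: each (case, PT) pair contributes one
count, so a case reporting three target-SOC PTs adds three events to
the SOC tally but remains one case.  For PT *p*:

|                 | PT *p* | all other PTs |
|-----------------|--------|---------------|
| target drug     | a      | b             |
| all other drugs | c      | d             |

ROR = (a·d)/(b·c) with the Wald interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).  When any cell is zero, 0.5 is
added to every cell (Haldane–Anscombe) and the estimate is flagged;
the reported event count `n` stays uncorrected.  A PT is *significant*
when ROR₀₂₅ > 1 (strict) and n ≥ 5.

No multiple-testing adjustment is applied: the minimum-count rule is
the only guard, which is the convention for hypothesis-generating
screens of spontaneous reports.  Flagged PTs are hypotheses, not
established risks — reporting odds ratios measure reporting
disproportion, not incidence or causality.

Stratified screens rebuild the 2×2 within each subgroup (sex, age
band, weight band, reporter class), excluding cases missing the
stratum variable from both margins; a stratum with zero drug events
returns an error entry rather than aborting the screen.

## Severity comparison

Categorical rows use the continuity-corrected Pearson χ² with one
degree of freedom, χ² = N·(|ad−bc| − N/2)²/(R₁R₂C₁C₂), the correction
clamped at zero when |ad−bc| < N/2.  When any expected cell is below
5 the two-sided Fisher exact test (point-probability rule) is used
instead; this single selection rule reproduces the test choices of the
published count tables the suite checks against.  Age and weight are
compared with both the pooled-variance t test and the two-sided
Mann–Whitney U (normal approximation with tie correction above n = 20,
exact below); both are always reported because published descriptive
tables in this field routinely mix the two.

## Clinical priority score

Each significant signal is scored on five features, 0–2 points each
(total 10): case count (<10 / 10–49 / ≥50), ROR₀₂₅ (<2 / 2–<5 / ≥5),
case-fatality proportion among the signal's cases (<25% / 25–<50% /
≥50%), reference-list membership (none / IME / DME, with DME taking
precedence), and a literature evidence grade (+ / ++, an input
annotation, not computed).  Bands: 0–4 weak, 5–7 moderate, 8–10
strong.  Deaths are counted as distinct cases with a DE outcome
mentioning the PT, never once per duplicate outcome row.

The shipped cut-points are a **calibrated reconstruction**: published
applications of this scale keep their exact point table in
supplementary material, so the defaults were chosen to reproduce the
published lacosamide cardiac-signal scores.  They reproduce 16 of the
17 published scores exactly and the 13-moderate/4-weak banding
exactly; the one discordant row (printed score 5 where the rubric
gives 6, same band) is feature-wise dominated by a row printed with a
*higher* score, so no monotone additive rubric can reproduce both.
Calibration is not independent validation — review the rubric before
applying it to another drug.  Because the lowest evidence grade earns
1 point, the attainable floor under the default rubric is 1.

## Time-to-onset and the Weibull shape-parameter test

TTO is the whole-day difference between the DEMO event date and the
earliest day-precision therapy start date of the suspect drug; both
dates must be full precision.  Zero days means onset on the day
therapy started.  Medians and IQRs use linear-interpolation quantiles
on the raw values.

For the hazard-trend classification, a two-parameter Weibull is fitted
by maximum likelihood: the profile score in the shape β,
1/β + mean(ln x) − Σxᵝln x / Σxᵝ, is strictly decreasing, so its root
is found by Brent's method on an expanding bracket (tolerance 1e-8)
after rescaling the sample by its geometric mean to keep xᵝ in
floating-point range (exact, by scale equivariance); the scale α then
has the closed form (Σxᵝ/n)^(1/β).  95% CIs are Wald intervals on
(log α, log β) from the observed information (central-difference
Hessian), back-transformed.  Fits require ≥ 10 usable values and
non-degenerate data; failures return a diagnostic error object rather
than raising.

Zero-day delays sit outside the support of the continuous likelihood;
the default shifts them to 0.5 days for fitting only
(`zero_handling="shift"`), with `"drop"` available.  Classification:
*early* iff β < 1 and CI upper < 1; *wear-out* iff β > 1 and CI lower
> 1; *random* otherwise.  In the pipeline, TTO values are pooled
across all PTs of a priority band (one fit per band), mirroring how
such analyses are reported; per-PT fits below the minimum n are out of
scope.  The model ignores censoring: cases that never develop the
event, or whose follow-up ended early, are simply absent, so β
describes the observed onset-delay distribution, not a true hazard.

## Synthetic data generator

`pvsignal.simulate.generate` emits "$"-delimited quarterly files whose
statistical structure matches what the analysis assumes: multi-table
cases keyed by primaryid/caseid; a configurable fraction of cases
duplicated as older versions (lower primaryid, earlier fda_dt), giving
deduplication an exact ground truth; PTs drawn from a catalogue of
background rates, with signal PTs' drug-side probability solved from
p/(1−p) = ρ·q/(1−q) so each carries an analytic expected ROR (the
non-signal mass is renormalised, so null PTs sit near but not exactly
at 1 — the recorded ground truth is exact for the realised probability
vectors); Weibull onset delays encoded as THER start dates and DEMO
event dates, a configurable fraction degraded to month precision;
seriousness, death, demographics, countries and reporter occupations
drawn at configurable rates.

Defaults emulate the descriptive profile of a large anticonvulsant
cohort in FAERS: 74% serious outcomes, 17% death among serious, 27%
of reports with a computable onset delay, 54.6% female with 11%
missing sex, 44% missing age, 74% missing weight, onset-delay Weibull
groups (α = 100, β = 0.48) and (α = 174, β = 0.52), a default group
(α = 120, β = 0.5), and 1 + Poisson(0.3) PTs per case (event-to-case
ratio ≈ 1.3).  Default cohort sizes (1,000 drug / 5,000 background
cases over 40 quarters) keep a full pipeline run in seconds; tests
scale up to ~50,000 cases where convergence properties demand it.

What the generator does **not** emulate: realistic co-prescription
networks, correlated demographics, secular reporting trends,
duplicate reports with *conflicting* content, verbatim drug-name noise
beyond suffixes, or true MedDRA granularity.  Passing tests therefore
demonstrate the correctness of the algorithms under the stated
stochastic model, not robustness to every pathology of real FAERS
data.

One seed drives all randomness; regeneration is byte-identical.  The
miniature committed-style fixture (~200 cases, `make_fixture_small`)
additionally hand-injects a zero-day onset, a date-error case, an
administrative PT alongside a cardiac one, and a PT absent from the
PT→SOC map, so every exclusion path is exercised deterministically.

## Numerical conventions

* z = 1.959963984540054 everywhere a 95% normal interval appears.
* Signal tables sort by descending ROR₀₂₅, ties by PT; priority tables
  by descending case count.
* `restrict_to_soc` warns about unmapped PTs and excludes them from
  the SOC tally only; the case keeps them for the drug-wide margin.
* Empty margins (a+b = 0 or c+d = 0) yield error estimates; empty
  strata yield error entries; both are reported, never silently
  skipped.

## Known limitations

* The screen's background is database-internal; external exposure
  denominators are unavailable, so no incidence can be derived.
* Reporter-class mapping from `occp_cod` ({MD, PH, HP, OT} →
  professional; {CN, LW} → consumer) is a convention, not an FDA
  specification.
* XML-dialect FAERS files and the pre-2012Q4 legacy schema are not
  supported.
* The shipped PT→SOC map and IME/DME/label lists are small synthetic
  fixtures for testing and the worked example — not the licensed
  MedDRA dictionary or the official EMA lists.
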