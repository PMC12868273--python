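# Methods

This note records the models, conventions and design choices behind
`pvfaers`, in the order the pipeline applies them.

## Report universe and cleaning

FAERS distributes quarterly `$`-delimited ASCII tables (DEMO, DRUG,
REAC, OUTC, THER, INDI, RPSR). All fields are read verbatim as text;
typing happens downstream. Ragged rows are skipped and counted, never
fatal; rows referencing a PRIMARYID absent from DEMO are kept but
excluded from analysis joins. The raw FDA dialect has no quoting; the
writer/reader additionally support backslash-escaped delimiters so every
table round-trips byte-exactly.

Cases are versioned by CASEID. Deduplication is global (all quarters
concatenated, one pass): per CASEID keep the row with the latest FDA_DT,
ties broken by the largest PRIMARYID, with numeric-aware comparison that
falls back to left-padded lexicographic order so the rule is total on
arbitrary identifiers. Deleted-case lists (distributed from 2019Q1) are
unioned and applied after deduplication to every quarter — a deleted
case is deleted globally. Rows missing CASEID are quarantined, not
dropped. The accounting identity `rows_in − duplicates_removed −
quarantined = rows_out` holds by construction and is checked against the
generator's injected-duplicate count.

Dates must be exactly eight digits forming a valid calendar date;
anything else (blank, 4/6-digit partials, impossible dates) is missing.
Ages convert to years by unit code (YR ×1, DEC ×10, MON ÷12, WK ÷52, DY
÷365.25, HR ÷8766); negative or non-numeric values are missing, but no
upper plausibility filter is applied — reporting streams genuinely
contain extreme ages and silently censoring them would misstate the
summary table. Age bands are half-open: [0,18), [18,45), [45,65),
[65,∞). Report year comes from the retained version's FDA_DT. Country
defaults to the occurrence field (`occr_country`), with the reporter
field selectable.

## Terminology mapping

Drug verbatims are case-folded, whitespace-collapsed, stripped of
trailing dosage/form tokens, and looked up exactly against a
verbatim→INN map; misses return an unmapped sentinel. Unmapped reports
stay in the database denominator N but get no drug-level row — they
carry information about the event margin even when the drug cannot be
identified. Combination products ("dorzolamide; timolol") are single
entities. Each INN maps to one or more ATC codes; level-1 classes are
the distinct first letters, and a drug in k classes is counted in all k
class tallies (repeated counting), so class counts legitimately sum to
more than the number of drugs. MedDRA PTs map to a single primary SOC; a
case is an ocular-injury case iff ≥ 1 PT maps to "Eye disorders". The
licensed WHO Drug Dictionary and MedDRA cannot be redistributed, so the
package bundles mock mini-dictionaries (~60 drug names/aliases, ~50 PTs
incl. non-ocular decoys) for tests and synthetic runs; real analyses
supply the full dictionaries as two-column CSVs.

## Disproportionality

Counting unit is the deduplicated report. Drug-level analyses count a
report once however many ocular PTs it carries; pair-level analyses
count each (report, PT) presence once; N is the entire deduplicated
database (all SOCs), since the 2×2 margins span the non-drug/non-event
space. Formulas are in the README. Choices worth recording:

* **No Haldane correction by default.** Zero cells flag the estimate as
  undefined rather than shifting it; the signal rule requires a ≥ 3
  anyway. A 0.5-correction flag exists for exploratory use.
* **BCPNN variant.** Default is the shrunken observed-to-expected IC
  with the credibility approximation IC025 = IC − 3.3(a+½)^−½ −
  2(a+½)^−3/2; the original beta/Dirichlet expectation–variance form is
  available (`variant="bate"`). The two agree in sign and converge for
  a ≥ 3; the Bate form shrinks slightly harder at small a.
* **MGPS.** The pipeline default EBGM is the relative reporting ratio
  a/E with a lognormal 5% bound — the common practice in FAERS papers
  that quote "EBGM05". The rigorous DuMouchel two-component
  gamma-mixture prior is provided as `mgps_full`: the prior is fitted by
  maximising the negative-binomial marginal likelihood (bounded
  multi-start L-BFGS-B + Nelder-Mead polish; log-parameters clipped to
  ±7), posteriors are gamma mixtures, EBGM = exp E[ln λ | a] and EB05
  the 5th posterior percentile by bisection. On pure-null data the ML
  prior legitimately degenerates toward a point mass — the mixture model
  presumes heterogeneity, which real databases have.
* **Combined verdict.** All thresholds strict: a ≥ 3 ∧ ROR lower > 1 ∧
  PRR lower > 1 ∧ IC025 > 0 ∧ EBGM05 > 2 ∧ a > 0; any undefined
  statistic fails. The four-way AND is deliberately conservative; no
  further multiplicity adjustment is applied.
* Estimates are reported at full precision internally and rounded
  half-up to 2 decimals only in presentation outputs.

## Time-to-onset and Weibull failure typing

TTO = EVENT_DT − earliest valid START_DT of the Primary Suspect drug's
therapy rows, in whole days; 0 is a valid same-day onset. Exclusions are
values with reasons (missing event/start, malformed partial dates,
negative interval), never exceptions. Summaries use linear interpolation
between order statistics (numpy default, "type 7") and the closed day
bands [0,30], [31,60], [61,90], [91,120], [121,150], [151,180],
[181,360], (360,∞).

The Weibull fit maximises the likelihood over (ln α, ln β) (BFGS from a
moments start). Zero days are replaced by 0.5 before fitting — the
density is singular at 0 for β < 1 — with zero-dropping switchable; the
replacement is recorded in the fit metadata. 95% CIs are Wald intervals
on the log parameters from the finite-difference observed information,
exponentiated so bounds stay positive. Fits need ≥ 30 valid values
(configurable) and a non-degenerate sample; failures are flagged, not
classified. Classification: early iff β's upper limit < 1, wear-out iff
lower limit > 1, random otherwise — an endpoint exactly at 1.00 counts
as "includes 1". Note that rounding onsets to whole days biases β̂
slightly upward for heavy-near-zero distributions; the CI-coverage study
therefore uses continuous draws, while end-to-end tests only require the
classification to survive discretisation. Censoring-aware survival
modelling is out of scope.

## Descriptives

The characteristics table reports counts and percentages of the
unique-patient denominator for sex, age bands, report year, reporter,
country, outcomes and TTO bands; percentages are half-up at 2 decimals,
single-select sections sum to 100 ± rounding. Outcomes are multi-select,
so their counts may exceed the denominator. The share of "serious"
reports depends on which codes count as serious; published serious
shares are generally not reconstructible from per-code rows, so the set
is explicit and configurable, defaulting to {DE, LT, HO, DS, CA, RI}
(OT excluded).

The package bundles reference tabulations of a large published
2004Q1–2024Q4 FAERS ocular-injury cohort (832,314 patients; printed
counts, and 30 per-drug Weibull fits with CIs). They serve as inputs to
identity checks: the percentage code path must reproduce the printed
shares exactly from the printed counts, and the failure-type rule must
reproduce the printed 28 early / 2 random split.

## Synthetic generator

The generator emulates the structural features the pipeline must handle:
versioned duplicate cases (an extra version with later FDA_DT and larger
PRIMARYID for a configured fraction of cases; default 0.2021, matching
the ~16.8% duplicate-row share of the raw database), deletion lists
riding on post-2019 quarters, blank/partial event dates (default 73.65%,
the published cohort's TTO exclusion rate), demographic marginals
(female 60.56%, age unspecified 38.65%, consumer reporters 50.04%, ...),
multi-select outcomes, trade-name aliases, and planted statistics: per
drug a report share, an ocular rate ratio (P(ocular|drug) = background
rate × ratio, validated ≤ 1), and Weibull(α, β) onset times realised as
START_DT/EVENT_DT pairs. START_DT is uniform in the quarter, FDA_DT lags
the event by 0–60 days. One Primary Suspect drug per report; concomitant
drugs are a documented extension.

The `paper2024` preset plants twelve drugs at the published cohort's
Weibull parameters with PRR-scale rate ratios (clipped to 18 so
probabilities stay valid at the 5% background ocular rate). Planted
shares total ~3.6% of the universe: per-drug shares are inflated
relative to the real database (where the top drug holds ~0.3%) so that
desk-scale runs of 10⁴–10⁵ reports give analysable counts, but kept
small enough that the all-other-drugs comparator stays within ~25% of
the background rate. `null` keeps the marginals with all rate ratios 1;
`uniform` is a flat debugging preset.

Everything drawn is recorded in a truth file; the same seed and config
produce a byte-identical file set.

What the generator does **not** emulate: correlated missingness,
duplicate reports with conflicting field values, multi-drug regimens,
indication-driven confounding, free-text verbatim noise beyond simple
aliases, or secular reporting trends. Passing recovery tests therefore
demonstrates correctness of the machinery under the stated model, not
robustness to every real-data pathology.

## Validation studies and problem sizes

`scripts/acceptance.py` (seeded) recomputes:

* the seven reference-cohort percentages and the dedup accounting
  identity (exact integer/decimal arithmetic);
* the failure-type split of the 30 reference Weibull fits;
* planted-signal recall: 10 universes × 20,000 reports; fraction of
  planted pairs with rate ratio ≥ 10 and observed a ≥ 20 flagged by the
  four-way rule (expected ≥ 95%);
* null calibration: 20 all-null universes × 4,000 reports; flagged
  drugs / drug-universe pairs (expected ≤ 5%, typically ≈ 0 — the
  four-way AND is conservative);
* rate-ratio recovery: one 100,000-report universe; worst multiplicative
  error of PRR against the generator's implied proportion ratio over
  drugs with a ≥ 30 (expected ≤ 1.5-fold). The planted quantity is a
  risk ratio, so PRR is the estimator scored; the odds-based ROR
  necessarily exceeds it when within-drug event probabilities are not
  rare (verified ROR ≥ PRR in the same run);
* Weibull CI coverage: 201 fits of n = 500 continuous draws across
  shapes {0.5, 1.0, 1.5} (expected ≥ 90% coverage of the 95% CI).

These sizes keep the full script under a minute on one CPU while leaving
comfortable statistical margins. The test suite runs the same studies at
identical sizes plus exhaustive small-table oracles (ROR/PRR against
exact rational arithmetic on all 2×2 tables with N ≤ 40).

## Known limitations

Signal detection is unstratified (no age/sex adjustment) and subject to
all the usual spontaneous-reporting caveats (no denominators of use, no
causality). The simplified EBGM understates shrinkage relative to full
MGPS for very sparse cells. XML-dialect FAERS files and direct FDA
downloads are out of scope; column-layout eras other than the bundled
default require a user-extended dialect.
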