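# Methods

`txcrowd` implements an end-to-end observational analysis of racial and
ethnic disparities in organ-transplant crowdfunding: from raw campaign
records through organ-type text classification, geographic resolution,
probabilistic race/ethnicity assignment, outcome construction, state-level
activity/need regressions, and adjusted incidence-rate-ratio (IRR) models.
Because the original scraped corpus and the external registry panels are not
redistributable, every input is emulated by a synthetic-cohort generator
with known ground truth, and the package's claims are validated by
closed-loop parameter recovery rather than by re-scraping.

## The synthetic cohort

The generator emulates four inputs under one seed, each from an independent
child random stream (so any single input is reproducible in isolation):

1. **Campaign corpus.** `n_campaigns` (default 20 000) fundraisers created
   2015 through March 2019; creation years are weighted 1/1/1/1/0.25 so 2019
   contributes a quarter-year. Race/ethnicity is drawn from the four-level
   mix White 0.52, Black 0.17, Hispanic 0.15, Other 0.16. The donation count
   is NB2 negative binomial (Var = mu + alpha·mu², alpha = 0.8 — far enough
   from zero that the dispersion test must choose the negative binomial)
   with log-mean linear in the true covariates: race (amount-raised
   multipliers 0.85 Black, 0.80 Hispanic, 0.95 Other vs White), creation
   year, social-media shares (plus a quadratic term with true coefficient
   0), organizer≠beneficiary, a high-fraud flag, a solid-organ flag, and
   three state indicators. The amount raised is donations × a lognormal
   per-donation amount (mean $75), so all three dollar outcomes are
   internally consistent and overdispersed. Goals are lognormal
   (median $10 000); the goal's log-mean is shifted by
   log(IRR_amount/IRR_success) per race so that the expected success rate
   carries its own configured multipliers (0.88 Black, 0.82 Hispanic).
   Because the race effect sits on the donation count and per-donation
   amounts are race-independent, the implied average-donation IRR is 1 for
   every group — matching the study's null finding for that outcome.
2. **City gazetteer.** States on a planar grid with cities scattered around
   each state center (Euclidean distances; spherical/haversine optional),
   lognormal populations, 1–3 zip codes per city (70% single-zip, which
   calibrates the share of campaigns with multiple candidate race/ethnicity
   outcomes to roughly the observed 7%), and a configurable
   hospital-city fraction.
3. **Name/zip probability table.** One row per (first name, last name, zip):
   a probability vector over the four categories summing to 1, whose argmax
   equals the generating race with fidelity f (default 0.9) independently
   per zip — a stand-in for recorded output of a commercial onomastic
   classifier.
4. **State–year–race panel.** Waiting-list additions (WLAs) are Poisson
   around race-specific per-100k base rates (log-median rates centred on
   the observed medians: White 57.6, Black 122.6, Hispanic 39.2 per 100k),
   uninsurance proportions are Beta around race-level means (White 0.07,
   Black 0.10, Hispanic 0.19), populations are lognormal race shares of a
   state total, and a configurable fraction of state-race cells is flagged
   population-insufficient to exercise the suppression rule.

Stories are template-generated: at least three clinical templates per organ
place a lexicon word adjacent to the organ term, "multiple" stories combine
two organs, "missing" stories mention a transplant without any organ term,
and a configurable fraction of stories append distractor sentences that
mention organs in non-clinical contexts ("a heart of gold") with no
clinically relevant adjacency — by construction, so they probe the
adjacency rule, not the lexicon.

What the generator deliberately does **not** emulate: real U.S. name
frequencies or zip geography, platform-specific page structure, correlation
between narrative quality and outcomes, or spatial correlation of race mix
across neighboring states. Passing recovery tests therefore demonstrate
that the *estimators* are correct under the stated generative model, not
that the substantive findings would replicate on re-scraped data.

## Corpus filtering

Records are deduplicated by canonical URL (lowercased, query string and
trailing slash stripped; first occurrence kept), then filtered by four rules
applied in a fixed order with first-match attribution so the audit is
additive: (1) non-US, (2) invalid numeric fields, (3) story lacking the
substring "transplant" (case-insensitive), (4) outliers in amount raised or
donation count. The outlier rule is concretized as a cut strictly above the
0.999 empirical quantile (linear interpolation) computed on the set
surviving rules 1–3; the quantile is configurable and the realized
thresholds are recorded in the audit. A recomputed upper-quantile cut is
not exactly idempotent on continuous data (the re-estimated quantile of the
truncated sample falls just below the truncated maximum), so
`apply_exclusions` accepts a previous audit's realized thresholds, under
which re-filtering is exactly idempotent. Monetary fields are held as
integer cents in memory and dollars-with-two-decimals on disk, converted by
exact decimal arithmetic.

## Organ-type classification

Stories are lowercased; hyphens separate tokens; punctuation is stripped;
the compound "bone marrow" collapses to one token *before* stop-word
removal; stop words (a frozen list shipped with the package) are removed,
deliberately creating new adjacencies. A story is organ-specific when a
clinically relevant word is immediately adjacent (before or after) to the
organ token; two or more qualifying organs yield "multiple", none yields
"missing". The label depends only on the story and the lexicon, never on
corpus context. The shipped lexicon (generic transplant-need words such as
"transplant", "failure", "donor", "surgery" plus organ-specific terms such
as "dialysis", "cirrhosis", "fibrosis") is a documented stand-in and fully
overridable; `collect_bigrams` exports ranked before/after pair frequencies
for curating it. Solid organs are heart, lung, kidney, liver, pancreas.

## Geographic resolution and query planning

Reported "city, state" strings are matched exactly (case-insensitively)
against the gazetteer; matches resolve to that city's zip set. Unmatched
records fall back to deterministic rule-based story scanning: gazetteer
"City, ST" mentions classified as host or beneficiary by a cue-word window
(host preferred), then full state-name mentions. No NER or external
geocoding is used.

The query planner unions three city subsets — hospital-flagged cities, the
k = 25 largest population centers per state (ties broken by name), and all
cities within eps of a DBSCAN cluster grown over seed campaign locations
(defaults eps = 50 km, min_pts = 1, so every seed founds a cluster) — and
emits the deduplicated query strings "{organ} transplant in {City}, {ST}"
over the seven organ terms. Coverage statistics report the fraction of
gazetteer cities and of total population within a radius r of any planned
city. DBSCAN is delegated to scikit-learn and verified in tests against a
hand-written density-reachability oracle.

## Race/ethnicity assignment

Per campaign, each candidate zip contributes the recorded top category and
probability. The primary aggregation weights each observed category by its
vote share times its mean probability: score(c) = (n_c/N)·mean(p over the
n_c zips naming c), assigning the argmax (7 of 10 zips naming White at mean
0.8 scores 0.7 × 0.8 = 0.56). The alternative procedure takes the category
of the single highest-probability zip. Ties break toward more votes, then
alphabetically — an arbitrary but frozen rule. Categories never observed as
a top category score 0. Published descriptions of this weighting are
typically given only through such worked examples; the per-category
"share × mean probability, argmax" reading adopted here is guarded by the
concordance flag (weighted vs max agreement) and the certainty-threshold
sensitivity, both carried through to the model stage. The certainty cut is
strict: score > 0.6. Only the top category per zip is used; the upstream
classifier's second-ranked pair is not consumed.

## State-level analysis

2019 WLAs are scaled by 0.25 (linear interpolation of the quarter-year
window). State-race cells flagged insufficient or below `min_population`
(default 10 000) are dropped and logged, with an explicit override list
available to mirror external suppression rules. Rates are per 100 000
race-specific population; uninsurance is kept as a proportion in [0, 1]
(survey tables sometimes label it "per 100 000", but reported medians of
0.07–0.19 are only consistent with proportions; the unit label is
configurable). Activity
vs need is summarized by OLS slopes of solid-organ campaigns per 100k on
WLAs per 100k and on the uninsurance rate, per race, with t-based
inference. Group summaries use medians and IQRs under the inclusive
linear-interpolation quartile convention; the across-group mean-equality
test is reported both as the one-way ANOVA F and its large-sample
chi-square equivalent ((k−1)·F on k−1 df), so either reading of a
"chi-square t-test for the difference in means" is checkable.

## IRR models

Each outcome (amount raised in whole dollars, success rate in percent,
average donation in dollars) is regressed with a log link on race dummies
(White baseline), year dummies (2015 baseline), shares and shares², the
organizer≠beneficiary, high-fraud (top decile of the fraud score by
default), and solid-organ indicators, and three state indicators: fourth
quartile of race-specific WLAs per 100k, fourth quartile of race-specific
uninsurance (both ≥ the 75th percentile, inclusive convention), and
Medicaid expansion. The family is chosen by a Cameron–Trivedi auxiliary
regression — ((y−mu)²−y)/mu on mu without intercept, one-sided t test —
selecting NB2 when p < 0.05; the success rate is always fitted by Poisson
pseudo-likelihood on the percent scale (IRRs are scale-free, so
percent-vs-fraction only shifts the intercept). NB2 is estimated by full
MLE (Newton from Poisson starting values, with a BFGS fallback; a
stationary point with a numerically zero score is accepted when the
optimizer reports precision loss, and a fixed-alpha fit is available, whose
alpha→0 limit reproduces the Poisson fit). Dollar outcomes are rounded to
whole units before NB fitting. Standard errors are sandwich estimates
clustered on state with the degrees-of-freedom small-sample scaling (CR1);
IRRs and their CIs are the exact exponentials of the coefficient-scale
estimates. Rows are canonically ordered inside the model so estimates are
exactly invariant to input row order — this is also what makes repeated
pipeline runs byte-identical. Records with zero donations drop out of the
average-donation model only.

Sensitivity analyses refit the base model on four subsets — solid-organ
campaigns only, excluding 2019, weighted/max-concordant classifications
only, and certainty score > 0.6 — plus two reduced specifications (race and
year alone; race, year and campaign characteristics alone). Subsets too
small to estimate are reported as not estimable without aborting the run.

Parameter-recovery testing fits the models on the generator's *true* race
labels: with name-table fidelity 0.9, classification error attenuates race
IRRs toward 1, so coverage of the generative truth through the noisy
assignment channel would measure misclassification, not estimator quality.
Assignment accuracy is verified separately (observed accuracy ≥ f − 3
binomial SEs), and the full pipeline (with the noisy channel) is exercised
end-to-end for determinism and funnel audits.

## Numerical and design choices

- Quantiles and quartiles use inclusive linear interpolation throughout
  (IQRs and Q4 flags are convention-sensitive; one convention is frozen).
- Printed percentage shares use half-up decimal rounding, not banker's
  rounding, to match publication style.
- Determinism: all randomness flows from one integer seed through named
  child streams; corpora, panels, coefficient tables, and manifests are
  byte-identical across runs with identical configuration.
- Problem sizes in the shipped tests: single-fit checks at n = 8 000,
  coverage studies at 100 replicates × n = 20 000 (story generation is
  skipped in replicates that never touch the text), classifier accuracy at
  n = 5 000 stories, geometry oracles at 50 points.
- Cluster count defaults to the 51 state-level units; the cluster-robust
  estimator requires at least two clusters and the quartile flags at least
  four states per race group.

## Known limitations

- The shipped organ lexicon and stop-word list are stand-ins; real-corpus
  performance depends on curating them (the bigram export exists for this).
- The weighted-aggregation reading of the score formula is one consistent
  interpretation of a worked example; the max-probability alternative and
  the concordance restriction bound its influence.
- The generator's average-donation race effect is identically 1, so that
  model's recovery test can only confirm a null.
- Success-rate Poisson pseudo-likelihood treats a continuous ratio as a
  count-model outcome; robust errors make the inference valid for the mean
  model, but the dispersion statistic has no count interpretation there.
- State-level slopes on synthetic geography are not comparable to any
  published slope; they validate the estimator, not the substantive result.
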