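# txcrowd

Racial and ethnic disparity analysis of organ-transplant crowdfunding
campaigns, built as a tested, reusable pipeline on synthetic cohorts with
known ground truth.

Medical crowdfunding is a major financing channel for transplant
candidates facing high out-of-pocket costs, and campaign outcomes may
differ systematically by the organizer's race or ethnicity. `txcrowd`
implements the full analysis chain such a study requires:

- a **synthetic cohort generator** emulating the four inputs (campaign
  corpus, city gazetteer, name/zip onomastic probability table,
  state–year–race panel of waiting-list additions and uninsurance) with
  every generative parameter recorded as ground truth;
- **corpus filtering** — URL deduplication and a four-rule exclusion
  filter (non-US, invalid fields, no "transplant" in the story, outliers)
  with an additive audit trail;
- **organ-type classification** of free-text stories by bigram adjacency:
  a story is organ-specific when a clinically relevant word is immediately
  adjacent to the organ term; multi-organ stories are "multiple", others
  "missing";
- **geographic resolution** of self-reported "city, state" against a
  gazetteer with story-text fallback, plus the three-subset query planner
  (hospital cities, top-25 population centers per state, DBSCAN clusters
  around seed locations) with population-coverage statistics;
- **race/ethnicity assignment** from name/zip classifier output,
  aggregating over a campaign's candidate zips by vote-share-weighted mean
  probability (with a max-probability alternative, concordance flag, and a
  strict 60% certainty threshold);
- **state-level analysis** — campaigns and waiting-list additions (WLAs)
  per 100 000 race-specific population, KFF-style small-population
  suppression, OLS activity/need slopes, and group median/IQR summaries
  with mean-equality tests;
- **IRR count models** — the centerpiece, statsmodels-style: `IRRModel`
  is built from a DataFrame and `fit()` returns `IRRResults`.

## The model

For outcome $y_i$ (amount raised in dollars, success rate in percent, or
average donation) of campaign $i$ in state $s(i)$:

$$\log E[y_i] = \beta_0 + \sum_{r \ne \text{White}} \beta_r\,\mathbb{1}[\text{race}_i = r] + x_i^\top\gamma$$

with $x_i$ the year dummies (2015 baseline), shares and shares², the
organizer≠beneficiary, high-fraud and solid-organ indicators, and three
state indicators (Q4 race-specific WLAs per 100k, Q4 race-specific
uninsurance, Medicaid expansion). The family is negative binomial (NB2) or
Poisson according to a Cameron–Trivedi overdispersion test; the incidence
rate ratio $\mathrm{IRR}_r = e^{\beta_r}$ is the multiplicative effect on
the expected outcome, with sandwich standard errors clustered on the 51
state units (CR1).

## Worked example

```python
from txcrowd import RunConfig, TruthConfig, run_pipeline

cfg = RunConfig(truth=TruthConfig(seed=42, n_campaigns=5000))
res = run_pipeline(cfg, "run42")
print(res.manifest["funnel"])
print(res.irr_results["amount_raised"].summary())
```

prints the campaign funnel and the fitted amount-raised model:

```
{'found': 5000, 'deduplicated': 5000, 'passed_exclusions': 4992, 'analytic_set': 4992}
IRR model: amount_raised ~ race + 12 covariates
family: negbin (alpha = 1.082)
n = 4992, clusters(state) = 51
overdispersion: t = 19.90, p = 3.8e-85 -> negbin
term                             IRR              95% CI         p
const                       3075.422 2769.208 - 3415.496         0
race_Black                     0.844    0.775 -    0.919  9.06e-05
race_Hispanic                  0.857    0.774 -    0.948   0.00276
race_Other                     0.853    0.774 -    0.941   0.00143
...
```

The generator drew this cohort with true amount-raised IRRs of 0.85
(Black) and 0.80 (Hispanic) versus White; the fitted IRRs of 0.844 and
0.857 recover them within the cluster-robust confidence intervals — the
dispersion test correctly picks the negative binomial (the donation counts
were drawn with NB2 overdispersion alpha = 0.8). `res.table1` carries the
counts, shares, and median/IQR outcome summaries by race;
`res.slopes` the per-race state-level activity/need slopes; and with
`run_sensitivities=True` the four subset sensitivity analyses and two
reduced specifications.

A CLI mirrors the library (`txcrowd simulate`, `txcrowd filter`,
`txcrowd classify-organs`, `txcrowd plan-queries`, `txcrowd assign-race`,
`txcrowd fit-irr`, `txcrowd run --seed 42 --out rundir`).

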