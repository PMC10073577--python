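# Methods

## Study design being implemented

The pipeline implements an active-comparator cohort design in
administrative claims: infants of mothers prescribed a rhubarb-rhizome
Kampo formulation (KRR) in the first trimester are compared with infants
of mothers prescribed magnesium oxide (MgO), the first-line osmotic
laxative, in the first trimester. Because both groups were treated for
constipation, comparing them reduces confounding by indication relative
to an untreated comparator. The outcome is any major congenital
malformation (MCM) diagnosed in the infant's first year. Mothers exposed
to senna glycosides (SG) in the first trimester are excluded from the
comparison because senna shares sennoside A with rhubarb rhizome and
would contaminate both arms.

## Pregnancy dating

Claims record neither conception nor delivery dates. The package dates
pregnancies as follows, in whole calendar days:

* **Onset**: for each GA-annotated diagnosis, candidate onset =
  diagnosis date − (7·weeks + days). The annotation with the latest
  diagnosis date is used, on the rationale that dating late in pregnancy
  is most accurate. Weeks-only records imply day 0. When two annotations
  share the latest date but disagree, the smaller implied gestation
  (later onset) is taken and a warning logged — conservative for
  first-trimester exposure classification; the choice is arbitrary and
  configurable in principle.
* **Delivery**: a delivery-specific procedure entry (latest if several);
  else any other delivery-related entry; else the 15th of the infant's
  birth month (insurance does not always cover uncomplicated deliveries,
  so ~40% of mothers genuinely lack entries). Entries dated outside the
  birth month ±1 month are ignored with a warning.
* **Cap**: if delivery − onset > 294 days (the post-term induction
  threshold), onset is reset to delivery − 294 days and the episode
  flagged. The cap is applied before trimester construction.
* **Trimesters**: days 0–97 (through week 13 day 6), 98–195 (week 14
  day 0 through week 27 day 6), 196–delivery (week 28 day 0 onward),
  each window closed at both ends and clipped at delivery; the third
  window is empty below 196 days of gestation.

## Exposure model

Each prescription's exposure date falls back dispensing date → admission
date → the 15th of the claim month (month and year are always present on
a claim). The exposure interval is [date, date + days of supply − 1]. A
drug class is "exposed in trimester T" when any interval of that class
overlaps the trimester window; a `dispense_date` rule (classification by
the resolved date alone) is available as a configuration switch for
sensitivity work. As-needed prescriptions count as exposure in the
primary analysis; sensitivity analysis 4 removes mothers whose
index-class prescriptions were all as-needed. Kampo products are matched
by product name (they carry no WHO-ATC laxative codes); MgO and SG by
ATC code. The drug dictionary is YAML configuration.

## Eligibility and covariates

The cascade (each stage counted in the attrition report): infant
enrolled with the insurer in its birth month and linked to the mother;
datable pregnancy; continuous maternal coverage from 3 months before
onset through delivery, checked at month granularity because the
database exposes enrollment by month; delivery year 2010–2019 (first
estimable pregnancy kept — the pipeline constructs at most one episode
per mother, so this stage is structural); ≥12 months of infant coverage
from the birth month; singleton delivery; no infant chromosomal
abnormality (Q90–Q99), since those are not exposure-related and dilute
risk detection.

Adjustment covariates: maternal age at delivery in bands ≤24 / 25–29 /
30–34 / ≥35 (reference: youngest), delivery year in bands 2010–2012 /
2013–2015 / 2016–2019 (reference: earliest), preterm birth, epilepsy,
diabetes, obesity, and first-trimester use of a suspected teratogen.
Preterm birth is defined as gestation < 259 days (37 weeks, the WHO
convention; the source design lists the covariate without a threshold).
Condition covariates are ascertained from any matching diagnosis between
onset − 3 months and delivery; the window is a design choice ("medical
history" is not otherwise operationalisable in claims) and the code
prefixes are editable YAML. The teratogen list is a placeholder of five
well-known teratogenic ATC codes, explicitly not a validated list.

## Outcome ascertainment

An infant has an MCM when at least one diagnosis matches an included
ICD-10 prefix (major subset of Q00–Q89) and no excluded minor-anomaly
prefix, dated within the first day of the birth month through the last
day of the 11th month after it — a 12-month window at month granularity,
because exact birth dates are unavailable. The included/excluded split
ships as an editable EUROCAT-style YAML default grouped into the ten
organ systems used for reporting; tests deliberately validate against
the synthetic generator's own code choices, so pipeline correctness does
not depend on the default list's clinical fidelity. Note the
major/minor boundary within Q00–Q89 is genuinely ambiguous in the source
design; the package implements "major subset included, configured minor
subset excluded".

## Statistics

* **Crude OR**: (a·d)/(b·c) with the Woolf 95% interval
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). A zero cell raises an error
  that suggests the optional 0.5 continuity correction (off by default;
  the primary analysis has no zero cells). Reported to 3 decimals.
* **Adjusted OR**: maximum-likelihood logistic regression
  (exposure indicator + the covariates above), Wald 95% interval on the
  exposure term. Newton–Raphson is tried first; on non-convergence or a
  singular Hessian — common under quasi-separation when a covariate
  stratum has no events — the fit is repeated with BFGS and the wide
  Wald interval is kept, which is the standard behaviour of mainstream
  statistical software. Complete separation raises an explicit error.
  Constant covariate columns are dropped with a warning. In an
  exposure-only model the Wald interval equals the Woolf interval (the
  2×2 is saturated); this is tested to 1e-6.
* **Trend tests**: Cochran–Armitage with integer scores 1, 2, 3 across
  trimesters; z² equals the 1-df trend chi-square (validated against R's
  `prop.trend.test`). A mother prescribed in several trimesters counts
  in each trimester's numerator (the prevalence table's rows are
  per-trimester prevalences, not mutually exclusive categories). The
  third-trimester denominator is restricted to pregnancies reaching
  gestational day 196. An exact conditional version enumerates all
  tables with the observed margins (multivariate hypergeometric null)
  and is cross-checked against a seeded Monte-Carlo permutation test;
  it is feasible for small counts only.
* **Group comparison**: Pearson chi-square without continuity
  correction for categorical variables (this reproduces the published
  group-comparison p-values; the Yates-corrected statistic does not),
  two-sample t-test for continuous ones. Expected cells below 1 flag
  the chi-square as unreliable. Two-sided tests, α = 0.05, no
  multiplicity correction.
* **Sensitivity analyses**: (1) drop mothers with first-trimester
  teratogen prescriptions; (2) keep mothers with strictly more than 30
  total supply days of the index laxative overlapping the first
  trimester; (3) drop mothers with both MgO and KRR in the first
  trimester; (4) drop mothers whose index-class first-trimester
  prescriptions were all as-needed. Each re-runs the crude and adjusted
  estimates on the subset.

## Synthetic data generator

The generator emulates the structure of the study database so that the
pipeline can be validated against known truth. Defaults are the study
conditions:

| parameter | default | rationale |
|---|---|---|
| gestation length | N(270.7, 12.9²) days, truncated to [119, 294], rounded | reported distribution |
| delivery evidence | 49.4% specific / 9.4% other / 41.2% none | reported dating-method shares |
| GA visit schedule | weeks 8, 12, 20, 30, 38 | typical prenatal schedule; visit patterns are not reported, so this is a stated choice |
| prescription prevalence | per class: overall + per-trimester targets from the prescription-frequency table | see correlation model below |
| missing dispensing date | 5% (half retain an admission date) | plausible; not reported |
| MCM base rate | 6.1% (logit intercept) | reported first-year MCM prevalence |
| covariate prevalences | comparator-group values (hypertension 1.7%, diabetes 4.5%, obesity 0.7%, epilepsy 0.9%, teratogen 0.4%, caesarean 22.7%) | group-characteristics table |
| covariate→outcome effects | log(1.5) for preterm birth and obesity, 0 otherwise | plausible, arbitrary; only recovery of the exposure effect is tested, not these values |
| multiple births / chromosomal / enrollment churn | 1% / 0.5% / 2% | plausible rates to exercise the exclusion stages |

Within a drug class, per-trimester prescribing must be correlated:
independent draws at the per-trimester prevalences would give an
any-trimester prevalence far above the reported one (47% vs 34.6% for
MgO). The generator uses a one-factor model — a latent "user" indicator
with probability π, and conditional per-trimester draws Bernoulli(p_t/π)
— where π is solved numerically so that both the per-trimester and the
any-trimester marginals match their targets simultaneously.

The outcome is drawn per infant with probability
expit(logit(base rate) + β_KRR·krr_t1 + Σ β_c·covariate_c), where β_KRR
is the configurable true log odds ratio (0 by default). Truth (onset,
delivery, exposure flags, covariates, outcome) is recorded before
missingness injection, so dating and recovery tests are exact.

**What the generator does not emulate**: real coding idiosyncrasies and
code granularity; correlation between exposure choice and covariates
(the large obesity imbalance between groups seen in the real data is not
reproduced — covariates are drawn independently of exposure, so the
synthetic crude and adjusted estimates differ little); stillbirths and
abortions (unobservable in the source design); sequential pregnancies;
seasonal prescribing. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under clean-ish conditions, not
robustness to every real-data pathology.

## Validation studies and problem sizes

`validation.py` runs the full pipeline per replicate (generation through
adjusted estimate). The package's calibration checks use 200 replicates
of 10,000 mothers at a true null (CI coverage of 1.0, band 95% ± 4%)
and 100 replicates of 20,000 mothers at a true odds ratio of 2
(mean adjusted log-OR compared with log 2). At 10,000 mothers only
~60–70 mothers are KRR-exposed with ~4 expected events, so individual
replicates are noisy and occasional quasi-separation is expected; these
sizes keep each study within a few minutes while the replicate counts
give tolerances of a few percent. Replicates with an inestimable
exposure effect count as non-covering in the coverage study
(conservative) and are omitted from the recovery mean.

A caveat on the recovery study: at 20,000 mothers the exposed arm holds
~125 mothers with ~16 expected events, which is the sparse-data regime
for the maximum-likelihood log odds ratio. The sample log-odds is a
concave transform of the event count, so its expectation sits slightly
below the true value at these counts (direct binomial simulation of the
same 2×2 puts the attenuation near −0.03), and the per-replicate
standard deviation of the estimate is ~0.3, leaving a Monte-Carlo
standard error of ~0.03 on a 100-replicate mean. A tolerance on the
recovery mean much tighter than ~0.1 is therefore not a clean test of
pipeline fidelity at this scale — per-replicate agreement with a
truth-exposure oracle is the sharper check, and the estimator matches
that oracle closely. Bias-reduced (Firth-type) fitting would shrink the
attenuation but is deliberately not used: the implemented estimator is
plain ML logistic with a Wald interval, matching the analysis being
reproduced.

## Numerical and formatting choices

Odds ratios and intervals are reported to 3 decimals; percentages to 1
decimal in outcome tables and 2 in prevalence tables (matching the
respective published precisions). All randomness flows from a single
integer seed through `numpy.random.default_rng`; identical configuration
yields byte-identical bundles and reports. CSV output uses ISO-8601
dates, `YYYY-MM` year-months, empty strings for missing values and
`true`/`false` booleans.

## Known limitations

* The default ICD-10 and drug code lists are placeholders; real analyses
  must substitute validated lists.
* Exposure is prescription-based: dispensed ≠ ingested, and
  over-the-counter laxatives are invisible — both understate exposure.
* The month-midpoint delivery fallback dates ~41% of pregnancies with up
  to ±15 days of error, which slightly blurs third-trimester
  classification and can trigger the 294-day cap spuriously near term.
* The exact trend test enumerates O(n²) tables and is only for small
  fixtures.
* One pregnancy per mother; multifetal and sequential pregnancies are
  out of scope.
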