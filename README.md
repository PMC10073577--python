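# kampopreg

A claims-database pharmacoepidemiology pipeline for assessing whether
first-trimester exposure to rhubarb-rhizome-containing Kampo medicines
(KRR) — traditional Japanese herbal laxatives — is associated with major
congenital malformations (MCM) in infants, using magnesium oxide (MgO),
the standard osmotic laxative, as an active comparator. The design
addresses confounding by indication: both groups are constipated and
treated, so the contrast isolates the choice of laxative.

The package is aimed at pharmacoepidemiologists working with Japanese
administrative claims, where neither pregnancy onset nor delivery dates
are recorded directly and must be reconstructed from gestational-age
(GA) annotations and delivery-related claims. Because such databases are
proprietary, the package ships a synthetic claims generator with known
ground truth, so every stage — dating, eligibility, exposure, outcome
ascertainment, statistics — is testable end to end.

## What it computes

* **Pregnancy dating.** Onset = diagnosis date − annotated GA (most
  recent annotation wins); delivery = delivery-specific procedure entry,
  else other delivery-related entry, else the 15th of the infant's birth
  month. Gestation is capped at 294 days (onset moved back if exceeded).
  Trimesters: gestational days 0–97, 98–195, 196–delivery.
* **Cohort.** Mother–infant linkage within the insurer, continuous
  maternal coverage from 3 months before onset through delivery,
  delivery in 2010–2019, ≥12 months infant follow-up, singleton, no
  chromosomal abnormality (ICD-10 Q90–Q99); attrition reported per stage.
* **Exposure.** Prescription dates resolved via dispensing → admission →
  month-15th; exposure intervals from days of supply; group 1 = MgO in
  trimester 1, group 2 = KRR in trimester 1 (with or without MgO),
  senna-glycoside exposure excludes the mother.
* **Outcome.** MCM = major ICD-10 Q00–Q89 diagnosis (minus a
  configurable minor-anomaly list) in the infant's first year of life.
* **Statistics.** Crude odds ratio with the Woolf interval
  `exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`; adjusted OR from
  multivariate logistic regression (maternal age and delivery-year
  bands, preterm birth, epilepsy, diabetes, obesity, first-trimester
  teratogen use) with a Wald interval; Cochran–Armitage trimester trend
  tests (asymptotic and exact-conditional); group-comparison tables; the
  four sensitivity analyses (teratogen-free subset, >30 supply days,
  no dual MgO+KRR exposure, not as-needed-only).

## Worked example

```python
from kampopreg import TwoByTwo, crude_or

res = crude_or(TwoByTwo(a=28, b=450 - 28, c=680, d=9852 - 680))
print(f"{res.or_point:.3f} ({res.ci_low:.3f}-{res.ci_high:.3f})")
```

prints `0.895 (0.606-1.322)`: among 450 KRR-exposed infants, 28 had an
MCM (6.2%), versus 680 of 9,852 (6.9%) in the MgO group — a confidence
interval straddling 1, i.e. no detectable difference in malformation
risk between the two laxatives.

End to end on synthetic data (`python examples/04_full_analysis.py`):

```
attrition:
    5000  linked mother-infant pairs (infant enrolled in birth month)
    5000  datable pregnancy episode
    4944  maternal coverage from onset - 3 months through delivery
    ...
group sizes: {'excluded_sg': 101, 'group1_mgo': 673, 'group2_krr': 33, 'unexposed': 4021}
crude OR 0.426 (0.057-3.188), 47 events in 706 pairs
adjusted OR 0.488 (0.064-3.729)
```

(a null-effect cohort: with only 33 KRR-exposed mothers at this size the
interval is wide and covers 1, as it should)

The `examples/` directory has one short script per capability:
simulation, dating, exposure classification, the full pipeline, and the
published-statistics reproduction. A thin CLI wraps the same calls:

```bash
kampopreg simulate --n 5000 --seed 7 --out bundle/
kampopreg analyze --bundle bundle/ --out report/
```

`report/` then holds `table1.csv`–`table4.csv` (group characteristics,
prescription prevalence with trend tests, MCM prevalence by organ
system, crude/adjusted/sensitivity odds ratios), the per-mother
intermediate frames, and `attrition.json`.

## Configuration

Drug dictionaries and ICD-10 code lists are editable YAML
(`src/kampopreg/data/*.yaml`): the 17 KRR product names, MgO/senna ATC
codes, covariate condition prefixes, and the major/minor malformation
split. The defaults are reasonable placeholders, not validated clinical
code lists; swap in your own for real analyses. See `docs/methods.md`
for the model, its assumptions, and known limitations.
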