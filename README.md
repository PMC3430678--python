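# msikit

A toolkit for WHO maternal near-miss assessment and Maternal Severity
Index (MSI) benchmarking, for obstetric epidemiologists, quality-of-care
auditors and health-service researchers.

## The problem and the model

Maternal deaths are too rare at the facility level to audit care reliably.
The WHO maternal near-miss approach therefore studies women who *nearly*
died: a **maternal near miss** is a woman who presented at least one of 25
standard life-threatening conditions (severity markers, grouped by organ
system) during pregnancy, childbirth or postpartum and survived. The count
of distinct markers present in a case is her **maternal severity score**
(MSS, 0–25).

The **Maternal Severity Index** is the estimated probability of maternal
death among women with life-threatening conditions, from a logistic model
developed in a one-year multicenter surveillance study in 27 Brazilian
referral maternity hospitals (82,388 deliveries, 9,555 complicated
pregnancies, 770 near misses, 140 deaths):

```
logit = β₀ + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄ + β₅x₅ + β₆x₆ + β₇x₇
MSI   = e^logit / (1 + e^logit)
```

with x₁ the severity score and x₂…x₇ binary indicators (condition
identified within the first 24 h of stay; severe pre-eclampsia; cancer;
any cardiovascular-failure marker; any respiratory-failure marker;
hysterectomy), and β = (−7.540, 0.309, 0.287, −0.579, 3.492, 4.209,
1.513, −1.169) — packaged as the coefficient set `brazil2012`.

Summing MSI over a cohort gives its expected death count; the
observed/expected (O/E) ratio, with exact Poisson limits, benchmarks a
facility or period against the reference standard of care after case-mix
adjustment.

The package provides:

- `msikit.markers` — the 25-marker catalog (with published lab cutoffs and
  unit handling), case classification, severity score, organ profiles
- `msikit.msi` — covariate derivation and the MSI formula
- `msikit.epi` — validation statistics: sensitivity/specificity (Wilson),
  likelihood ratios (Simel), relative risks (Katz), MMR, score-mortality
  tables
- `msikit.modeling` — logistic refits, stepwise selection, Hosmer–Lemeshow,
  Nagelkerke R², AUROC with DeLong intervals, cohort splitting, AUROC
  sample-size
- `msikit.benchmark` — expected deaths, O/E ratios, stratified reports
- `msikit.simulate` — a calibrated synthetic-cohort generator so everything
  is testable without patient data
- `msikit.io` / `msi` CLI — CSV/JSON readers, writers and a thin
  command-line surface (`msi simulate|classify|score|validate|benchmark|fit`)

## Worked example

```python
from msikit import CaseRecord, classify_case, severity_score, msi

case = CaseRecord(
    "c",
    {"cardiac_arrest", "cpr", "intubation_ventilation", "shock",
     "vasoactive_drugs"},
    early_identification=True,
)
print(classify_case(case).value, severity_score(case), round(msi(case), 3))
```

prints `maternal_near_miss 5 0.503`: five markers including cardiovascular
and respiratory failure, identified on admission, give an estimated death
probability of 50.3% — and since the woman survived, she is a maternal near
miss. The scripts in `examples/` walk through each capability; e.g.
`python examples/03_validation_statistics.py` reconstructs the criteria's
validation statistics from the packaged study counts and prints

```
plr             106.8 (99.56-114.6)
...
MMR: 170 per 100,000 live births (144-201)
```

(a positive likelihood ratio of ~107 is why near misses are valid proxies
for deaths), and `python examples/04_benchmark_facilities.py` benchmarks
two simulated facilities, flagging the one with excess mortality
(`O/E=1.62 (1.28-2.01)`).

MSI estimates describe groups of women with similar severity; they must
not be used to guide the care of an individual patient.

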