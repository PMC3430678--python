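# Methods

## The marker catalog and case classification

The catalog encodes the 25 WHO life-threatening conditions with their
organ system (cardiovascular, respiratory, renal,
coagulation/hematological, hepatic, neurological, uterine), their severity
group (group B corresponds to SOFA score categories 3–4, i.e. greater
severity) and, for the eight threshold-bearing markers, the published
cutoff per unit scale with the published strictness (creatinine `≥300` is
non-strict, platelets `<50 000` strict, pH `<7.1` strict, respiratory rate
two-sided `>40 or <6`, and so on).

Two unit-scale notes:

- The creatinine (300) and bilirubin (100) SI cutoffs are printed in some
  sources as "mmol/l", a magnitude only physiologically coherent as
  **µmol/l** (300 µmol/l ≈ 3.4 mg/dl). The catalog stores the printed
  numbers verbatim per unit scale, treats the SI unit as µmol/l and
  accepts "mmol/l" as an alias of the same printed cutoff. Values are
  never converted between scales; an unknown unit is an error.
- The SpO₂ marker requires saturation `<90%` sustained for ≥60 minutes;
  the numeric comparison applies to the saturation value, and the duration
  requirement is part of the marker definition (the raw-lab CSV column is
  documented as the lowest saturation sustained for an hour).

Classification is the WHO definition: died → maternal death; survived
with ≥1 marker → maternal near miss; otherwise no life-threatening
condition. A death without any recorded marker is accepted (input data may
be incomplete) but triggers a validation warning, since every death in the
reference cohort presented at least one marker. The hysterectomy input
flag and the uterine marker denote the same condition, so either sets
both. Raw laboratory values only ever *add* markers; explicit marker
entries take precedence and are never removed.

## The MSI model

The MSI covariates are derived mechanically from a case record: x₁ is the
severity score counting **all** distinct markers (including those that also
drive the x₅/x₆/x₇ indicators — the published definition imposes no
exclusion); x₅ is any of {pH <7.1, continuous vasoactive drugs, cardiac
arrest, CPR}; x₆ is any of {gasping, PaO₂/FiO₂ <200, intubation/ventilation
not related to anesthesia}; x₂ (identified within the first 24 h of stay)
is interpreted as *any* marker identified early, since the source text
does not restrict it to the first marker; x₃ (severe pre-eclampsia) and x₄
(cancer) are input flags, not derivable from markers. Probabilities are
kept at full precision internally; display rounding happens only at the
reporting layer.

## Interval methods

Chosen to be the ones that reproduce the reference study's printed
intervals, and fixed package-wide:

| Quantity | Method |
|---|---|
| proportions (sensitivity, specificity, per-bin mortality) | Wilson score |
| likelihood ratios | Simel log method |
| relative risks | Katz log method |
| MMR | Wilson on the proportion (default); exact Garwood Poisson limits optional |
| O/E ratio | exact Poisson limits on observed deaths, expected as offset (SMR convention; a toolkit convention, labelled as such in output) |
| AUROC | DeLong |

The MMR default deserves a note: exact Poisson limits on 140 deaths give a
lower bound of 143.4 per 100,000, while the study prints 144; the Wilson
interval on the binomial proportion reproduces the printed 144–201
exactly, so it is the default, with `method="poisson"` available for the
classical rate convention.

Statistics whose stated method cannot produce a value (a likelihood ratio
with specificity 1, a relative risk with zero deaths in one arm, a
score-mortality correlation with zero outcome variance) are returned with
an explicit `note` flagging them as undefined — never as silent NaN.

## Model development

`fit_logistic` is maximum-likelihood logistic regression (statsmodels'
Newton/IRLS). Perfect or quasi-separation is *detected* — via solver
warnings, singular-Hessian failures (retried with BFGS so the diverging
fit can be inspected) or standardized coefficients exceeding 15 — and
flagged on the returned fit, not silently penalized away. Stepwise
selection is forward entry by likelihood-ratio test at p < 0.05 with
backward removal at p > 0.10 after each entry, a step cap guarding against
cycles; LR tests are used for both directions as the most reproducible
choice. The Hosmer–Lemeshow test sorts by predicted risk (stable sort,
ties broken by case order), splits into ten near-equal groups, uses
χ² = Σ (O−E)²/(E(1−E/n_g)) with df = groups − 2, and merges degenerate
groups (E = 0 or E = n_g) into a neighbour with a log message. Nagelkerke
R² is Cox–Snell rescaled by its maximum. The development/testing split is
seeded simple random sampling without outcome stratification, |A| =
round(0.8·n). The AUROC sample-size computation uses the Hanley–McNeil
variance; the negative:positive ratio is a **required** argument because no
universal default is defensible — published requirements depend on it
strongly and the reference study does not state the ratio it assumed.

## The synthetic-cohort generator

The generator emulates a referral-hospital surveillance cohort.
Defaults, all overridable in `SimulationConfig`:

- deliveries 82,388; complication rate 9,555/82,388; live-birth ratio
  82,144/82,388 (the reference denominators);
- per-marker prevalence among complicated women set to the published
  per-marker case counts divided by 9,555;
- marker co-occurrence via a single-factor latent threshold (probit)
  model: marker m present iff √ρ·z + √(1−ρ)·ε_m exceeds the threshold
  matching its marginal prevalence. One parameter ρ reproduces the heavy
  upper tail of the score distribution without inventing a 25×25
  correlation structure for which no data exist. ρ = 0.738, calibrated
  once by bisection so the simulated marker-free fraction among
  complicated women matches the published 8,645/9,555, then frozen. At
  that value the simulated severe-case count (~910 per 9,555) and the
  mean score among severe cases (3.21 vs 3.23) match the reference cohort
  and the simulated score distribution reproduces the published one
  qualitatively (heavier mid-range, comparable tail mass);
- deaths drawn as Bernoulli(MSI) under the configured coefficients —
  the generator uses the same model the scorer applies, which makes
  coefficient recovery and O/E calibration well-posed checks;
- flag rates: early identification 0.7, severe pre-eclampsia 0.4, cancer
  0.01, drawn independently of markers. These are toolkit assumptions for
  a referral setting, not published values.

What the generator deliberately does **not** emulate: referral dynamics
and delays in care, marker-specific death gradients beyond what the MSI
covariates carry (real per-marker relative risks vary more than a
score-plus-indicators model implies), dependence of the flags on severity,
and perinatal outcomes. Consequently, passing simulation tests demonstrate
that the *procedures* (classification, scoring, fitting, benchmarking) are
correct and internally consistent — not that the MSI coefficients are
correct for any new real population. Under the calibrated defaults a
study-sized cohort yields ~110 expected deaths versus the 140 observed in
the reference study; the gap reflects exactly those unmodelled features.

## Problem sizes in tests and the acceptance script

Parameter recovery refits the seven-covariate model on 100 independent
cohorts of ~8,000 severe cases (≈950 deaths each) and checks each
coefficient's Monte-Carlo mean within ±3 MC standard errors of its
generating value. O/E calibration uses 200 facility-sized cohorts
(~220 severe cases, ~24 expected deaths each); the mean O/E is within
±3 MC SE of 1. Because simulated deaths are Bernoulli — variance below the
Poisson variance the SMR interval assumes — the exact-Poisson O/E interval
is conservative, and the coverage check asserts *at least* nominal
coverage rather than a two-sided ≈95% band. AUROC is verified against an
O(n²) concordant-pair count at n ≤ 500, and Hosmer–Lemeshow p-values are
checked for approximate uniformity (KS at α = 0.01) over 200 replicates
simulated under the fitted model. These sizes give each check stable
verdicts at fixed seeds while the full suite stays fast.

## Known limitations

- The MSI reference population is women with ≥1 severity marker; by
  default benchmark reports score only those cases (an explicit toggle
  includes marker-free cases, whose model-implied death probability is
  logistic(−7.540) ≈ 5.3×10⁻⁴).
- The broader "pregnancy-related complications" membership has no
  operational definition here; it is an input (the complication rate in
  simulation, the file contents when reading data).
- Per-marker "per 1000 deliveries" prevalences are recomputed from counts
  and the deliveries denominator; reference publications' printed cells
  of that column are internally inconsistent by ~1% and are not
  reproduced.
- The toolkit deliberately implements no triage or clinical decision
  logic; reports carry a caveat that MSI estimates must not guide
  individual management.
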