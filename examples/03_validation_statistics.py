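"""Reconstruct the validation statistics of the WHO near-miss criteria
from the published cohort counts.

Uses the packaged counts of the 2012 multicenter Brazilian surveillance
study (82,388 deliveries; 9,555 complicated; 140 deaths; 770 near misses)
to recompute the criteria's diagnostic accuracy, two per-marker relative
risks, the severity-score mortality gradient and the maternal mortality
ratio.
"""

from msikit import (
    TwoByTwoTable,
    accuracy_stats,
    mmr,
    relative_risk,
    score_mortality_from_counts,
)
from msikit import reference

print("Accuracy of the WHO criteria (all women, deaths as gold standard):")
stats = accuracy_stats(TwoByTwoTable(140, 770, 0, 81478))
for name, est in stats.items():
    ci = f"({est.lo:.4g}-{est.hi:.4g})" if est.defined else "(CI n/a)"
    print(f"  {name:12s} {est.point:8.4g} {ci}")

print("\nPer-marker relative risk of death (among complicated women):")
for marker in ("shock", "intubation_ventilation"):
    d, s = reference.MARKER_DEATH_SURVIVOR[marker]
    du, su = reference.MARKER_UNEXPOSED_DEATHS[marker]
    rr = relative_risk(d, d + s, du, du + su)
    print(f"  {marker:24s} mortality {d / (d + s):6.2%}  "
          f"RR {rr.point:6.1f} ({rr.lo:.1f}-{rr.hi:.1f})")

print("\nSeverity score vs mortality:")
res = score_mortality_from_counts(
    [n for n, _ in reference.SCORE_DISTRIBUTION],
    [d for _, d in reference.SCORE_DISTRIBUTION],
)
for _, row in res.table.iloc[[0, 4, 8, 15]].iterrows():
    print(f"  score {row['bin']:>3s}: n={row['n']:5d}  "
          f"mortality {row['mortality']:6.1%} "
          f"({row['lo']:.1%}-{row['hi']:.1%})")
print(f"  Pearson r(score, mortality) = {res.pearson_r:.2f}")

est = mmr(reference.MATERNAL_DEATHS, reference.LIVE_BIRTHS)
print(f"\nMMR: {est.point:.0f} per 100,000 live births "
      f"({est.lo:.0f}-{est.hi:.0f})")

# The positive likelihood ratio ~107 means presenting any WHO marker
# raises the odds of death by two orders of magnitude: survivors of these
# conditions are valid proxies for maternal deaths (near misses).
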