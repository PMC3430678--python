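"""Diagnostic accuracy and descriptive epidemiology statistics.

Sensitivity/specificity with Wilson score intervals, likelihood ratios with
Simel log-method intervals, relative risks with Katz log-method intervals,
the maternal mortality ratio, and the severity-score-by-mortality table with
its Pearson correlation.  Interval methods are the ones that reproduce the
published intervals of the validation study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .markers import CATALOG, CaseRecord, severity_score

__all__ = [
    "TwoByTwoTable",
    "IntervalEstimate",
    "accuracy_stats",
    "relative_risk",
    "proportion_ci",
    "mmr",
    "ScoreMortalityResult",
    "score_mortality_from_counts",
    "score_mortality_table",
    "marker_table",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class IntervalEstimate:
    """A point estimate with a two-sided confidence interval.

    When the interval (or the point) is not computable by the stated method
    the estimate is explicitly flagged via ``note`` and the undefined
    members are NaN -- never silently propagated.
    """

    point: float
    lo: float
    hi: float
    level: float = 0.95
    method: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not self.note and np.isfinite([self.point, self.lo, self.hi]).all():
            if not (self.lo <= self.point <= self.hi):
                raise ValueError(
                    f"invalid interval: lo={self.lo} point={self.point} "
                    f"hi={self.hi}"
                )

    @property
    def defined(self) -> bool:
        return not self.note


@dataclass(frozen=True)
class TwoByTwoTable:
    """Deaths (columns) by criterion positivity (rows): tp, fp, fn, tn."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("2x2 table is empty")

    @classmethod
    def from_cases(
        cls, positive: Iterable[bool], died: Iterable[bool]
    ) -> "TwoByTwoTable":
        tp = fp = fn = tn = 0
        for pos, d in zip(positive, died):
            if pos and d:
                tp += 1
            elif pos:
                fp += 1
            elif d:
                fn += 1
            else:
                tn += 1
        return cls(tp, fp, fn, tn)


def proportion_ci(k: int, n: int, level: float = 0.95) -> IntervalEstimate:
    """Binomial proportion with a Wilson score interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    alpha = 1.0 - level
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    point = k / n
    # the Wilson interval contains the point and lies in [0,1] by
    # construction; guard against float rounding at the boundaries
    lo = min(max(float(lo), 0.0), point)
    hi = max(min(float(hi), 1.0), point)
    return IntervalEstimate(point, lo, hi, level, "wilson")


def _lr_interval(
    point: float, var_log: float, level: float, which: str
) -> IntervalEstimate:
    z = stats.norm.ppf(0.5 + level / 2)
    if point == 0.0:
        return IntervalEstimate(
            0.0, float("nan"), float("nan"), level, "simel-log",
            note=f"{which} is 0; log-method CI not computable",
        )
    if not math.isfinite(point) or var_log < 0:
        return IntervalEstimate(
            point, float("nan"), float("nan"), level, "simel-log",
            note=f"{which} CI not computable by the log method",
        )
    half = z * math.sqrt(var_log)
    return IntervalEstimate(
        point, point * math.exp(-half), point * math.exp(half), level,
        "simel-log",
    )


def accuracy_stats(
    t: TwoByTwoTable, level: float = 0.95
) -> dict[str, IntervalEstimate]:
    """Sensitivity, specificity and likelihood ratios for a 2x2 table.

    Sensitivity/specificity carry Wilson intervals; the likelihood ratios
    carry Simel log-method intervals
    (var ln PLR = 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn), and symmetrically
    for the NLR).  A ratio with a zero denominator (e.g. PLR when
    specificity is 1) is flagged undefined rather than returned as NaN.
    """
    tp, fp, fn, tn = t.tp, t.fp, t.fn, t.tn
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("both diseased and non-diseased totals must be > 0")
    sens = proportion_ci(tp, tp + fn, level)
    spec = proportion_ci(tn, tn + fp, level)

    # positive likelihood ratio = sens / (1 - spec)
    if fp == 0:
        plr = IntervalEstimate(
            float("inf"), float("nan"), float("nan"), level, "simel-log",
            note="PLR undefined: specificity = 1 (no false positives)",
        )
    else:
        point = (tp / (tp + fn)) / (fp / (fp + tn))
        var = 0.0
        var += (1 / tp - 1 / (tp + fn)) if tp > 0 else float("inf")
        var += 1 / fp - 1 / (fp + tn)
        plr = _lr_interval(point, var, level, "PLR")

    # negative likelihood ratio = (1 - sens) / spec
    if tn == 0:
        nlr = IntervalEstimate(
            float("inf"), float("nan"), float("nan"), level, "simel-log",
            note="NLR undefined: specificity = 0 (no true negatives)",
        )
    elif fn == 0:
        nlr = IntervalEstimate(
            0.0, float("nan"), float("nan"), level, "simel-log",
            note="NLR is 0 (perfect sensitivity); log-method CI not"
                 " computable",
        )
    else:
        point = (fn / (tp + fn)) / (tn / (fp + tn))
        var = (1 / fn - 1 / (tp + fn)) + (1 / tn - 1 / (fp + tn))
        nlr = _lr_interval(point, var, level, "NLR")

    return {"sensitivity": sens, "specificity": spec, "plr": plr, "nlr": nlr}


def relative_risk(
    exposed_deaths: int,
    exposed_total: int,
    unexposed_deaths: int,
    unexposed_total: int,
    level: float = 0.95,
) -> IntervalEstimate:
    """Crude relative risk with Katz log-method confidence interval.

    CI = exp(ln RR +/- z * sqrt(1/a - 1/n1 + 1/c - 1/n0)).  Zero deaths in
    either arm make the log method non-computable; the point estimate (0 or
    inf) is returned with an explanatory note.
    """
    a, n1, c, n0 = exposed_deaths, exposed_total, unexposed_deaths, unexposed_total
    if n1 <= 0 or n0 <= 0:
        raise ValueError("group totals must be positive")
    if not (0 <= a <= n1 and 0 <= c <= n0):
        raise ValueError("deaths cannot exceed group totals")
    z = stats.norm.ppf(0.5 + level / 2)
    if a == 0 or c == 0:
        point = 0.0 if a == 0 else float("inf")
        return IntervalEstimate(
            point, float("nan"), float("nan"), level, "katz-log",
            note="zero deaths in one arm; log-method CI not computable",
        )
    rr = (a / n1) / (c / n0)
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return IntervalEstimate(
        rr, rr * math.exp(-z * se), rr * math.exp(z * se), level, "katz-log"
    )


def mmr(
    deaths: int,
    live_births: int,
    level: float = 0.95,
    method: str = "wilson",
) -> IntervalEstimate:
    """Maternal mortality ratio per 100,000 live births.

    ``method="wilson"`` (default) treats deaths/live-births as a binomial
    proportion with a Wilson score interval, which reproduces the published
    interval of the validation study; ``method="poisson"`` gives classical
    exact (Garwood) Poisson limits on the death count scaled by the
    denominator.
    """
    if live_births <= 0:
        raise ValueError("live_births must be positive")
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    scale = 1e5 / live_births
    point = deaths * scale
    alpha = 1.0 - level
    if method == "wilson":
        est = proportion_ci(deaths, live_births, level)
        lo, hi = est.lo * 1e5, est.hi * 1e5
    elif method == "poisson":
        lo = 0.0 if deaths == 0 else stats.chi2.ppf(alpha / 2, 2 * deaths) / 2 * scale
        hi = stats.chi2.ppf(1 - alpha / 2, 2 * (deaths + 1)) / 2 * scale
    else:
        raise ValueError(f"unknown method {method!r}")
    return IntervalEstimate(point, lo, hi, level, f"mmr-{method}")


@dataclass
class ScoreMortalityResult:
    """Severity-score bins with per-bin mortality and the score-mortality
    Pearson correlation (open top bin coded at the cap)."""

    table: pd.DataFrame
    pearson_r: float | None
    note: str = ""


def score_mortality_from_counts(
    n_per_bin: Sequence[int],
    deaths_per_bin: Sequence[int],
    cap: int = 15,
    level: float = 0.95,
) -> ScoreMortalityResult:
    """Score-by-mortality table from per-bin counts.

    ``n_per_bin``/``deaths_per_bin`` cover scores 0..cap-1 plus the open
    ``cap+`` bin (length cap+1).  The Pearson correlation is computed over
    non-empty bins between the score value (open bin coded = cap) and the
    bin mortality proportion; it is flagged undefined when mortality has
    zero variance.
    """
    if len(n_per_bin) != cap + 1 or len(deaths_per_bin) != cap + 1:
        raise ValueError(f"expected {cap + 1} bins (0..{cap - 1} and {cap}+)")
    rows = []
    for score, (n, d) in enumerate(zip(n_per_bin, deaths_per_bin)):
        label = f"{cap}+" if score == cap else str(score)
        if n > 0:
            est = proportion_ci(d, n, level)
            rows.append((label, score, n, d, est.point, est.lo, est.hi))
        else:
            rows.append((label, score, 0, 0, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows,
        columns=["bin", "score_value", "n", "deaths", "mortality", "lo", "hi"],
    )
    filled = table.dropna(subset=["mortality"])
    note = ""
    if len(filled) < 2 or filled["mortality"].nunique() == 1:
        r: float | None = None
        note = "correlation undefined: mortality has zero variance"
    elif filled["score_value"].nunique() == 1:
        r = None
        note = "correlation undefined: only one non-empty score bin"
    else:
        r = float(
            np.corrcoef(filled["score_value"], filled["mortality"])[0, 1]
        )
    return ScoreMortalityResult(table, r, note)


def score_mortality_table(
    cohort: Sequence[CaseRecord], cap: int = 15, level: float = 0.95
) -> ScoreMortalityResult:
    """Bin a cohort by maternal severity score and tabulate mortality."""
    if not cohort:
        raise ValueError("cohort is empty")
    n = [0] * (cap + 1)
    d = [0] * (cap + 1)
    for case in cohort:
        b = min(severity_score(case), cap)
        n[b] += 1
        d[b] += int(case.died)
    return score_mortality_from_counts(n, d, cap=cap, level=level)


def marker_table(
    cohort: Sequence[CaseRecord],
    deliveries: int,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-marker deaths, survivors, prevalence and relative risk.

    One row per catalog marker.  Prevalence is cases presenting the marker
    per 1000 deliveries; the relative risk compares mortality in cases with
    the marker against cases (within the cohort) lacking it.  Markers with
    zero cases get empty statistics rather than being dropped.
    """
    if deliveries <= 0:
        raise ValueError("deliveries must be positive")
    total = len(cohort)
    total_deaths = sum(int(c.died) for c in cohort)
    rows = []
    for m in CATALOG:
        d = sum(1 for c in cohort if m.marker_id in c.markers_present and c.died)
        s = sum(
            1 for c in cohort if m.marker_id in c.markers_present and not c.died
        )
        n_with = d + s
        n_without = total - n_with
        row: dict[str, object] = {
            "marker_id": m.marker_id,
            "label": m.label,
            "deaths": d,
            "survivors": s,
            "prevalence_per_1000_deliveries": n_with / deliveries * 1000,
        }
        if n_with == 0:
            row.update(
                mortality_pct=np.nan, rr=np.nan, rr_lo=np.nan, rr_hi=np.nan,
                rr_note="no cases present this marker",
            )
        elif n_without == 0:
            row.update(
                mortality_pct=d / n_with * 100,
                rr=np.nan, rr_lo=np.nan, rr_hi=np.nan,
                rr_note="no comparison cases without this marker",
            )
        else:
            rr = relative_risk(
                d, n_with, total_deaths - d, n_without, level=level
            )
            row.update(
                mortality_pct=d / n_with * 100,
                rr=rr.point, rr_lo=rr.lo, rr_hi=rr.hi, rr_note=rr.note,
            )
        rows.append(row)
    return pd.DataFrame(rows)
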