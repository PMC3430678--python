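"""Observed-vs-expected mortality benchmarking with the MSI.

The mean MSI of a cohort estimates the expected number of maternal deaths
(sum of per-case death probabilities); comparing observed deaths to this
expectation (the O/E ratio, the classical indirect-standardization
convention with exact Poisson limits on the observed count) benchmarks the
management of severe maternal morbidity against the standard of care of the
reference population that produced the coefficients.

By default only cases with at least one severity marker are scored: the MSI
reference population is women with life-threatening conditions.  Marker-free
cases are counted separately and can be included explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .epi import IntervalEstimate
from .markers import CaseRecord, severity_score
from .msi import DEFAULT_COEFFICIENTS, MsiCoefficients, msi_batch

__all__ = [
    "CohortBenchmarkReport",
    "StratifiedBenchmark",
    "expected_deaths",
    "oe_ratio",
    "benchmark_cohort",
    "compare_strata",
]


@dataclass
class CohortBenchmarkReport:
    """Severity and mortality summary for one cohort (or stratum)."""

    label: str
    n_cases: int
    n_scored: int
    n_marker_free: int
    mean_severity_score: float
    mean_msi: float
    expected_deaths: float
    observed_deaths: int
    oe: IntervalEstimate | None

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n_cases": self.n_cases,
            "n_scored": self.n_scored,
            "n_marker_free": self.n_marker_free,
            "mean_severity_score": self.mean_severity_score,
            "mean_msi": self.mean_msi,
            "expected_deaths": self.expected_deaths,
            "observed_deaths": self.observed_deaths,
        }
        if self.oe is not None:
            d["oe_ratio"] = self.oe.point
            d["oe_lo"] = self.oe.lo
            d["oe_hi"] = self.oe.hi
            d["oe_note"] = self.oe.note
        else:
            d["oe_ratio"] = None
            d["oe_note"] = "no scored cases"
        return d


@dataclass
class StratifiedBenchmark:
    """Per-stratum benchmark reports plus the pooled report."""

    strata: dict[str, CohortBenchmarkReport]
    pooled: CohortBenchmarkReport


def _scored(cohort: Sequence[CaseRecord], include_marker_free: bool):
    if include_marker_free:
        return list(cohort)
    return [c for c in cohort if c.markers_present]


def expected_deaths(
    cohort: Sequence[CaseRecord],
    coef: MsiCoefficients = DEFAULT_COEFFICIENTS,
    include_marker_free: bool = False,
) -> float:
    """Expected number of deaths: the sum of per-case MSI values."""
    if not cohort:
        raise ValueError("cohort is empty")
    return float(sum(msi_batch(_scored(cohort, include_marker_free), coef)))


def oe_ratio(
    observed: int, expected: float, level: float = 0.95
) -> IntervalEstimate:
    """Observed/expected mortality ratio with exact Poisson limits.

    Observed deaths are treated as Poisson with the expected count as
    offset (the classical standardized-mortality-ratio convention; the
    interval method is this toolkit's convention, not taken from the
    reference study).
    """
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if expected <= 0:
        if observed > 0:
            return IntervalEstimate(
                float("inf"), float("nan"), float("nan"), level, "smr-poisson",
                note="expected deaths is 0 with observed > 0; not comparable",
            )
        raise ValueError("expected deaths must be positive")
    alpha = 1.0 - level
    lo_count = (
        0.0 if observed == 0 else stats.chi2.ppf(alpha / 2, 2 * observed) / 2
    )
    hi_count = stats.chi2.ppf(1 - alpha / 2, 2 * (observed + 1)) / 2
    return IntervalEstimate(
        observed / expected, lo_count / expected, hi_count / expected, level,
        "smr-poisson",
    )


def benchmark_cohort(
    cohort: Sequence[CaseRecord],
    coef: MsiCoefficients = DEFAULT_COEFFICIENTS,
    label: str = "cohort",
    include_marker_free: bool = False,
    level: float = 0.95,
) -> CohortBenchmarkReport:
    """Severity summary, expected deaths and O/E ratio for one cohort."""
    scored = _scored(cohort, include_marker_free)
    n_marker_free = sum(1 for c in cohort if not c.markers_present)
    observed = sum(int(c.died) for c in scored)
    if not scored:
        return CohortBenchmarkReport(
            label=label,
            n_cases=len(cohort),
            n_scored=0,
            n_marker_free=n_marker_free,
            mean_severity_score=0.0,
            mean_msi=float("nan"),
            expected_deaths=0.0,
            observed_deaths=observed,
            oe=None,
        )
    probs = msi_batch(scored, coef)
    expected = float(sum(probs))
    return CohortBenchmarkReport(
        label=label,
        n_cases=len(cohort),
        n_scored=len(scored),
        n_marker_free=n_marker_free,
        mean_severity_score=sum(severity_score(c) for c in scored)
        / len(scored),
        mean_msi=expected / len(scored),
        expected_deaths=expected,
        observed_deaths=observed,
        oe=oe_ratio(observed, expected, level) if expected > 0 else None,
    )


def compare_strata(
    cohort: Sequence[CaseRecord],
    coef: MsiCoefficients = DEFAULT_COEFFICIENTS,
    include_marker_free: bool = False,
    level: float = 0.95,
) -> StratifiedBenchmark:
    """One benchmark report per stratum label plus the pooled cohort.

    Cases with ``stratum=None`` go to the stratum ``"(unlabelled)"``.
    Strata with zero scored (severe) cases are reported as empty, never
    dropped silently.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    groups: dict[str, list[CaseRecord]] = {}
    for c in cohort:
        groups.setdefault(c.stratum or "(unlabelled)", []).append(c)
    strata = {
        label: benchmark_cohort(
            cases, coef, label=label,
            include_marker_free=include_marker_free, level=level,
        )
        for label, cases in sorted(groups.items())
    }
    pooled = benchmark_cohort(
        cohort, coef, label="pooled",
        include_marker_free=include_marker_free, level=level,
    )
    return StratifiedBenchmark(strata=strata, pooled=pooled)
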