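"""The Maternal Severity Index (MSI): published-coefficient death-probability model.

The MSI is the estimated probability of maternal death among women with
pregnancy-related life-threatening conditions, from a logistic model

    logit = b0 + b1*x1 + b2*x2 + ... + b7*x7,   MSI = e^logit / (1 + e^logit)

where x1 is the maternal severity score (number of WHO markers present) and
x2..x7 are binary indicators: life-threatening condition identified within
the first 24 h of hospital stay, severe pre-eclampsia, cancer, any marker of
cardiovascular failure (pH <7.1, continuous vasoactive drugs, cardiac
arrest, CPR), any marker of respiratory failure (gasping, PaO2/FiO2 <200,
intubation/ventilation not related to anesthesia), and hysterectomy.

The default coefficient set ("brazil2012") is the model developed in the
2012 multicenter Brazilian validation study of the WHO near-miss criteria.
MSI estimates describe groups of women with similar severity; they must not
be used to guide the management of an individual patient.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

from .markers import (
    CARDIOVASCULAR_FAILURE_MARKERS,
    RESPIRATORY_FAILURE_MARKERS,
    CaseRecord,
    severity_score,
)

__all__ = [
    "MsiCoefficients",
    "MsiCovariates",
    "BRAZIL2012",
    "DEFAULT_COEFFICIENTS",
    "derive_covariates",
    "msi",
    "msi_batch",
]


@dataclass(frozen=True)
class MsiCoefficients:
    """Constant and covariate coefficients of the MSI logistic model."""

    beta0: float
    beta1: float  # per additional severity marker
    beta2: float  # identified in first 24 h of stay
    beta3: float  # severe pre-eclampsia
    beta4: float  # cancer
    beta5: float  # any cardiovascular-failure marker
    beta6: float  # any respiratory-failure marker
    beta7: float  # hysterectomy
    name: str = "custom"

    def as_vector(self) -> tuple[float, ...]:
        return (self.beta0, self.beta1, self.beta2, self.beta3, self.beta4,
                self.beta5, self.beta6, self.beta7)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MsiCoefficients":
        payload = json.loads(text)
        return cls(**payload)


#: The published coefficient set of the 2012 Brazilian validation study.
BRAZIL2012 = MsiCoefficients(
    beta0=-7.540,
    beta1=0.309,
    beta2=0.287,
    beta3=-0.579,
    beta4=3.492,
    beta5=4.209,
    beta6=1.513,
    beta7=-1.169,
    name="brazil2012",
)

DEFAULT_COEFFICIENTS = BRAZIL2012

COEFFICIENT_SETS = {"brazil2012": BRAZIL2012}


@dataclass(frozen=True)
class MsiCovariates:
    """The covariate vector (x1..x7) entering the MSI logit."""

    x1: int
    x2: int
    x3: int
    x4: int
    x5: int
    x6: int
    x7: int

    def as_vector(self) -> tuple[int, ...]:
        return (self.x1, self.x2, self.x3, self.x4, self.x5, self.x6, self.x7)


def derive_covariates(case: CaseRecord) -> MsiCovariates:
    """Derive the MSI covariates from a case record.

    x1 counts all distinct markers (including those that also drive the
    x5/x6/x7 indicators); x2 is true when any life-threatening condition was
    identified within the first 24 h of hospital stay.
    """
    markers = set(case.markers_present)
    return MsiCovariates(
        x1=severity_score(case),
        x2=int(case.early_identification),
        x3=int(case.severe_preeclampsia),
        x4=int(case.cancer),
        x5=int(bool(markers & CARDIOVASCULAR_FAILURE_MARKERS)),
        x6=int(bool(markers & RESPIRATORY_FAILURE_MARKERS)),
        x7=int(case.hysterectomy),
    )


def msi_from_covariates(
    cov: MsiCovariates, coef: MsiCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Evaluate the MSI logistic formula on an explicit covariate vector."""
    logit = coef.beta0 + sum(
        b * x for b, x in zip(coef.as_vector()[1:], cov.as_vector())
    )
    return 1.0 / (1.0 + math.exp(-logit))


def msi(case: CaseRecord, coef: MsiCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Estimated death probability for one case; always in (0, 1)."""
    return msi_from_covariates(derive_covariates(case), coef)


def msi_batch(
    cohort: Sequence[CaseRecord] | Iterable[CaseRecord],
    coef: MsiCoefficients = DEFAULT_COEFFICIENTS,
) -> list[float]:
    """Element-wise MSI over a cohort, order preserved.

    Per-record failures are re-raised with the case id for context.
    """
    out: list[float] = []
    for case in cohort:
        try:
            out.append(msi(case, coef))
        except Exception as exc:  # pragma: no cover - defensive context
            raise type(exc)(f"case {case.case_id!r}: {exc}") from exc
    return out
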