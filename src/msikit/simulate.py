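"""Synthetic delivery-cohort generator.

Emulates a referral-hospital surveillance cohort: of ``n_deliveries``
admissions, a fraction develops pregnancy-related complications; each
complicated woman draws a latent severity factor z ~ N(0,1) and presents
marker m iff sqrt(rho)*z + sqrt(1-rho)*eps_m exceeds the marker-specific
threshold calibrated to its target prevalence (a single-factor probit
model, so one parameter rho controls all marker co-occurrence and the heavy
upper tail of the severity-score distribution).  Death is drawn as
Bernoulli(MSI) under the configured coefficient set, which makes parameter
recovery and O/E calibration well-posed checks.

``calibrated_config`` packages the configuration whose marker prevalences
match the published per-marker counts of the 2012 Brazilian validation
cohort and whose rho was calibrated once (by bisection) so the simulated
fraction of marker-free complicated women matches the published 8645/9555.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import reference
from .markers import (
    CARDIOVASCULAR_FAILURE_MARKERS,
    HYSTERECTOMY_MARKER,
    MARKER_IDS,
    RESPIRATORY_FAILURE_MARKERS,
    CaseRecord,
)
from .msi import BRAZIL2012, MsiCoefficients

__all__ = [
    "SimulationConfig",
    "CohortDenominators",
    "generate_cohort",
    "simulate_msi_design",
    "calibrated_config",
    "CALIBRATED_RHO",
]

#: Latent-factor correlation frozen by the packaged calibration run
#: (bisection on the marker-free fraction among complicated women).
CALIBRATED_RHO = 0.738


@dataclass
class CohortDenominators:
    deliveries: int
    live_births: int
    complicated: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SimulationConfig:
    """Generator settings; the seed is mandatory for reproducibility."""

    seed: int
    n_deliveries: int = reference.DELIVERIES
    complication_rate: float = reference.COMPLICATED / reference.DELIVERIES
    marker_prevalence: dict[str, float] = field(
        default_factory=reference.marker_prevalence_among_complicated
    )
    rho: float = CALIBRATED_RHO
    coefficients: MsiCoefficients = BRAZIL2012
    early_identification_rate: float = 0.7
    severe_preeclampsia_rate: float = 0.4
    cancer_rate: float = 0.01
    live_birth_ratio: float = reference.LIVE_BIRTHS / reference.DELIVERIES
    #: rho is an invention of the generator: the source study publishes no
    #: joint marker distribution, only per-marker margins.
    rho_provenance: str = "calibrated to the published score-0 fraction"

    def validate(self) -> None:
        if self.n_deliveries <= 0:
            raise ValueError("n_deliveries must be positive")
        for name in (
            "complication_rate",
            "early_identification_rate",
            "severe_preeclampsia_rate",
            "cancer_rate",
            "live_birth_ratio",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(
                f"rho={self.rho} infeasible: need 0 <= rho < 1 for the"
                " single-factor model"
            )
        unknown = set(self.marker_prevalence) - MARKER_IDS
        if unknown:
            raise ValueError(f"unknown markers in prevalence: {sorted(unknown)}")
        for m, p in self.marker_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {m} outside [0, 1]: {p}")

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        payload = json.loads(text)
        if isinstance(payload.get("coefficients"), dict):
            payload["coefficients"] = MsiCoefficients(**payload["coefficients"])
        return cls(**payload)


def calibrated_config(seed: int, n_deliveries: int = reference.DELIVERIES) -> SimulationConfig:
    """The packaged configuration calibrated to the reference cohort."""
    return SimulationConfig(seed=seed, n_deliveries=n_deliveries)


def _draw_arrays(config: SimulationConfig):
    """Vectorized draw of one cohort: marker matrix, flags, deaths.

    Returns ``(markers, present, x2, x3, x4, died, denom)`` where
    ``markers`` is the sorted marker-id list and ``present`` the boolean
    case-by-marker matrix over complicated women.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    markers = sorted(config.marker_prevalence)
    prev = np.array([config.marker_prevalence[m] for m in markers])

    n_compl = int(rng.binomial(config.n_deliveries, config.complication_rate))
    denom = CohortDenominators(
        deliveries=config.n_deliveries,
        live_births=int(round(config.n_deliveries * config.live_birth_ratio)),
        complicated=n_compl,
    )
    if n_compl == 0:
        empty = np.zeros((0, len(markers)), dtype=bool)
        zb = np.zeros(0, dtype=bool)
        return markers, empty, zb, zb, zb, zb, denom

    with np.errstate(divide="ignore"):
        tau = stats.norm.ppf(1.0 - prev)  # prev=0 -> +inf, never present
    z = rng.standard_normal(n_compl)
    eps = rng.standard_normal((n_compl, len(markers)))
    present = (
        np.sqrt(config.rho) * z[:, None] + np.sqrt(1.0 - config.rho) * eps
        > tau[None, :]
    )

    x2 = rng.random(n_compl) < config.early_identification_rate
    x3 = rng.random(n_compl) < config.severe_preeclampsia_rate
    x4 = rng.random(n_compl) < config.cancer_rate

    idx = {m: j for j, m in enumerate(markers)}
    cv_cols = [idx[m] for m in sorted(CARDIOVASCULAR_FAILURE_MARKERS) if m in idx]
    resp_cols = [idx[m] for m in sorted(RESPIRATORY_FAILURE_MARKERS) if m in idx]
    hyst_col = idx.get(HYSTERECTOMY_MARKER)

    score = present.sum(axis=1)
    cv = present[:, cv_cols].any(axis=1) if cv_cols else np.zeros(n_compl, bool)
    resp = (
        present[:, resp_cols].any(axis=1) if resp_cols
        else np.zeros(n_compl, bool)
    )
    hyst = (
        present[:, hyst_col] if hyst_col is not None
        else np.zeros(n_compl, bool)
    )
    c = config.coefficients
    logit = (
        c.beta0
        + c.beta1 * score
        + c.beta2 * x2
        + c.beta3 * x3
        + c.beta4 * x4
        + c.beta5 * cv
        + c.beta6 * resp
        + c.beta7 * hyst
    )
    p_death = 1.0 / (1.0 + np.exp(-logit))
    died = rng.random(n_compl) < p_death
    return markers, present, x2, x3, x4, died, denom


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[CaseRecord], CohortDenominators]:
    """Generate one synthetic cohort; deterministic given the config seed.

    Returns the list of complicated-case records (marker-free complicated
    women included, with empty marker sets) plus the cohort denominators.
    Uncomplicated deliveries contribute only to the denominators.
    """
    markers, present, x2, x3, x4, died, denom = _draw_arrays(config)
    n_compl = denom.complicated
    hyst_col = (
        markers.index(HYSTERECTOMY_MARKER)
        if HYSTERECTOMY_MARKER in markers
        else None
    )
    marker_arr = np.array(markers)
    cohort = [
        CaseRecord(
            case_id=f"case{i:06d}",
            markers_present=set(marker_arr[present[i]]),
            early_identification=bool(x2[i]),
            severe_preeclampsia=bool(x3[i]),
            cancer=bool(x4[i]),
            hysterectomy=(
                bool(present[i, hyst_col]) if hyst_col is not None else False
            ),
            died=bool(died[i]),
        )
        for i in range(n_compl)
    ]
    return cohort, denom


def simulate_msi_design(config: SimulationConfig):
    """Severe-case (>=1 marker) MSI design matrix and death outcomes.

    A vectorized shortcut for model re-derivation studies: returns
    ``(X, y)`` where ``X`` is a DataFrame with columns x1..x7 and ``y`` the
    0/1 death indicator, restricted to women with at least one marker.
    Identical in distribution to deriving covariates from
    :func:`generate_cohort` records, and identical draw-for-draw at the
    same seed.
    """
    import pandas as pd

    markers, present, x2, x3, x4, died, _ = _draw_arrays(config)
    idx = {m: j for j, m in enumerate(markers)}
    cv_cols = [idx[m] for m in sorted(CARDIOVASCULAR_FAILURE_MARKERS) if m in idx]
    resp_cols = [idx[m] for m in sorted(RESPIRATORY_FAILURE_MARKERS) if m in idx]
    score = present.sum(axis=1)
    severe = score > 0
    X = pd.DataFrame(
        {
            "x1": score[severe].astype(int),
            "x2": x2[severe].astype(int),
            "x3": x3[severe].astype(int),
            "x4": x4[severe].astype(int),
            "x5": present[severe][:, cv_cols].any(axis=1).astype(int)
            if cv_cols
            else 0,
            "x6": present[severe][:, resp_cols].any(axis=1).astype(int)
            if resp_cols
            else 0,
            "x7": present[severe][:, idx[HYSTERECTOMY_MARKER]].astype(int)
            if HYSTERECTOMY_MARKER in idx
            else 0,
        }
    )
    return X, died[severe].astype(int)
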