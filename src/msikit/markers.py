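"""WHO severity-marker catalog and case-level classification.

The WHO maternal near-miss approach defines 25 clinical, laboratory and
management-based markers of life-threatening organ dysfunction during
pregnancy, childbirth or the postpartum period.  A woman who presents at
least one marker and survives is a *maternal near miss*; one who dies is a
*maternal death*; the number of distinct markers present is her *maternal
severity score*.

Markers are grouped per organ system into group A and group B, where group B
reflects greater severity (SOFA score categories 3 and 4).
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

__all__ = [
    "SeverityMarker",
    "CaseRecord",
    "CaseCategory",
    "CATALOG",
    "MARKER_IDS",
    "ORGAN_SYSTEMS",
    "GROUP_B_MARKERS",
    "CARDIOVASCULAR_FAILURE_MARKERS",
    "RESPIRATORY_FAILURE_MARKERS",
    "HYSTERECTOMY_MARKER",
    "LAB_MARKER_MAP",
    "evaluate_lab_marker",
    "classify_case",
    "severity_score",
    "organ_dysfunction_profile",
    "catalog_to_json",
]

ORGAN_SYSTEMS = (
    "cardiovascular",
    "respiratory",
    "renal",
    "coagulation/hematological",
    "hepatic",
    "neurological",
    "uterine",
)


@dataclass(frozen=True)
class SeverityMarker:
    """One of the 25 WHO life-threatening-condition markers.

    ``threshold`` maps a recognized unit string to a tuple of
    ``(direction, cutoff)`` clauses combined with OR; ``direction`` is one of
    ``"<"``, ``">"``, ``">="`` with the strictness exactly as published.
    """

    marker_id: str
    label: str
    organ_system: str
    group: str  # "A" or "B"
    kind: str  # clinical_sign | lab_threshold | management_proxy
    threshold: dict[str, tuple[tuple[str, float], ...]] | None = None


def _m(marker_id, label, organ, group, kind, threshold=None):
    return SeverityMarker(marker_id, label, organ, group, kind, threshold)


# The catalog, per organ system.  Lab cutoffs keep the published numbers per
# unit scale; creatinine/bilirubin SI cutoffs (300, 100) are stored under
# umol/l -- the printed "mmol/l" magnitudes are only physiologically coherent
# as micromoles per litre, and "mmol/l" is accepted as an alias of the same
# printed cutoff.
CATALOG: tuple[SeverityMarker, ...] = (
    # cardiovascular dysfunction
    _m("shock", "Shock", "cardiovascular", "A", "clinical_sign"),
    _m("lactate_high", "Lactate >5 mmol/l", "cardiovascular", "A",
       "lab_threshold", {"mmol/l": ((">", 5.0),)}),
    _m("ph_low", "pH <7.1", "cardiovascular", "B",
       "lab_threshold", {"": (("<", 7.1),)}),
    _m("vasoactive_drugs", "Use of continuous vasoactive drugs",
       "cardiovascular", "B", "management_proxy"),
    _m("cardiac_arrest", "Cardiac arrest", "cardiovascular", "B",
       "clinical_sign"),
    _m("cpr", "Cardio-pulmonary resuscitation (CPR)", "cardiovascular", "B",
       "management_proxy"),
    # respiratory dysfunction
    _m("acute_cyanosis", "Acute cyanosis", "respiratory", "A",
       "clinical_sign"),
    _m("resp_rate_abnormal", "Respiratory rate >40 or <6/min", "respiratory",
       "A", "lab_threshold", {"/min": ((">", 40.0), ("<", 6.0))}),
    _m("spo2_low", "Oxygen saturation <90% for >=60 minutes", "respiratory",
       "A", "lab_threshold", {"%": (("<", 90.0),)}),
    _m("gasping", "Gasping", "respiratory", "B", "clinical_sign"),
    _m("pao2_fio2_low", "PaO2/FiO2 <200 mmHg", "respiratory", "B",
       "lab_threshold", {"mmhg": (("<", 200.0),)}),
    _m("intubation_ventilation",
       "Intubation and ventilation not related to anesthesia", "respiratory",
       "B", "management_proxy"),
    # renal dysfunction
    _m("oliguria", "Oliguria non responsive to fluids or diuretics", "renal",
       "A", "clinical_sign"),
    _m("creatinine_high", "Creatinine >=300 umol/l or >=3.5 mg/dl", "renal",
       "B", "lab_threshold",
       {"umol/l": ((">=", 300.0),), "mmol/l": ((">=", 300.0),),
        "mg/dl": ((">=", 3.5),)}),
    _m("dialysis", "Dialysis for acute renal failure", "renal", "B",
       "management_proxy"),
    # coagulation / hematological dysfunction
    _m("clotting_failure", "Clotting failure", "coagulation/hematological",
       "A", "clinical_sign"),
    _m("transfusion_5plus", "Transfusion of >=5 units of blood/red cells",
       "coagulation/hematological", "A", "management_proxy"),
    _m("thrombocytopenia", "Acute thrombocytopenia (<50 000 platelets)",
       "coagulation/hematological", "B", "lab_threshold",
       {"per-ul": (("<", 50000.0),), "10^9/l": (("<", 50.0),)}),
    # hepatic dysfunction
    _m("jaundice_preeclampsia", "Jaundice in the presence of pre-eclampsia",
       "hepatic", "A", "clinical_sign"),
    _m("bilirubin_high", "Bilirubin >100 umol/l or >6.0 mg/dl", "hepatic",
       "B", "lab_threshold",
       {"umol/l": ((">", 100.0),), "mmol/l": ((">", 100.0),),
        "mg/dl": ((">", 6.0),)}),
    # neurological dysfunction
    _m("metabolic_coma",
       "Metabolic coma (loss of consciousness with glucose and ketoacids in"
       " urine)", "neurological", "A", "clinical_sign"),
    _m("stroke", "Stroke", "neurological", "A", "clinical_sign"),
    _m("status_epilepticus",
       "Status epilepticus / uncontrollable fits / total paralysis",
       "neurological", "A", "clinical_sign"),
    _m("prolonged_unconsciousness",
       "Coma / loss of consciousness lasting 12 hours or more",
       "neurological", "B", "clinical_sign"),
    # uterine dysfunction
    _m("hysterectomy", "Hysterectomy due to infection or hemorrhage",
       "uterine", "A", "management_proxy"),
)

MARKER_IDS: frozenset[str] = frozenset(m.marker_id for m in CATALOG)
_BY_ID: dict[str, SeverityMarker] = {m.marker_id: m for m in CATALOG}
GROUP_B_MARKERS: frozenset[str] = frozenset(
    m.marker_id for m in CATALOG if m.group == "B"
)

# MSI indicator groups: the group-B cardiovascular / respiratory markers.
CARDIOVASCULAR_FAILURE_MARKERS = frozenset(
    {"ph_low", "vasoactive_drugs", "cardiac_arrest", "cpr"}
)
RESPIRATORY_FAILURE_MARKERS = frozenset(
    {"gasping", "pao2_fio2_low", "intubation_ventilation"}
)
HYSTERECTOMY_MARKER = "hysterectomy"

# analyte name -> (marker_id, default unit); analytes accepted by
# evaluate_lab_marker.  spo2 values must be the saturation sustained for at
# least 60 minutes (the duration requirement is part of the marker
# definition, not of the numeric comparison).
LAB_MARKER_MAP: dict[str, str] = {
    "ph": "ph_low",
    "lactate": "lactate_high",
    "respiratory_rate": "resp_rate_abnormal",
    "spo2": "spo2_low",
    "pao2_fio2": "pao2_fio2_low",
    "creatinine": "creatinine_high",
    "platelets": "thrombocytopenia",
    "bilirubin": "bilirubin_high",
}


class CaseCategory(enum.Enum):
    """Mutually exclusive, exhaustive outcome categories."""

    MATERNAL_DEATH = "maternal_death"
    MATERNAL_NEAR_MISS = "maternal_near_miss"
    NO_LIFE_THREATENING_CONDITION = "no_life_threatening_condition"


@dataclass
class CaseRecord:
    """One woman's severity markers, covariate flags and vital status.

    ``raw_labs`` maps analyte name -> (value, unit); positive lab values are
    materialized into ``markers_present`` on construction (explicit marker
    entries always take precedence and are never removed).  The hysterectomy
    flag and the uterine marker are one and the same condition: setting
    either sets both.
    """

    case_id: str
    markers_present: set[str] = field(default_factory=set)
    early_identification: bool = False
    severe_preeclampsia: bool = False
    cancer: bool = False
    hysterectomy: bool = False
    died: bool = False
    raw_labs: dict[str, tuple[float, str]] | None = None
    stratum: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.markers_present) - MARKER_IDS
        if unknown:
            raise ValueError(
                f"case {self.case_id!r}: unknown marker ids {sorted(unknown)}"
            )
        if self.raw_labs:
            for analyte, (value, unit) in self.raw_labs.items():
                if evaluate_lab_marker(analyte, value, unit):
                    self.markers_present.add(LAB_MARKER_MAP[analyte])
        # one boolean drives both the flag and the uterine marker
        if self.hysterectomy:
            self.markers_present.add(HYSTERECTOMY_MARKER)
        elif HYSTERECTOMY_MARKER in self.markers_present:
            self.hysterectomy = True


def _normalize_unit(unit: str | None) -> str:
    if unit is None:
        return ""
    u = unit.strip().lower().replace("µ", "u").replace("per ", "per-")
    if u in {"-", "--", "none"}:
        return ""
    if u in {"/ul", "per-ul", "cells/ul", "per-microliter"}:
        return "per-ul"
    if u in {"per-min", "/min", "min-1", "breaths/min"}:
        return "/min"
    if u in {"mm hg", "mmhg"}:
        return "mmhg"
    if u in {"percent", "%"}:
        return "%"
    return u


def evaluate_lab_marker(analyte: str, value: float, unit: str | None = None) -> bool:
    """Return True iff ``value`` crosses the published cutoff for ``analyte``.

    Strictness follows the published inequality exactly (creatinine ``>=``,
    platelets strictly ``<``, pH strictly ``<`` ...).  Unknown analytes or
    units raise ``ValueError`` -- values are never silently coerced between
    unit scales.
    """
    key = analyte.strip().lower()
    if key not in LAB_MARKER_MAP:
        raise ValueError(
            f"unknown analyte {analyte!r}; expected one of "
            f"{sorted(LAB_MARKER_MAP)}"
        )
    marker = _BY_ID[LAB_MARKER_MAP[key]]
    assert marker.threshold is not None
    u = _normalize_unit(unit)
    if u not in marker.threshold:
        raise ValueError(
            f"unrecognized unit {unit!r} for analyte {analyte!r}; expected "
            f"one of {sorted(marker.threshold)}"
        )
    for direction, cutoff in marker.threshold[u]:
        if direction == "<" and value < cutoff:
            return True
        if direction == ">" and value > cutoff:
            return True
        if direction == ">=" and value >= cutoff:
            return True
    return False


def classify_case(case: CaseRecord) -> CaseCategory:
    """Classify a case as maternal death, near miss, or neither.

    A record with ``died=True`` and no markers is accepted and classified as
    a maternal death (with a validation warning): in the validation study
    every woman who died presented at least one marker, but input data may
    violate that.
    """
    if case.died:
        if not case.markers_present:
            warnings.warn(
                f"case {case.case_id!r}: died without any recorded severity "
                "marker (every death in the reference cohort had >=1)",
                stacklevel=2,
            )
        return CaseCategory.MATERNAL_DEATH
    if case.markers_present:
        return CaseCategory.MATERNAL_NEAR_MISS
    return CaseCategory.NO_LIFE_THREATENING_CONDITION


def severity_score(case: CaseRecord) -> int:
    """Maternal severity score: the number of distinct markers present."""
    return len(set(case.markers_present))


def organ_dysfunction_profile(case: CaseRecord) -> dict[str, str]:
    """Per organ system, the highest severity group present (B dominates A)."""
    profile = {organ: "none" for organ in ORGAN_SYSTEMS}
    for mid in case.markers_present:
        m = _BY_ID[mid]
        if m.group == "B":
            profile[m.organ_system] = "groupB"
        elif profile[m.organ_system] == "none":
            profile[m.organ_system] = "groupA_only"
    return profile


def catalog_to_json() -> str:
    """The full marker catalog as JSON, for audit."""
    entries = []
    for m in CATALOG:
        entries.append(
            {
                "marker_id": m.marker_id,
                "label": m.label,
                "organ_system": m.organ_system,
                "group": m.group,
                "kind": m.kind,
                "threshold": (
                    None
                    if m.threshold is None
                    else {
                        unit: [list(clause) for clause in clauses]
                        for unit, clauses in m.threshold.items()
                    }
                ),
            }
        )
    return json.dumps(entries, indent=2)
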