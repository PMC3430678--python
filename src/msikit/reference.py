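"""Published counts of the 2012 multicenter Brazilian validation study.

These are the printed cohort denominators, per-marker death/survivor counts
and the severity-score distribution from the one-year prospective
surveillance (27 referral maternity hospitals, July 2009 - June 2010) that
validated the WHO maternal near-miss criteria and developed the MSI model.
They are inputs for reconstructing the study's accuracy and risk statistics
and for calibrating the synthetic-cohort generator; nothing in the package
treats them as outputs.
"""

from __future__ import annotations

#: Cohort denominators.
DELIVERIES = 82_388
LIVE_BIRTHS = 82_144
COMPLICATED = 9_555  # women with pregnancy-related complications
SEVERE = 910  # women with >=1 WHO severity marker
MATERNAL_DEATHS = 140
NEAR_MISSES = 770

#: Per-marker (deaths, survivors) among women presenting the marker.
MARKER_DEATH_SURVIVOR: dict[str, tuple[int, int]] = {
    "shock": (74, 176),
    "cardiac_arrest": (51, 13),
    "ph_low": (51, 22),
    "lactate_high": (24, 56),
    "vasoactive_drugs": (101, 143),
    "cpr": (102, 18),
    "acute_cyanosis": (55, 68),
    "gasping": (24, 13),
    "resp_rate_abnormal": (74, 118),
    "spo2_low": (80, 106),
    "pao2_fio2_low": (53, 48),
    "intubation_ventilation": (123, 172),
    "oliguria": (35, 55),
    "creatinine_high": (21, 77),
    "dialysis": (24, 39),
    "clotting_failure": (33, 63),
    "thrombocytopenia": (30, 170),
    "transfusion_5plus": (50, 199),
    "jaundice_preeclampsia": (7, 22),
    "bilirubin_high": (13, 37),
    "prolonged_unconsciousness": (36, 29),
    "metabolic_coma": (6, 12),
    "stroke": (10, 15),
    "status_epilepticus": (5, 11),
    "hysterectomy": (22, 149),
}

#: Deaths among complicated women NOT presenting each marker (printed
#: alongside the per-marker rows; the totals per row always sum to the
#: complicated-cohort size 9,555).
MARKER_UNEXPOSED_DEATHS: dict[str, tuple[int, int]] = {
    marker: (MATERNAL_DEATHS - d, COMPLICATED - (d + s) - (MATERNAL_DEATHS - d))
    for marker, (d, s) in MARKER_DEATH_SURVIVOR.items()
}

#: Severity-score distribution among complicated women: score -> (n, deaths).
#: Scores of 15 or more are pooled in the final open category.
SCORE_DISTRIBUTION: list[tuple[int, int]] = [
    (8645, 0),   # 0 markers
    (402, 0),    # 1
    (148, 3),    # 2
    (70, 6),     # 3
    (61, 14),    # 4
    (59, 19),    # 5
    (46, 16),    # 6
    (29, 15),    # 7
    (18, 10),    # 8
    (20, 15),    # 9
    (20, 13),    # 10
    (6, 4),      # 11
    (13, 11),    # 12
    (4, 3),      # 13
    (7, 5),      # 14
    (7, 6),      # 15+
]


def marker_prevalence_among_complicated() -> dict[str, float]:
    """Per-marker prevalence among the 9,555 complicated women."""
    return {
        marker: (d + s) / COMPLICATED
        for marker, (d, s) in MARKER_DEATH_SURVIVOR.items()
    }
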