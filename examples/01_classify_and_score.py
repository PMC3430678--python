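"""Classify obstetric cases against the WHO life-threatening-condition
markers and compute the maternal severity score.

Builds three hand-written case records -- one entered via raw laboratory
values -- and prints each woman's category (maternal death / maternal near
miss / no life-threatening condition), her severity score (number of
distinct WHO markers present) and the per-organ dysfunction profile.
"""

from msikit import (
    CaseRecord,
    classify_case,
    organ_dysfunction_profile,
    severity_score,
)

cases = [
    # postpartum hemorrhage with shock, survived after hysterectomy
    CaseRecord("pph-01", {"shock", "transfusion_5plus"}, hysterectomy=True),
    # eclampsia with renal failure entered via raw labs: creatinine 4.1
    # mg/dl crosses the >=3.5 mg/dl cutoff and materializes the marker
    CaseRecord(
        "ecl-02", {"status_epilepticus"},
        raw_labs={"creatinine": (4.1, "mg/dl"), "ph": (7.25, "")},
    ),
    # uncomplicated delivery
    CaseRecord("del-03", set()),
]

for case in cases:
    category = classify_case(case)
    print(f"{case.case_id}: {category.value}")
    print(f"  severity score = {severity_score(case)}"
          f"  markers = {sorted(case.markers_present)}")
    profile = organ_dysfunction_profile(case)
    involved = {k: v for k, v in profile.items() if v != "none"}
    print(f"  organ systems involved: {involved or 'none'}")

# A score of 0 with survival means no life-threatening condition; any
# marker with survival is a maternal near miss by the WHO definition.
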