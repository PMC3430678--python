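"""Evaluate the Maternal Severity Index (MSI) on worked cases.

Derives the seven model covariates from case records and evaluates the
published logistic formula.  The MSI is the estimated probability of
maternal death given the life-threatening conditions present; it describes
groups of similar women, never an individual prognosis.
"""

from msikit import CaseRecord, derive_covariates, msi

cases = {
    "no markers": CaseRecord("a", set()),
    "shock only": CaseRecord("b", {"shock"}),
    "cardiac arrest + CPR + ventilation, found on admission": CaseRecord(
        "c",
        {"cardiac_arrest", "cpr", "intubation_ventilation", "shock",
         "vasoactive_drugs"},
        early_identification=True,
    ),
    "severe pre-eclampsia with hysterectomy": CaseRecord(
        "d", {"shock"}, severe_preeclampsia=True, hysterectomy=True
    ),
}

for label, case in cases.items():
    cov = derive_covariates(case)
    print(f"{label}:")
    print(f"  covariates x1..x7 = {cov.as_vector()}")
    print(f"  MSI = {msi(case):.3g}")

# Reading the output: five markers with cardiovascular and respiratory
# failure push the death probability above 50%, while the pre-eclampsia and
# hysterectomy covariates are 'protective' within the model (effective
# treatments exist), lowering the estimate relative to equally-scored cases.
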