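"""Configuration calls from Marfey retention times and derivative masses.

Hydrolysate peaks are matched to authentic FDAA standards within 0.2 min;
the 10.1-min peak has no standard (erythro-beta-OH-Asp) and is resolved by
the two-reagent elution-order rule.  Derivative and fragment masses locate
the analytes by selected-ion extraction.
"""

from siderokit import assign_by_rt, derivative_mz, elution_order_call
from siderokit.marfey import DEFAULT_ELUTION_RULES, MarfeyRecord, partial_hydrolysis_candidates
from siderokit.masscore import NOMINAL, residue_by_name
from siderokit.presets import (
    ADVANCED_MARFEY_ERYTHRO_RT,
    MARFEY_HYDROLYSATE_C3,
    MARFEY_STANDARDS_C3,
    potashchelin,
)

standards = [
    MarfeyRecord(rt=rt, reagent=rg, analyte=a, configuration=c, source="standard")
    for a, c, rg, rt in MARFEY_STANDARDS_C3
]
hydrolysate = [MarfeyRecord(rt=rt, reagent="L-FDAA") for rt in MARFEY_HYDROLYSATE_C3]

res = assign_by_rt(hydrolysate, standards, tol=0.2)
print("assigned:", ", ".join(res.assigned_labels()))
print("unmatched retention times:", [p.rt for p in res.unmatched])

call = elution_order_call(
    ADVANCED_MARFEY_ERYTHRO_RT["L-FDLA"],
    ADVANCED_MARFEY_ERYTHRO_RT["D-FDLA"],
    DEFAULT_ELUTION_RULES["beta-OH-Asp"],
)
print(f"advanced Marfey call for the 10.1-min analyte: "
      f"{call['configuration']}-erythro-beta-OH-Asp")

bha = residue_by_name("beta-OH-Asp")
print("FDLA derivative [M+Na]+ for selected-ion extraction:",
      derivative_mz(bha, "L-FDLA", "[M+Na]+", NOMINAL))

hits = partial_hydrolysis_candidates(potashchelin("B"), 496, tol=0.5)
for h in hits:
    print(f"m/z 496 explained by residues {h['residue_span']} as {h['adduct']}: "
          f"{h['sequence']}")
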