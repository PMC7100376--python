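"""Full elucidation chain on the potashchelin A worked example.

Feeds the observed y peaks, the Marfey tables, the advanced elution-order
measurement and the NRPS domain string into one call and prints the final
per-position stereochemistry with its evidence trail.
"""

import json

from siderokit import HydroxylaseContext, PeakList, elucidate
from siderokit.marfey import MarfeyRecord
from siderokit.presets import (
    ADVANCED_MARFEY_ERYTHRO_RT,
    MARFEY_HYDROLYSATE_C3,
    MARFEY_HYDROLYSATE_COUNTS,
    MARFEY_STANDARDS_C3,
    PTC_DOMAIN_STRING,
    potashchelin,
)

peaks = PeakList.from_mz([218, 319, 450, 537, 624, 681, 768], tolerance=0.5)
standards = [
    MarfeyRecord(rt=rt, reagent=rg, analyte=a, configuration=c, source="standard")
    for a, c, rg, rt in MARFEY_STANDARDS_C3
]
hydrolysate = [
    MarfeyRecord(rt=rt, reagent="L-FDAA", count=MARFEY_HYDROLYSATE_COUNTS.get(rt, 1))
    for rt in MARFEY_HYDROLYSATE_C3
]
advanced = [{
    "analyte": "beta-OH-Asp", "diastereomer_class": "erythro",
    "rt_l_fdla": ADVANCED_MARFEY_ERYTHRO_RT["L-FDLA"],
    "rt_d_fdla": ADVANCED_MARFEY_ERYTHRO_RT["D-FDLA"],
}]

report = elucidate(
    peaks,
    precursor_mz=1097,
    marfey_standards=standards,
    marfey_hydrolysate=hydrolysate,
    advanced_marfey=advanced,
    domain_string=PTC_DOMAIN_STRING,
    hydroxylase_context=HydroxylaseContext(
        standalone=(("PtcA", "3R"),), fused=((1, "3S"),)
    ),
    proposal=potashchelin("A"),
    seed=1,
)

print("final configurations (N to C):")
for c in report["configurations"]:
    note = f"  ({c['note']})" if c.get("note") else ""
    print(f"  {c['position']}: {c['configuration']:>9}-{c['substrate']}{note}")
print("\nconflicts:")
for conflict in report["conflicts"]:
    print(" -", conflict)
print("\nreconciliation:", report["nrps"]["reconciliation"]["verdict"])
print("ladder validation:",
      f"{report['validation']['matched']}/{report['validation']['ladder_size']} matched")
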