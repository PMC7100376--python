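"""Formula parsing and exact masses for the four potashchelins.

Parses each published protonated formula and prices it monoisotopically;
agreement with the published calcd [M+H]+ values (to < 0.5 mDa) validates
the pinned atomic-mass table and the neutral-atom protonation convention.
"""

from siderokit import monoisotopic_mass, nominal_mass, parse_formula

CALCD = {
    "A": "C43H73N10O23",
    "B": "C43H71N10O22",
    "C": "C43H73N10O22",
    "D": "C45H75N10O22",
}

print("compound  [M+H]+ formula     monoisotopic   nominal")
for which, formula in CALCD.items():
    f = parse_formula(formula)
    print(f"   {which}      {f.hill():<16} {monoisotopic_mass(f):12.4f} {nominal_mass(f):9d}")

water = parse_formula("H2O")
print(f"\nB differs from A by one H2O ({monoisotopic_mass(water):.4f} Da): "
      "the 3-OH dodecanoyl tail is replaced by an unsaturated one.")
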