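"""De novo residue decoding from the observed y-series of potashchelin A.

Successive differences of the sorted peaks are residue masses; each is
annotated with every table residue within 0.5 Da.  The 218 start spans two
residues (Ser plus the lactamized N(delta)-OH-Orn terminus), and the
Thr/allo-Thr step stays ambiguous by mass alone — Marfey analysis decides.
"""

from siderokit import decode_ladder
from siderokit.fragments import PeakList

peaks = PeakList.from_mz([218, 319, 450, 537, 624, 681, 768], tolerance=0.5)
decoded = decode_ladder(peaks, tol=0.5, series="y", terminal_convention="cyclized")

print("composite start (inner, terminal):", decoded.composite_terminal)
for step in decoded.steps:
    labels = ", ".join("/".join(g) for g in step.candidates) or "NO CANDIDATE"
    print(f"  delta {step.delta:5.0f} Da -> {labels}")
print(f"uniquely decoded steps: {decoded.score}/{len(decoded.steps)}")
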