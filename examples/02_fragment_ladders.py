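"""Theoretical b/y ladders for the potashchelins and homolog offsets.

The y series (C-terminal fragments) is identical across A-D because the
homologs differ only in the acyl tail; every b fragment shifts by exactly
the tail mass difference, which is how the tails were read off the spectra.
"""

from siderokit import NOMINAL, b_ladder, homolog_offset, match_peaks, y_ladder
from siderokit.fragments import PeakList
from siderokit.presets import potashchelin

a = potashchelin("A")
print("potashchelin A:", a.sequence_str())
print("y series:", y_ladder(a, NOMINAL).mz_values)
print("b series:", b_ladder(a, NOMINAL).mz_values)

for other in "BCD":
    off = homolog_offset(b_ladder(a, NOMINAL), b_ladder(potashchelin(other), NOMINAL))
    print(f"b-series offset A minus {other}: {off.offset:g} Da")

observed = PeakList.from_mz([218, 319, 450, 537, 624, 681, 768], tolerance=0.5)
res = match_peaks(y_ladder(a, NOMINAL), observed)
print(f"observed y peaks matched: {res.n_matched}/{len(observed)} "
      f"(indices {[i for i, _, _ in res.matched]})")
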