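# siderokit

Structure-elucidation toolkit for acylated peptide siderophores — the
lipopeptides that halophilic and marine bacteria secrete to scavenge iron.
It implements, as a tested and reusable pipeline, the desk computations by
which such molecules are characterized:

* **Mass arithmetic** (`siderokit.masscore`): elemental-formula parsing,
  pinned monoisotopic/nominal masses, [M+H]+/[M+Na]+ adducts, and the
  residue table for the nonproteinogenic building blocks of this compound
  class (β-hydroxyaspartate, N(δ)-hydroxyornithine, allo-threonine, …).
* **MS/MS fragment ladders** (`siderokit.fragments`): theoretical b/y
  series for N-acylated peptides with a C-terminal lactam, peak matching,
  and homolog-offset comparison (`b_k` shifts by exactly the acyl-tail mass
  difference; `y_k` does not move).
* **De novo decoding** (`siderokit.denovo`): successive mass differences of
  an observed ladder annotated against the residue table, with explicit
  ambiguity (isobaric Thr/allo-Thr) and composite-terminal handling.
* **Marfey analysis** (`siderokit.marfey`): retention-time assignment
  against authentic FDAA/FDLA standards, the advanced two-reagent
  elution-order rule for configuration calls without a standard, derivative
  m/z prediction for selected-ion extraction, and partial-hydrolysis
  fragment search.
* **NRPS stereochemistry** (`siderokit.nrps`): domain-string parsing and
  the condensation-domain rules (C_Dual ⇒ D donor, C_LCL ⇒ L, C_DCL
  flagged), TauD β-hydroxylase diastereomer assignment, and reconciliation
  against hydrolysate inventories.
* **Hydroxylase phylogeny** (`siderokit.phylo`): p-distance neighbor-joining
  with bootstrap supports and clade-membership classification of
  β-hydroxylase stereospecificity (3R vs 3S product).
* **Synthetic data** (`siderokit.synthetic`): seeded generators for
  structures, noisy spectra, jittered retention-time tables and two-clade
  protein families, so the whole pipeline is testable offline.

The worked example threaded through the package is the potashchelin family
(A–D), four acylated nonapeptides from *Halomonas* sp. MG34 sharing the
headgroup β-OH-Asp–Ser–Gly–Ser–Ser–β-OH-Asp–Thr–Ser–cyclo-N(δ)-OH-Orn; the
pinned structures and assay tables live in `siderokit.presets`.

## The core calculations

A residue contributes its residue mass (amino acid − H₂O) to the chain; the
C-terminal fragment series is

```
y_k = Σ (last k residue masses) + H2O + H     (H2O dropped for a lactamized terminus)
```

and the N-terminal series for an acylated peptide is

```
b_k = acyl + Σ (first k residue masses)
```

with no added proton, because the acyl group replaces the N-terminal amine
hydrogen (free-amine peptides use the textbook `Σ + 1`).  The two series
obey `b_k + y_{n−k} = [M+H]+ + 1` in nominal mode, which is checked
property-style on thousands of random structures.  Marfey derivatives are
priced as `AA + reagent − HF`; NRPS configurations follow from the C-domain
subtype of the *next* module; β-OH-Asp diastereomers follow the pinned
naming table (2S,3S = L-*threo*, 2S,3R = L-*erythro*, …).

## Worked example

```sh
python examples/07_end_to_end.py
```

feeds the observed y peaks (218…768), the Marfey retention-time tables, the
advanced elution-order measurement (10.5 vs 10.0 min) and the NRPS domain
string into one `elucidate()` call and prints:

```
final configurations (N to C):
  1:   L-threo-Asp
  2:         D-Ser
  3:   achiral-Gly
  4:         D-Ser
  5:         L-Ser
  6: L-erythro-Asp
  7:    D-allo-Thr
  8:         L-Ser  (flipped to match the hydrolysate inventory)
  9:         L-Orn

conflicts:
 - position 8: C_DCL in module 9 expects a D donor but no epimerization
   activity acts on this residue; D is unsupported

reconciliation: consistent_with_conflicts
ladder validation: 7/9 matched
```

Position 1 carries L-*threo*-β-OH-Asp (installed by the TauD domain fused
into the first extension module, 3S clade) and position 6 L-*erythro*
(stand-alone PtcA, 3R clade); position 8 is the one place where the naive
condensation-domain rule disagrees with the hydrolysate evidence, and the
report carries both rather than hiding either.  The other examples
(`examples/01…06`) each exercise one capability with a few lines of output.

A thin CLI mirrors the library:
`siderokit mass|ladder|denovo|marfey|nrps|stereotype|simulate|elucidate`.

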