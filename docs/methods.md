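# Methods

This note records the models, conventions and design choices behind
siderokit, and what the synthetic-data tests do and do not demonstrate.

## Mass model

Atomic masses are an internal table of principal-isotope masses pinned to
five decimals (H 1.00783, C 12.00000, N 14.00307, O 15.99491, F 18.99840,
Na 22.98977, …); no external element database is consulted at runtime, so
every mass in the package is bit-stable across machines.  Two scales are
exposed:

* **monoisotopic** — principal-isotope sums, used for high-resolution
  precursor work;
* **nominal** — integer mass-number sums, used for low-resolution MS/MS
  ladders, whose printed values are integers.

**Protonation convention.** A protonated species is priced as the
neutral-atom sum of its protonated formula, i.e. +1.00783 per charge with
the electron mass neglected.  This is the convention under which published
"calcd [M+H]+" values for this compound class are produced, and the four
potashchelin precursor values reproduce to within 0.3 mDa under it.  The
sodium adduct uses the true cation mass 22.98922 (Na − e⁻); the two
conventions differ by half an electron mass, far below every tolerance in
play.  Charge states above 1, average masses and isotope envelopes are out
of scope.

**Residues and acyls.** The residue table stores residue-form formulas
(amino acid − H₂O).  allo-Thr shares the Thr formula and differs only in
its configuration labels, so the two are isobaric by construction and the
decoder treats them as one mass group with two labels.  Acyl groups are
acid-minus-OH fragments with formula CnH(2n−2d−1)O(1+h) for n carbons, d
double bonds, h hydroxyls; double-bond geometry is carried as metadata and
never affects mass.

## Fragment ladders

Structures are N-acylated linear peptides whose C-terminal residue may be
closed into a lactam (a side-chain amine attacking the C-terminal carboxyl,
as in cyclic N(δ)-hydroxyornithine).  The lactam removes one H₂O from both
the neutral molecule and every y fragment containing the terminus.

* `y_k = Σ(last k residues) + H2O + proton`, water suppressed when
  lactamized — so the cyclized N-OH-Orn terminus gives y₁ = 131 nominal.
* `b_k = acyl + Σ(first k residues)` for acylated peptides.  The acyl group
  replaces the N-terminal amine H whose mass otherwise appears as the `+1`
  in the textbook free-amine convention (`b_k = Σ + 1`); both conventions
  are implemented and the structure's acylation state picks the default.
* Complementarity: `b_k + y_{n−k} = [M+H]+ + 1` (nominal) for every k,
  regardless of acyl tail or cyclization.  This is the central bookkeeping
  identity and is tested on 1,000 randomly generated structures.

Matching theoretical ladders to observed peaks is greedy by smallest
|Δm/z| with each observed peak serving at most one index; equal-delta ties
resolve toward the lower observed m/z so results are deterministic.  The
default MS/MS mode is nominal with 0.5 Da tolerance, appropriate for
integer-valued printed ladders; monoisotopic mode exists for precursor
work.

## De novo decoding

Peaks are sorted ascending and successively differenced; each difference is
annotated with every isobaric residue group within tolerance.  Ambiguity is
reported, never auto-resolved: mass cannot separate Thr from allo-Thr, and
in real workflows Marfey analysis and NMR arbitrate.  The score counts
uniquely decoded steps.  The first y value may span two residues when the
terminus is lactamized (the lactam suppresses the y₁-defining water, so
y₂-like values appear first); `explain_composite_start` enumerates all
residue pairs consistent with the start under the declared terminal
convention, requiring a lactam-capable terminal residue in cyclized mode.
With peak dropout, merged deltas are flagged no-candidate or multi-residue
rather than silently mis-assigned (tested).

## Marfey configuration calls

Retention-time assignment is a pure function of (peaks, standards,
tolerance), comparing only like reagent with like.  The default tolerance
is 0.2 min: the authentic standards in the bundled table are separated by
at least 0.4 min, so 0.2 min is the largest window that can never produce a
cross-standard ambiguity, and it reproduces the published assignment set
with the erythro-β-OH-Asp peak (10.1 min, no standard available) correctly
left unmatched.

The advanced (two-reagent) method is encoded as data, not code: an
`ElutionRule` declares, per analyte class, which elution order of the
L- versus D-FDLA derivatives implies L.  The shipped rule for β-OH-Asp
diastereomers is "L-FDLA derivative eluting after the D-FDLA derivative ⇒
L at C-2"; retention differences under 0.1 min are indeterminate.  Users
can supply their own rules per analyte.

Reagent formulas are pinned internally (FDAA C9H9FN4O5, FDLA C12H15FN4O5,
condensation loss HF) and validated by reproducing the published m/z 466
[M+Na]+ selected ion.  Only mono-derivatization is modeled by default;
di-derivatized species (possible for Orn) are representable by applying
the reagent arithmetic twice but are outside the default search.

The partial-hydrolysis search enumerates every contiguous residue run of a
structure — N-terminal runs keep the acyl tail, C-terminal runs keep the
lactam state — and prices both [M+H]+ and [M+Na]+ for each, because a
hydrolysis product ion's adduct is generally unstated; for the potashchelin
B product at m/z 496 the sodiated acyl-β-OH-Asp-Ser-Gly fragment is the
unique match within 0.5 Da.

## NRPS stereochemistry rules

Module segmentation: the loading module is everything before the first
condensation-family domain; each extension module starts at a C-family
domain, except that a second C continuing an interrupted condensation
domain (C-TauD-C) stays in the same module.  The configuration of the
residue loaded by module *i* follows from the C subtype of module *i+1*:

| downstream C | configuration | rationale |
| --- | --- | --- |
| C_Dual | D | epimerizes its donor during condensation |
| C_LCL | L | L donor, L acceptor |
| C_DCL | D (flagged) | expects a D donor but has no epimerase activity |
| (none — terminal) | L, marked "assumed" | no downstream evidence |

Gly is achiral regardless.  The C_DCL case is deliberately carried as a
conflict rather than trusted: a D donor requires some epimerizing activity
acting on that residue, and when none exists in the architecture the D
expectation is unsupported.  In the potashchelin architecture this happens
at position 8, and the hydrolysate inventory (two L-Ser, two D-Ser)
resolves it to L; `reconcile` reports `consistent_with_conflicts` when
flipping exactly the flagged positions reconciles the counts, and the
pipeline then emits the flipped configuration with an explicit note instead
of silently preferring either source.

β-hydroxylation: a TauD domain fused into a module's C domain hydroxylates
the Asp loaded by that module; remaining Asp positions receive stand-alone
hydroxylase classes in order.  The (C2, C3) pair names the diastereomer:
(2S,3S) = L-*threo*, (2S,3R) = L-*erythro*, (2R,3R) = D-*threo*,
(2R,3S) = D-*erythro*.  All hydroxylation annotations are marked
"predicted": the division of labor between two hydroxylases and two Asp
positions is inferred from architecture adjacency, not enzymatically
demonstrated.

## Hydroxylase phylogeny

Distances are p-distances (mismatches over compared columns) with pairwise
gap deletion — a deliberate choice where common practice varies; a pair
with no comparable columns is an error, not a zero.  Tree inference is
neighbor joining with two determinism choices: minimum-Q ties break to the
lowest index pair, and negative branch lengths are clamped to zero with the
remainder shifted to the sister edge (sum preserved).  Rooting is by
declared outgroup when present, else midpoint.  On an exactly additive
metric NJ provably recovers the generating tree; this is tested, along with
topology agreement against an independent NJ implementation.

Distance+NJ stands in for likelihood inference by design: the claim the
classifier makes is *clade membership*, which at the simulated divergences
(within-clade substitution probability 0.05 per site, between-clade 0.4,
length 300) is insensitive to the inference method; a maximum-likelihood
backend is explicitly out of scope.  Bootstrap supports come from
column-resampled replicates; each internal edge of the original tree gets
the percentage of replicates containing its (unrooted, canonicalized)
bipartition, seeded and reproducible.

Classification walks rootward from the query tip to the smallest enclosing
clade whose non-query leaves carry one uniform stereo label (outgroups
break purity; other queries do not), attaching that clade's bootstrap
support; with no pure clade below the root it falls back to the nearest
labeled leaf by path length, and an exact tie is `ambiguous`.  The call is
a prediction, never a guarantee: hydroxylase phylogenies can track
genus-level mutational history as much as catalytic stereospecificity, and
no correction for that confounding is attempted.

## Synthetic data: what it emulates, what it does not

Every generator is a pure function of (config, seed); the same seed
reproduces outputs byte for byte, and simulation-derived statistics in the
tests are replayable from their logged seeds.

* Structures: 5–12 residues uniformly from the residue table, one of four
  C12/C14 acyl tails, C-terminal lactam with probability ½ when the
  terminal residue permits — the scaffold class of acylated peptide
  siderophores, not any one molecule's residue statistics.
* Spectra: theoretical ladder minus Bernoulli(dropout 0.1) deletions, plus
  Gaussian m/z jitter (σ 0.1 Da) and Poisson(3) decoy peaks uniform on
  [100, precursor].  This is a deliberately simple null: no intensity
  model, no isotope envelopes, no correlated chemical noise, single fixed
  charge.  Passing round-trip tests therefore shows the ladder logic is
  self-consistent under thinning and jitter, not that the decoder survives
  real chimeric spectra.
* Marfey tables: standards at their base retention times, hydrolysate
  peaks jittered with σ 0.05 min — half the published minimum standard
  separation scaled by the same factor as the assignment window, giving a
  ≥ 99% recovery benchmark over 1,000 draws.  No gradient drift or
  co-elution structure is modeled.
* Protein families: a uniform-random root, two clade ancestors at
  substitution probability 0.4 per site, leaves and queries at 0.05, 8
  references per clade, length 300, 20 seeds for the accuracy benchmark.
  Sites evolve independently with a uniform replacement model; rate
  heterogeneity, indels and compositional bias are absent, so the ≥ 95%
  accuracy result measures the classifier's clade logic, not its robustness
  to realistic protein evolution.

## Numerical and degenerate-input choices

* Formula subtraction that would go negative raises, naming the element.
* Ladder types enforce strictly increasing indices and m/z at
  construction.
* RT assignment treats deltas equal within 1 μmin as ties (float safety)
  and reports ties as ambiguous rather than picking.
* Bootstrap replicates whose resampled columns leave some pair with no
  comparable sites are skipped and contribute no support.
* Problem sizes in the tests (1,000 structures, 1,000 retention-time
  draws, 20 phylogeny seeds, 100 bootstrap replicates) are the package's
  benchmark conditions; all complete in seconds.

## Known limitations

* b/y only: a/c/x/z ions, internal fragments, neutral losses and multiply
  charged fragments are not modeled.
* The de novo decoder assumes a single clean series; it does not build a
  spectrum graph over mixed unordered series.
* Retention times are matched, never predicted from structure.
* A-domain substrate specificity is taken from the annotated domain
  string, not predicted from sequence.
* The phylogeny component classifies; it does not search tree space or fit
  substitution models.
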