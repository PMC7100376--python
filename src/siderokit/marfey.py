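"""Marfey-derivative configuration assignment and derivative-mass prediction.

Marfey's method condenses a chiral aryl reagent (FDAA, or the leucinamide
analog FDLA) onto an amino acid's alpha-amine with loss of HF, turning
enantiomers into chromatographically separable diastereomers.  Two readouts
are supported:

* **Standards comparison** — hydrolysate derivative retention times are
  matched against authentic standards run under the same gradient
  (:func:`assign_by_rt`).
* **Elution-order rule (advanced method)** — when no standard exists, the
  analyte is derivatized separately with L- and D-FDLA and the configuration
  is called from which derivative elutes later (:func:`elution_order_call`).
  The rule per analyte class is data, not code: the shipped default encodes
  the beta-OH-Asp behaviour (L-FDLA derivative eluting after the D-FDLA
  derivative implies L at C-2).

:func:`derivative_mz` predicts derivative masses for selected-ion
extraction, and :func:`partial_hydrolysis_candidates` enumerates contiguous
sub-structures of a lipopeptide to explain partial-hydrolysis product ions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .fragments import LipopeptideStructure
from .masscore import (
    ElementalFormula,
    MassMode,
    NOMINAL,
    ResidueSpec,
    adduct_mz,
    parse_formula,
)

__all__ = [
    "MarfeyRecord",
    "ReagentSpec",
    "ElutionRule",
    "AssignmentResult",
    "REAGENTS",
    "DEFAULT_ELUTION_RULES",
    "assign_by_rt",
    "elution_order_call",
    "derivative_mz",
    "partial_hydrolysis_candidates",
]

_HF = parse_formula("HF")


@dataclass(frozen=True)
class MarfeyRecord:
    """One chromatographic observation: analyte, reagent, retention time.

    Standards carry a full configuration; hydrolysate records may leave
    ``analyte``/``configuration`` empty until assigned.  ``count`` is the
    residue multiplicity a hydrolysate peak represents (from integration
    against a single-residue reference), default 1.
    """

    rt: float
    reagent: str
    analyte: str = ""
    configuration: str = ""
    source: str = "hydrolysate"
    count: int = 1

    def __post_init__(self):
        if self.rt <= 0:
            raise ValueError("retention time must be positive")
        if self.source not in ("standard", "hydrolysate"):
            raise ValueError("source must be 'standard' or 'hydrolysate'")
        if self.source == "standard" and not (self.analyte and self.configuration):
            raise ValueError("standards must carry analyte and configuration")


@dataclass(frozen=True)
class ReagentSpec:
    """A Marfey-type reagent; derivatization adds the reagent and drops HF."""

    name: str
    formula: ElementalFormula
    condensation_loss: ElementalFormula = _HF


REAGENTS: dict[str, ReagentSpec] = {
    "L-FDAA": ReagentSpec("L-FDAA", parse_formula("C9H9FN4O5")),
    "D-FDAA": ReagentSpec("D-FDAA", parse_formula("C9H9FN4O5")),
    "L-FDLA": ReagentSpec("L-FDLA", parse_formula("C12H15FN4O5")),
    "D-FDLA": ReagentSpec("D-FDLA", parse_formula("C12H15FN4O5")),
}


@dataclass(frozen=True)
class ElutionRule:
    """Per-analyte-class elution-order rule for the advanced method.

    ``implies_when_l_later`` is the configuration called when the L-FDLA
    derivative elutes *after* the D-FDLA derivative; the opposite order
    calls the opposite configuration.  Retention-time differences below
    ``resolution`` (min) are indeterminate.
    """

    analyte: str
    implies_when_l_later: str = "L"
    resolution: float = 0.1
    citation: str = ""

    def opposite(self) -> str:
        return "D" if self.implies_when_l_later == "L" else "L"


DEFAULT_ELUTION_RULES: dict[str, ElutionRule] = {
    "beta-OH-Asp": ElutionRule(
        analyte="beta-OH-Asp",
        implies_when_l_later="L",
        citation="FDLA elution order for beta-hydroxyaspartate diastereomers",
    ),
}


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of matching hydrolysate peaks to standards."""

    assignments: tuple[tuple[MarfeyRecord, MarfeyRecord], ...]  # (peak, standard)
    unmatched: tuple[MarfeyRecord, ...]
    ambiguous: tuple[tuple[MarfeyRecord, tuple[MarfeyRecord, ...]], ...]

    def assigned_labels(self) -> tuple[str, ...]:
        from .masscore import stereo_label

        return tuple(
            stereo_label(std.configuration, std.analyte) for _, std in self.assignments
        )


def assign_by_rt(
    hydrolysate: Sequence[MarfeyRecord],
    standards: Sequence[MarfeyRecord],
    tol: float = 0.2,
) -> AssignmentResult:
    """Assign each hydrolysate peak the unique standard within ``tol`` minutes.

    Peaks are only compared against standards of the same reagent.  A peak
    with no standard within tolerance is unmatched; a peak with more than
    one is ambiguous (all hits listed).  Pure function of its inputs:
    deterministic and permutation-invariant.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not standards:
        raise ValueError("standards table is empty")
    assignments = []
    unmatched = []
    ambiguous = []
    for peak in sorted(hydrolysate, key=lambda r: (r.rt, r.reagent)):
        hits = sorted(
            (s for s in standards
             if s.reagent == peak.reagent and abs(s.rt - peak.rt) <= tol),
            key=lambda s: (abs(s.rt - peak.rt), s.rt),
        )
        if not hits:
            unmatched.append(peak)
        elif (len(hits) == 1
              or abs(hits[0].rt - peak.rt) < abs(hits[1].rt - peak.rt) - 1e-6):
            assignments.append((peak, hits[0]))
        else:
            ambiguous.append((peak, tuple(hits)))
    return AssignmentResult(
        assignments=tuple(assignments),
        unmatched=tuple(unmatched),
        ambiguous=tuple(ambiguous),
    )


def elution_order_call(
    rt_l_fdla: float, rt_d_fdla: float, rule: ElutionRule
) -> dict:
    """L/D call from the elution order of the L- vs D-FDLA derivatives.

    Returns ``{"configuration": "L"|"D"|"indeterminate", "rule": ...}``.
    Swapping the two retention times always flips a determinate call.
    """
    diff = rt_l_fdla - rt_d_fdla
    if abs(diff) < rule.resolution:
        config = "indeterminate"
    elif diff > 0:
        config = rule.implies_when_l_later
    else:
        config = rule.opposite()
    return {"configuration": config, "rule": rule.analyte, "delta_rt": diff}


def derivative_mz(
    aa: ResidueSpec,
    reagent: ReagentSpec | str,
    adduct: str = "[M+H]+",
    mode: MassMode = NOMINAL,
) -> float:
    """m/z of the mono-derivatized free amino acid (AA + reagent - HF)."""
    if isinstance(reagent, str):
        reagent = REAGENTS[reagent]
    neutral = aa.free_formula + reagent.formula - reagent.condensation_loss
    return adduct_mz(neutral, adduct, mode)


def partial_hydrolysis_candidates(
    s: LipopeptideStructure,
    fragment_mz: float,
    adducts: Iterable[str] = ("[M+H]+", "[M+Na]+"),
    mode: MassMode = NOMINAL,
    tol: float = 0.5,
) -> list[dict]:
    """Contiguous sub-structures of ``s`` whose adduct m/z matches an ion.

    Enumerates every contiguous residue run: N-terminal-anchored runs retain
    the acyl tail; a run reaching the C-terminus retains the lactam state.
    Returns matching candidates as dicts with the sub-structure, adduct and
    computed m/z.  Run on the intact molecule's own precursor m/z the result
    always contains the full molecule.
    """
    n = len(s)
    out = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = LipopeptideStructure(
                residues=s.residues[i:j],
                acyl=s.acyl if i == 0 else None,
                c_terminal_cyclized=s.c_terminal_cyclized and j == n,
                name=f"{s.name}[{i + 1}..{j}]" if s.name else f"[{i + 1}..{j}]",
            )
            for adduct in adducts:
                mz = adduct_mz(sub.neutral_formula(), adduct, mode)
                if abs(mz - fragment_mz) <= tol:
                    out.append(
                        {
                            "structure": sub,
                            "residue_span": (i + 1, j),
                            "adduct": adduct,
                            "mz": mz,
                            "sequence": sub.sequence_str(),
                        }
                    )
    return out
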