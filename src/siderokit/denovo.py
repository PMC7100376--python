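"""Decode fragment ladders into residue sequences by successive mass differences.

The "sequential increase" reading of an MS/MS ladder: sort the observed
series, difference successive peaks, and annotate each difference with every
residue in the table whose mass lies within tolerance.  Ambiguity is
reported, never auto-resolved — mass alone cannot separate isobaric residues
(Thr vs allo-Thr) or choose between coincidental matches, and in practice
Marfey analysis and NMR arbitrate.  The decoder therefore scores a result by
the number of uniquely decoded steps.

Direction conventions: y-series ladders decode C-terminal to N-terminal;
b-series ladders decode N to C with the acyl mass as the initial offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .fragments import LipopeptideStructure, PeakList
from .masscore import MassMode, NOMINAL, ResidueSpec, WATER, builtin_residue_table

__all__ = [
    "DecodedStep",
    "DecodedSequence",
    "ConsistencyReport",
    "decode_ladder",
    "explain_composite_start",
    "sequence_consistency",
]


@dataclass(frozen=True)
class DecodedStep:
    """One successive mass difference with its candidate residues.

    ``candidates`` holds isobaric groups: residues sharing one formula are
    a single group with multiple labels (Thr/allo-Thr), so a step matched
    by exactly one group counts as uniquely decoded.
    """

    delta: float
    candidates: tuple[tuple[str, ...], ...]

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def no_candidate(self) -> bool:
        return len(self.candidates) == 0

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(name for group in self.candidates for name in group)


@dataclass(frozen=True)
class DecodedSequence:
    """Result of differencing a ladder against a residue table."""

    series: str
    steps: tuple[DecodedStep, ...]
    composite_terminal: tuple[tuple[str, ...], ...] = ()
    first_mz: float = 0.0

    @property
    def score(self) -> int:
        """Number of uniquely decoded steps."""
        return sum(1 for st in self.steps if st.unique)

    def residue_names(self) -> tuple[Optional[str], ...]:
        """Unique single-label calls per step; None where ambiguous/empty."""
        out = []
        for st in self.steps:
            if st.unique and len(st.candidates[0]) == 1:
                out.append(st.candidates[0][0])
            else:
                out.append(None)
        return tuple(out)


def _isobaric_groups(
    table: Sequence[ResidueSpec], mode: MassMode
) -> list[tuple[float, tuple[str, ...]]]:
    by_formula: dict[str, list[str]] = {}
    for r in table:
        by_formula.setdefault(r.formula.hill(), []).append(r.name)
    groups = []
    for hill, names in by_formula.items():
        mass = mode.mass(next(r.formula for r in table if r.formula.hill() == hill))
        groups.append((mass, tuple(names)))
    return sorted(groups)


def decode_ladder(
    peaks: PeakList,
    table: Optional[Sequence[ResidueSpec]] = None,
    tol: float = 0.5,
    series: str = "y",
    mode: MassMode = NOMINAL,
    terminal_convention: Optional[str] = None,
) -> DecodedSequence:
    """Annotate successive peak differences with candidate residues.

    Peaks are sorted ascending before differencing (input order does not
    matter).  Each difference is matched against the residue table within
    ``tol``; steps with several isobaric groups are ambiguous, steps with
    none are flagged no-candidate.  If ``terminal_convention`` is given
    ("free" or "cyclized"), the first peak is additionally explained as one
    or two terminal residues via :func:`explain_composite_start`.
    """
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to difference a ladder")
    if series not in ("b", "y"):
        raise ValueError("series must be 'b' or 'y'")
    table = list(table) if table is not None else builtin_residue_table()
    groups = _isobaric_groups(table, mode)
    mz = sorted(peaks.mz_values)
    steps = []
    for lo, hi in zip(mz, mz[1:]):
        delta = hi - lo
        cands = tuple(names for mass, names in groups if abs(mass - delta) <= tol)
        steps.append(DecodedStep(delta=delta, candidates=cands))
    composite: tuple[tuple[str, ...], ...] = ()
    if terminal_convention is not None and series == "y":
        expl = explain_composite_start(mz[0], table, tol, terminal_convention, mode)
        composite = tuple(expl["pairs"]) + tuple((n,) for n in expl["singles"])
    return DecodedSequence(
        series=series, steps=tuple(steps), composite_terminal=composite, first_mz=mz[0]
    )


def explain_composite_start(
    first_mz: float,
    table: Optional[Sequence[ResidueSpec]] = None,
    tol: float = 0.5,
    terminal_convention: str = "free",
    mode: MassMode = NOMINAL,
) -> dict:
    """Explain the first y value as one residue or an unordered residue pair.

    Terminal bookkeeping: a free C-terminus carries +H2O +proton (+19
    nominal); a lactamized C-terminus loses that water again (+1 nominal)
    and requires a lactam-capable residue at the terminus.  Returns
    ``{"singles": [name, ...], "pairs": [(inner, terminal), ...]}``.
    """
    if first_mz <= 0:
        raise ValueError("first_mz must be positive")
    if terminal_convention not in ("free", "cyclized"):
        raise ValueError("terminal_convention must be 'free' or 'cyclized'")
    table = list(table) if table is not None else builtin_residue_table()
    offset = mode.proton
    if terminal_convention == "free":
        offset += mode.mass(WATER)
    target = first_mz - offset
    singles = [
        r.name
        for r in table
        if abs(mode.mass(r.formula) - target) <= tol
        and (terminal_convention == "free" or r.lactam_capable)
    ]
    pairs = []
    for terminal in table:
        if terminal_convention == "cyclized" and not terminal.lactam_capable:
            continue
        for inner in table:
            total = mode.mass(terminal.formula) + mode.mass(inner.formula)
            if abs(total - target) <= tol:
                pairs.append((inner.name, terminal.name))
    # dedupe unordered duplicates only when both orderings are admissible
    seen = set()
    unique_pairs = []
    for p in pairs:
        key = frozenset(p) if terminal_convention == "free" else p
        if key not in seen:
            seen.add(key)
            unique_pairs.append(p)
    return {"singles": singles, "pairs": unique_pairs}


@dataclass(frozen=True)
class ConsistencyReport:
    """Position-by-position comparison of a decoding with a proposed structure."""

    consistent: bool
    mismatches: tuple[tuple[int, str, tuple[str, ...]], ...]  # (1-based pos, proposed, decoded labels)
    low_confidence: bool
    length_mismatch: Optional[str] = None


def sequence_consistency(
    decoded: DecodedSequence, proposal: LipopeptideStructure
) -> ConsistencyReport:
    """True iff every uniquely decoded step matches the proposal at that position.

    Steps from a y ladder are aligned C to N (the composite start spans the
    terminal residue pair when present); b-ladder steps align N to C.
    Ambiguous and no-candidate steps do not count against consistency, but a
    decoding with no unique step at all is flagged low-confidence.
    """
    n = len(proposal)
    names = [r.name for r in proposal.residue_specs]
    mismatches = []
    length_mismatch = None
    n_terminal = 2 if any(len(p) == 2 for p in decoded.composite_terminal) else 1
    for j, step in enumerate(decoded.steps, start=1):
        if decoded.series == "y":
            pos = n - n_terminal - j + 1  # 1-based from N-terminus
        else:
            pos = j + 1  # b1 spans acyl + residue 1; delta j enters residue j+1
        if not (1 <= pos <= n):
            length_mismatch = (
                f"step {j} maps outside the proposal (position {pos} of {n})"
            )
            continue
        if step.no_candidate or not step.unique:
            continue
        if names[pos - 1] not in step.candidates[0]:
            mismatches.append((pos, names[pos - 1], step.labels))
    low_confidence = all(not st.unique for st in decoded.steps)
    return ConsistencyReport(
        consistent=not mismatches,
        mismatches=tuple(mismatches),
        low_confidence=low_confidence,
        length_mismatch=length_mismatch,
    )
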