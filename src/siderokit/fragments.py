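"""Theoretical b/y fragment ladders for N-acylated peptides and peak matching.

Models the MS/MS logic used to sequence acylated peptide siderophores: the
molecule is an N-acylated linear peptide whose C-terminal residue may be
closed into a lactam (e.g. cyclic N(delta)-hydroxyornithine).  Collision-
induced dissociation along the backbone yields a C-terminal y series and an
N-terminal b series whose successive differences are residue masses.

b-ion convention
----------------
For an *acylated* peptide the acyl group replaces the N-terminal amine H, so
the printed integer b values are reproduced by ``b_k = acyl + sum(residues
1..k)`` with no added proton.  Free-amine peptides use the textbook
``b_k = sum(residues) + 1``.  Both conventions are exposed; acylated
structures default to the former.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .masscore import (
    AcylSpec,
    ElementalFormula,
    HYDROGEN,
    MassMode,
    NOMINAL,
    ResidueSpec,
    WATER,
    adduct_mz,
)

__all__ = [
    "LipopeptideStructure",
    "FragmentLadder",
    "PeakList",
    "y_ladder",
    "b_ladder",
    "precursor_mz",
    "match_peaks",
    "homolog_offset",
    "MatchResult",
    "OffsetResult",
]


@dataclass(frozen=True)
class LipopeptideStructure:
    """An ordered residue chain with an optional acyl tail and C-terminal lactam.

    ``residues`` holds ``(ResidueSpec, configuration-label)`` pairs; use the
    label ``"unknown"`` where the configuration is unresolved.  If
    ``c_terminal_cyclized`` the last residue must be lactam-capable and the
    C-terminal water is suppressed in all mass bookkeeping.
    """

    residues: tuple[tuple[ResidueSpec, str], ...]
    acyl: Optional[AcylSpec] = None
    c_terminal_cyclized: bool = False
    name: str = ""

    def __post_init__(self):
        if not self.residues:
            raise ValueError("structure needs at least one residue")
        if self.c_terminal_cyclized and not self.residues[-1][0].lactam_capable:
            raise ValueError(
                f"C-terminal cyclization requires a lactam-capable residue, "
                f"got {self.residues[-1][0].name}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_specs(self) -> tuple[ResidueSpec, ...]:
        return tuple(r for r, _ in self.residues)

    @property
    def configurations(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.residues)

    def neutral_formula(self) -> ElementalFormula:
        """Neutral molecular formula.

        Sum of residue formulas + H2O (peptide termini), minus one H where
        the acyl replaces the N-terminal amine H, plus the acyl formula,
        minus H2O again if the C-terminus is lactamized.
        """
        f = ElementalFormula()
        for r, _ in self.residues:
            f = f + r.formula
        f = f + WATER
        if self.acyl is not None:
            f = f + self.acyl.formula - HYDROGEN
        if self.c_terminal_cyclized:
            f = f - WATER
        return f

    def sequence_str(self) -> str:
        parts = []
        if self.acyl is not None:
            parts.append(self.acyl.describe())
        from .masscore import stereo_label

        for r, cfg in self.residues:
            label = r.name if cfg in ("", "unknown") else stereo_label(cfg, r.name)
            if self.c_terminal_cyclized and r is self.residues[-1][0]:
                label = f"cyclo-{label}"
            parts.append(label)
        return "-".join(parts)


@dataclass(frozen=True)
class FragmentLadder:
    """An indexed b- or y-series: ordered ``(index, m/z)`` entries."""

    series: str  # "b" or "y"
    entries: tuple[tuple[int, float], ...]
    mode: MassMode
    precursor_mz: float

    def __post_init__(self):
        if self.series not in ("b", "y"):
            raise ValueError("series must be 'b' or 'y'")
        idx = [i for i, _ in self.entries]
        mzs = [m for _, m in self.entries]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("ladder indices must be strictly increasing")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("ladder m/z must strictly increase with index")

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(m for _, m in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PeakList:
    """Observed peaks: ``(m/z, intensity-or-None)`` with a match tolerance in Da."""

    peaks: tuple[tuple[float, Optional[float]], ...]
    tolerance: float = 0.5

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("peak m/z must be positive")

    @classmethod
    def from_mz(cls, mz: Iterable[float], tolerance: float = 0.5) -> "PeakList":
        return cls(tuple((float(m), None) for m in mz), tolerance)

    @property
    def mz_values(self) -> tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def _residue_masses(s: LipopeptideStructure, mode: MassMode) -> list[float]:
    return [mode.mass(r.formula) for r, _ in s.residues]


def precursor_mz(
    s: LipopeptideStructure, adduct: str = "[M+H]+", mode: MassMode = NOMINAL
) -> float:
    """Adduct m/z of the intact molecule."""
    return adduct_mz(s.neutral_formula(), adduct, mode)


def y_ladder(s: LipopeptideStructure, mode: MassMode = NOMINAL) -> FragmentLadder:
    """y series: ``y_k`` covers the k C-terminal residues.

    ``y_k = sum(last k residue masses) + H2O + proton``, with the H2O
    suppressed when the C-terminal residue is lactamized.  Entries run
    k = 1..n; for an acylated peptide ``y_n`` is the full (acyl-free)
    peptide ion.
    """
    masses = _residue_masses(s, mode)
    water = mode.mass(WATER) if not s.c_terminal_cyclized else 0.0
    entries = []
    total = 0.0
    for k in range(1, len(masses) + 1):
        total += masses[-k]
        entries.append((k, total + water + mode.proton))
    return FragmentLadder(
        series="y",
        entries=tuple(entries),
        mode=mode,
        precursor_mz=precursor_mz(s, "[M+H]+", mode),
    )


def b_ladder(
    s: LipopeptideStructure,
    mode: MassMode = NOMINAL,
    max_index: Optional[int] = None,
) -> FragmentLadder:
    """b series: ``b_k`` covers the acyl tail plus the k N-terminal residues.

    Acylated: ``b_k = acyl + sum(first k residues)`` (no proton; the acyl
    replaces the amine H).  Free-amine: ``b_k = sum(first k residues) + 1``.
    Entries run k = 1..n-1 by default (``b_n`` is rarely observed).
    """
    masses = _residue_masses(s, mode)
    n = len(masses)
    top = max_index if max_index is not None else n - 1
    if not (1 <= top <= n):
        raise ValueError(f"max_index must be in 1..{n}")
    if s.acyl is not None:
        offset = mode.mass(s.acyl.formula)
    else:
        offset = mode.proton
    entries = []
    total = offset
    for k in range(1, top + 1):
        total += masses[k - 1]
        entries.append((k, total))
    return FragmentLadder(
        series="b",
        entries=tuple(entries),
        mode=mode,
        precursor_mz=precursor_mz(s, "[M+H]+", mode),
    )


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a theoretical ladder against observed peaks."""

    matched: tuple[tuple[int, float, float], ...]  # (index, observed mz, delta)
    unmatched_indices: tuple[int, ...]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def match_peaks(theoretical: FragmentLadder, observed: PeakList) -> MatchResult:
    """Greedy nearest match of ladder entries to observed peaks.

    Each theoretical entry is matched to the closest observed peak within
    tolerance; one observed peak may satisfy at most one index.  Pairs are
    assigned globally in order of increasing |delta|; equal-delta ties
    resolve toward the lower observed m/z, deterministically.
    """
    tol = observed.tolerance
    obs = sorted(observed.mz_values)
    candidates = []
    for idx, theo in theoretical.entries:
        for j, omz in enumerate(obs):
            delta = omz - theo
            if abs(delta) <= tol:
                candidates.append((abs(delta), omz, idx, j, delta))
    used_idx: set[int] = set()
    used_obs: set[int] = set()
    matched: dict[int, tuple[float, float]] = {}
    for absd, omz, idx, j, delta in sorted(candidates):
        if idx in used_idx or j in used_obs:
            continue
        used_idx.add(idx)
        used_obs.add(j)
        matched[idx] = (omz, delta)
    ordered = tuple(
        (idx, matched[idx][0], matched[idx][1])
        for idx, _ in theoretical.entries
        if idx in matched
    )
    unmatched = tuple(idx for idx, _ in theoretical.entries if idx not in matched)
    return MatchResult(matched=ordered, unmatched_indices=unmatched)


@dataclass(frozen=True)
class OffsetResult:
    """Result of a homolog ladder comparison."""

    constant: bool
    offset: Optional[float]
    deviations: tuple[tuple[int, float], ...] = ()  # (index, a_k - b_k) where nonconstant


def homolog_offset(
    a: FragmentLadder, b: FragmentLadder, tolerance: float = 1e-9
) -> OffsetResult:
    """Constant offset ``a_k - b_k`` across two same-series ladders.

    Homologous lipopeptides differing only in the acyl tail shift every b
    fragment by the acyl mass difference and no y fragment; this check is
    how such tail differences are read off printed ladders.
    """
    if a.series != b.series:
        raise ValueError(f"series mismatch: {a.series} vs {b.series}")
    if a.mode.mode != b.mode.mode:
        raise ValueError("mass-mode mismatch")
    if len(a) != len(b):
        raise ValueError(f"ladder length mismatch: {len(a)} vs {len(b)}")
    diffs = [(ia, ma - mb) for (ia, ma), (_, mb) in zip(a.entries, b.entries)]
    d0 = diffs[0][1]
    devs = tuple((i, d) for i, d in diffs if abs(d - d0) > tolerance)
    if devs:
        return OffsetResult(constant=False, offset=None, deviations=devs)
    return OffsetResult(constant=True, offset=d0)
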