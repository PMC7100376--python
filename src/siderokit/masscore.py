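"""Elemental-formula parsing and exact mass arithmetic.

This module is the numerical foundation of the toolkit: every fragment m/z,
adduct, derivative mass and precursor value elsewhere is assembled from the
:class:`ElementalFormula` arithmetic and the pinned atomic-mass table defined
here.

Two mass scales are supported:

* **monoisotopic** — the sum of principal-isotope atomic masses, the scale on
  which high-resolution [M+H]+ values are reported.  The convention used
  throughout is that a protonated species is priced as the *neutral-atom* sum
  of its protonated formula (H = 1.00783 Da, electron mass neglected), which
  reproduces published "calcd" values for peptide siderophores.
* **nominal** — integer mass-number sums, the scale on which low-resolution
  MS/MS fragment ladders are printed.

The residue table covers the proteinogenic and nonproteinogenic residues
found in acylated peptide siderophores of the aquachelin/cupriachelin/
potashchelin class: Ser, Gly, Thr/allo-Thr, Asp, beta-hydroxyaspartate,
Orn and N(delta)-hydroxyornithine (which can close a C-terminal lactam).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "ElementalFormula",
    "ResidueSpec",
    "AcylSpec",
    "MassMode",
    "MONOISOTOPIC",
    "NOMINAL",
    "parse_formula",
    "monoisotopic_mass",
    "nominal_mass",
    "formula_arith",
    "adduct_mz",
    "builtin_residue_table",
    "residue_by_name",
    "acyl_from_description",
    "FormulaError",
    "WATER",
    "PROTON_MONO",
    "SODIUM_CATION_MONO",
]

# Principal-isotope atomic masses, pinned to 5 decimals so results are
# bit-stable; no external element database is consulted at runtime.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00783,
    "C": 12.00000,
    "N": 14.00307,
    "O": 15.99491,
    "F": 18.99840,
    "Na": 22.98977,
    "P": 30.97376,
    "S": 31.97207,
    "Cl": 34.96885,
    "K": 38.96371,
    "Fe": 55.93494,
}

# Integer mass numbers of the same principal isotopes.
MASS_NUMBER: dict[str, int] = {
    "H": 1,
    "C": 12,
    "N": 14,
    "O": 16,
    "F": 19,
    "Na": 23,
    "P": 31,
    "S": 32,
    "Cl": 35,
    "K": 39,
    "Fe": 56,
}

#: Mass added per positive charge under each adduct, by scale.
PROTON_MONO = 1.00783
PROTON_NOMINAL = 1
SODIUM_CATION_MONO = 22.98922  # Na atom minus one electron
SODIUM_CATION_NOMINAL = 23

_ADDUCTS = {
    "[M+H]+": (PROTON_MONO, PROTON_NOMINAL),
    "[M+Na]+": (SODIUM_CATION_MONO, SODIUM_CATION_NOMINAL),
}


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count record; the unit of all mass arithmetic.

    Counts are non-negative integers; unknown element symbols are rejected
    at construction.  Equality is element-wise (zero counts are dropped).
    """

    _items: tuple[tuple[str, int], ...] = ()

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
        clean = tuple(sorted((el, n) for el, n in items.items() if n > 0))
        object.__setattr__(self, "_items", clean)

    @property
    def counts(self) -> dict[str, int]:
        return dict(self._items)

    def __getitem__(self, element: str) -> int:
        return dict(self._items).get(element, 0)

    def __bool__(self) -> bool:
        return bool(self._items)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.counts
        for el, n in other._items:
            merged[el] = merged.get(el, 0) + n
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = self.counts
        for el, n in other._items:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for element {el}"
                )
        return ElementalFormula(merged)

    def monoisotopic(self) -> float:
        return sum(n * ATOMIC_MASS[el] for el, n in self._items)

    def nominal(self) -> int:
        return sum(n * MASS_NUMBER[el] for el, n in self._items)

    def hill(self) -> str:
        """Canonical Hill-order serialization (C, H, then alphabetical)."""
        counts = self.counts
        parts: list[str] = []
        order: list[str] = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(el for el in counts if el not in ("C", "H"))
        else:
            order = sorted(counts)
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


# Common small molecules used in peptide bookkeeping.
WATER = ElementalFormula({"H": 2, "O": 1})
HYDROGEN = ElementalFormula({"H": 1})
HF = ElementalFormula({"H": 1, "F": 1})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string such as ``"C43H73N10O23"``.

    A cleanup pass strips underscore/asterisk decorations (as found in
    typeset manuscripts, e.g. ``"C_43_H_73_N_10_O_23_"``) and whitespace.
    Counts of 1 may be omitted.  Raises :class:`FormulaError` naming the
    offending span on malformed input.
    """
    cleaned = re.sub(r"[\s_*]", "", text)
    if not cleaned:
        raise FormulaError(f"empty formula string {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unparseable token at {cleaned[pos:pos + 4]!r}"
            )
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaError(f"malformed formula {text!r}: unknown element {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula) -> float:
    """Monoisotopic (principal-isotope) mass in Da."""
    return f.monoisotopic()


def nominal_mass(f: ElementalFormula) -> int:
    """Integer nominal mass (mass-number sum) in Da."""
    return f.nominal()


def formula_arith(
    a: ElementalFormula, b: ElementalFormula, op: Literal["add", "subtract"]
) -> ElementalFormula:
    """Element-wise formula addition or subtraction.

    Subtraction raises :class:`FormulaError` if any count would go negative.
    """
    if op == "add":
        return a + b
    if op == "subtract":
        return a - b
    raise ValueError(f"op must be 'add' or 'subtract', got {op!r}")


@dataclass(frozen=True)
class MassMode:
    """Mass scale plus the per-charge mass convention.

    ``monoisotopic`` adds the neutral-H atomic mass (1.00783) per proton;
    ``nominal`` adds exactly 1.
    """

    mode: Literal["monoisotopic", "nominal"] = "nominal"

    @property
    def proton(self) -> float:
        return PROTON_MONO if self.mode == "monoisotopic" else PROTON_NOMINAL

    def mass(self, f: ElementalFormula) -> float:
        return f.monoisotopic() if self.mode == "monoisotopic" else f.nominal()


MONOISOTOPIC = MassMode("monoisotopic")
NOMINAL = MassMode("nominal")


def adduct_mz(
    neutral: ElementalFormula, adduct: str, mode: MassMode = NOMINAL
) -> float:
    """m/z of a singly charged adduct ([M+H]+ or [M+Na]+) of a neutral formula."""
    if adduct not in _ADDUCTS:
        raise ValueError(
            f"unsupported adduct {adduct!r}; supported: {sorted(_ADDUCTS)}"
        )
    mono, nom = _ADDUCTS[adduct]
    charge_mass = mono if mode.mode == "monoisotopic" else nom
    return mode.mass(neutral) + charge_mass


@dataclass(frozen=True)
class ResidueSpec:
    """An amino-acid residue (amino acid minus water) with stereo metadata.

    ``lactam_capable`` marks residues whose side chain carries an
    amine-bearing nitrogen able to close a C-terminal lactam (Orn and
    N(delta)-OH-Orn).
    """

    name: str
    code: str
    formula: ElementalFormula
    chiral_centers: tuple[str, ...] = ()
    allowed_configs: tuple[str, ...] = ()
    lactam_capable: bool = False

    @property
    def nominal(self) -> int:
        return self.formula.nominal()

    @property
    def monoisotopic(self) -> float:
        return self.formula.monoisotopic()

    @property
    def free_formula(self) -> ElementalFormula:
        """Formula of the free amino acid (residue + H2O)."""
        return self.formula + WATER

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "code": self.code,
            "formula": self.formula.hill(),
            "chiral_centers": list(self.chiral_centers),
            "allowed_configs": list(self.allowed_configs),
            "lactam_capable": self.lactam_capable,
        }


def _residue(name, code, formula, centers, configs, lactam=False):
    return ResidueSpec(
        name=name,
        code=code,
        formula=parse_formula(formula),
        chiral_centers=tuple(centers),
        allowed_configs=tuple(configs),
        lactam_capable=lactam,
    )


_BHA_CONFIGS = ("L-threo", "L-erythro", "D-threo", "D-erythro")

_BUILTIN_RESIDUES: tuple[ResidueSpec, ...] = (
    _residue("Gly", "G", "C2H3NO", (), ()),
    _residue("Ser", "S", "C3H5NO2", ("C2",), ("L", "D")),
    _residue("Thr", "T", "C4H7NO2", ("C2", "C3"), ("L", "D")),
    # allo-Thr shares the Thr formula; distinguished only by configuration.
    _residue("allo-Thr", "aT", "C4H7NO2", ("C2", "C3"), ("L-allo", "D-allo")),
    _residue("Asp", "D", "C4H5NO3", ("C2",), ("L", "D")),
    _residue("beta-OH-Asp", "bD", "C4H5NO4", ("C2", "C3"), _BHA_CONFIGS),
    _residue("Orn", "O", "C5H10N2O", ("C2",), ("L", "D"), lactam=True),
    _residue("N-OH-Orn", "hO", "C5H10N2O2", ("C2",), ("L", "D"), lactam=True),
)


def builtin_residue_table() -> list[ResidueSpec]:
    """The built-in residue table (fresh list; entries are immutable)."""
    return list(_BUILTIN_RESIDUES)


_BY_NAME = {r.name: r for r in _BUILTIN_RESIDUES}
_BY_NAME.update({r.code: r for r in _BUILTIN_RESIDUES})
# Common aliases seen in the siderophore literature.
_BY_NAME["b-OH-Asp"] = _BY_NAME["beta-OH-Asp"]
_BY_NAME["cyclo-N-OH-Orn"] = _BY_NAME["N-OH-Orn"]
_BY_NAME["N(d)-OH-Orn"] = _BY_NAME["N-OH-Orn"]


def residue_by_name(name: str) -> ResidueSpec:
    """Look up a built-in residue by name, code, or common alias."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown residue {name!r}; known: {sorted(r.name for r in _BUILTIN_RESIDUES)}"
        ) from None


@dataclass(frozen=True)
class AcylSpec:
    """A fatty-acyl group in acyl form (fatty acid minus OH).

    The formula follows CnH(2n-2d-1)O(1+h) for n carbons, d double bonds and
    h hydroxyl substituents; joining the acyl to a peptide N-terminus then
    replaces the amine H whose mass would otherwise appear in the b series.
    """

    carbon_count: int
    double_bonds: tuple[tuple[int, str], ...] = ()
    hydroxyls: tuple[int, ...] = ()

    def __post_init__(self):
        n = self.carbon_count
        if n < 2:
            raise ValueError("acyl chain needs at least 2 carbons")
        for pos, geom in self.double_bonds:
            if not (2 <= pos < n):
                raise ValueError(f"double-bond position {pos} outside chain C2..C{n - 1}")
            if geom not in ("Z", "E"):
                raise ValueError(f"double-bond geometry must be 'Z' or 'E', got {geom!r}")
        for pos in self.hydroxyls:
            if not (2 <= pos <= n):
                raise ValueError(f"hydroxyl position {pos} outside chain C2..C{n}")

    @property
    def formula(self) -> ElementalFormula:
        n, d, h = self.carbon_count, len(self.double_bonds), len(self.hydroxyls)
        return ElementalFormula({"C": n, "H": 2 * n - 2 * d - 1, "O": 1 + h})

    @property
    def nominal(self) -> int:
        return self.formula.nominal()

    @property
    def monoisotopic(self) -> float:
        return self.formula.monoisotopic()

    def describe(self) -> str:
        tags = []
        for pos in self.hydroxyls:
            tags.append(f"{pos}-OH")
        for pos, geom in self.double_bonds:
            tags.append(f"{pos}{geom}")
        base = f"C{self.carbon_count}:{len(self.double_bonds)}"
        return f"{base}({','.join(tags)})" if tags else base

    def to_dict(self) -> dict:
        return {
            "carbon_count": self.carbon_count,
            "double_bonds": [list(db) for db in self.double_bonds],
            "hydroxyls": list(self.hydroxyls),
            "formula": self.formula.hill(),
        }


def acyl_from_description(
    carbons: int,
    double_bonds: Sequence[tuple[int, str]] = (),
    hydroxyls: Sequence[int] = (),
) -> AcylSpec:
    """Build an :class:`AcylSpec` from chain length, unsaturations and hydroxyls."""
    return AcylSpec(
        carbon_count=carbons,
        double_bonds=tuple((int(p), g) for p, g in double_bonds),
        hydroxyls=tuple(int(p) for p in hydroxyls),
    )


def stereo_label(configuration: str, name: str) -> str:
    """Human-readable '<config>-<residue>' label without duplicated qualifiers.

    ``stereo_label("D-allo", "allo-Thr")`` gives ``"D-allo-Thr"``.
    """
    if not configuration or configuration in ("achiral", "unknown", "unresolved"):
        return name
    tail = configuration.split("-")[-1]
    if name.startswith(f"{tail}-"):
        return f"{configuration}{name[len(tail):]}"
    return f"{configuration}-{name}"


def residue_table_json(table: Sequence[ResidueSpec] | None = None) -> str:
    """Serialize a residue table as JSON (name, code, formula, configs)."""
    return json.dumps([r.to_dict() for r in (table or _BUILTIN_RESIDUES)], indent=2)
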