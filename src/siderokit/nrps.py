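"""NRPS domain-architecture parsing and condensation-domain stereochemistry.

A nonribosomal peptide synthetase is a modular assembly line: a loading
module primes the starter unit (here a fatty acyl group via FAAL-ACP), and
each extension module selects one amino acid (A domain), tethers it (PCP)
and condenses it onto the growing chain (C domain); a terminal TE releases
the product.  Clusters of this class carry no stand-alone epimerization
domains — instead dual-function condensation domains (C_Dual) epimerize
their donor residue, so the configuration of the residue loaded by module i
is deduced from the subtype of the C domain in module i+1:

    C_Dual  =>  D        (epimerizes the donor during condensation)
    C_LCL   =>  L        (L donor, L acceptor)
    C_DCL   =>  D        (expects a D donor — but supplies no epimerase
                          itself, so with no upstream epimerization activity
                          the D expectation is recorded as a conflict)
    Gly     =>  achiral
    terminal residue (no downstream C)  =>  L, marked "assumed"

Beta-hydroxylation of Asp residues is carried out by TauD-family
dioxygenases — either fused into a C domain (acting on the Asp of the
adjacent module) or stand-alone — whose 3R/3S product class, combined with
the backbone C2 configuration, fixes the threo/erythro diastereomer:
(2S,3S) = L-threo, (2S,3R) = L-erythro, (2R,3R) = D-threo,
(2R,3S) = D-erythro.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "Domain",
    "Module",
    "ModuleArchitecture",
    "BackbonePrediction",
    "PredictedResidue",
    "HydroxylaseContext",
    "ReconcileReport",
    "parse_domain_string",
    "predict_backbone",
    "assign_hydroxylation",
    "reconcile",
    "DIASTEREOMER_NAMES",
]

C_FAMILY = ("C", "C_LCL", "C_DCL", "C_DUAL")
_KNOWN = ("FAAL", "ACP", "PCP", "TE", "TAUD") + C_FAMILY

#: (C2, C3) pair -> diastereomer label for beta-hydroxylated residues.
DIASTEREOMER_NAMES = {
    ("2S", "3S"): "L-threo",
    ("2S", "3R"): "L-erythro",
    ("2R", "3R"): "D-threo",
    ("2R", "3S"): "D-erythro",
}

_CANONICAL = {
    "FAAL": "FAAL",
    "ACP": "ACP",
    "PCP": "PCP",
    "TE": "TE",
    "TAUD": "TauD",
    "C": "C",
    "C_LCL": "C_LCL",
    "C_DCL": "C_DCL",
    "C_DUAL": "C_Dual",
}


class DomainParseError(ValueError):
    """Raised for unrecognizable domain tokens, with their position."""


@dataclass(frozen=True)
class Domain:
    """One catalytic domain; A domains carry their substrate."""

    kind: str
    substrate: str = ""

    def token(self) -> str:
        if self.kind == "A":
            return f"A_{self.substrate}_"
        return _CANONICAL[self.kind.upper()]


@dataclass(frozen=True)
class Module:
    """An ordered run of domains forming one module of the assembly line."""

    domains: tuple[Domain, ...]

    def kinds(self) -> tuple[str, ...]:
        return tuple(d.kind for d in self.domains)

    @property
    def a_substrate(self) -> Optional[str]:
        for d in self.domains:
            if d.kind == "A":
                return d.substrate
        return None

    @property
    def c_subtype(self) -> Optional[str]:
        """Subtype of the condensation domain opening this module.

        An interrupted C (C-TauD-C) reports the plain subtype "C"; the
        fused TauD is exposed via :attr:`has_fused_taud`.
        """
        for d in self.domains:
            if d.kind.upper() in C_FAMILY:
                return _CANONICAL[d.kind.upper()]
        return None

    @property
    def has_fused_taud(self) -> bool:
        kinds = [k.upper() for k in self.kinds()]
        return "TAUD" in kinds and any(k in C_FAMILY for k in kinds)

    @property
    def has_te(self) -> bool:
        return any(d.kind.upper() == "TE" for d in self.domains)


@dataclass(frozen=True)
class ModuleArchitecture:
    """A parsed assembly line: one loading module plus extension modules."""

    loading: Module
    extensions: tuple[Module, ...]
    provenance: str = ""
    warnings: tuple[str, ...] = ()

    @property
    def n_extensions(self) -> int:
        return len(self.extensions)

    def to_string(self) -> str:
        toks = [d.token() for d in self.loading.domains]
        for m in self.extensions:
            toks.extend(d.token() for d in m.domains)
        return "-".join(toks)


def _parse_token(tok: str, position: int) -> Domain:
    clean = tok.strip().strip("_*")
    if not clean:
        raise DomainParseError(f"empty domain token at position {position}")
    up = clean.upper()
    # A domain with substrate: A_Asp_, A(Asp), Aasp not accepted
    m = re.fullmatch(r"A[_(]?([A-Za-z][A-Za-z0-9-]*)?\)?_?", clean, flags=re.IGNORECASE)
    if up.startswith("A") and up not in _KNOWN and up != "ACP" and m and m.group(1):
        sub = m.group(1)
        return Domain(kind="A", substrate=sub[0].upper() + sub[1:].lower())
    if up in _KNOWN:
        return Domain(kind=_CANONICAL[up])
    raise DomainParseError(
        f"unknown domain token {tok!r} at position {position}"
    )


def parse_domain_string(text: str, provenance: str = "") -> ModuleArchitecture:
    """Parse a hyphen-separated domain string into modules.

    Module segmentation: the loading module is everything before the first
    condensation-family domain; each extension module starts at a C-family
    domain, except that a second C directly continuing an interrupted
    condensation domain (C-TauD-C) stays in the same module.  Tokens are
    case-insensitive; A-domain substrates appear as ``A_Xxx_`` or
    ``A(Xxx)``.  Unknown tokens raise :class:`DomainParseError`; an A
    domain without a PCP in its module is recorded as a structural warning.
    """
    raw = [t for t in text.replace(" ", "").split("-") if t != ""]
    if not raw:
        raise DomainParseError("empty domain string")
    domains = [_parse_token(tok, i + 1) for i, tok in enumerate(raw)]

    loading: list[Domain] = []
    modules: list[list[Domain]] = []
    current: Optional[list[Domain]] = None
    for d in domains:
        is_c = d.kind.upper() in C_FAMILY
        if current is None:
            if is_c:
                current = [d]
                modules.append(current)
            else:
                loading.append(d)
            continue
        if is_c:
            has_a = any(x.kind == "A" for x in current)
            has_c = any(x.kind.upper() in C_FAMILY for x in current)
            if has_c and not has_a:
                current.append(d)  # interrupted C continues (C-TauD-C)
            else:
                current = [d]
                modules.append(current)
        else:
            current.append(d)

    warnings = []
    ext = tuple(Module(domains=tuple(m)) for m in modules)
    for i, m in enumerate(ext, start=1):
        if m.a_substrate is not None and "PCP" not in [k.upper() for k in m.kinds()]:
            warnings.append(f"extension module {i}: A domain without PCP")
        if m.has_te and i != len(ext):
            warnings.append(f"extension module {i}: TE before the last module")
    load_mod = Module(domains=tuple(loading))
    if any(d.kind == "A" and d.substrate for d in loading):
        warnings.append("loading module carries an amino-acid A domain")
    return ModuleArchitecture(
        loading=load_mod,
        extensions=ext,
        provenance=provenance,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class PredictedResidue:
    """One backbone position: substrate, configuration and hydroxylation."""

    position: int  # 1-based from the N-terminus
    substrate: str
    configuration: str  # L | D | achiral | unresolved
    rule: str  # which rule fired
    assumed: bool = False
    hydroxylation: str = ""  # e.g. "beta-OH (L-threo, predicted)"

    def label(self) -> str:
        base = self.substrate
        if self.hydroxylation:
            base = f"beta-OH-{base}" if not base.startswith("beta-OH") else base
        if self.configuration in ("achiral", "unresolved"):
            return base
        return f"{self.configuration}-{base}"


@dataclass(frozen=True)
class BackbonePrediction:
    """Predicted peptide backbone with per-position rule provenance."""

    residues: tuple[PredictedResidue, ...]
    conflicts: tuple[str, ...] = ()
    conflict_positions: tuple[int, ...] = ()

    def configurations(self) -> tuple[str, ...]:
        return tuple(r.configuration for r in self.residues)


_ACHIRAL_SUBSTRATES = {"Gly"}


def predict_backbone(arch: ModuleArchitecture) -> BackbonePrediction:
    """Deduce backbone configurations from downstream C-domain subtypes.

    Total and deterministic on any parseable architecture: every position
    receives a configuration, an explicit rule citation, and C_DCL-derived
    D expectations are carried as conflicts rather than silently trusted
    (a C_DCL has no epimerase activity of its own, so without upstream
    epimerization machinery its D donor expectation is unsupported).
    """
    residues = []
    conflicts = []
    conflict_positions = []
    n = arch.n_extensions
    for i, module in enumerate(arch.extensions, start=1):
        substrate = module.a_substrate or "?"
        if substrate in _ACHIRAL_SUBSTRATES:
            residues.append(
                PredictedResidue(i, substrate, "achiral", rule="achiral substrate")
            )
            continue
        if i == n:
            residues.append(
                PredictedResidue(
                    i, substrate, "L", rule="terminal residue: no downstream C; default L",
                    assumed=True,
                )
            )
            continue
        downstream = arch.extensions[i].c_subtype  # C of module i+1
        if downstream == "C_Dual":
            cfg, rule = "D", "downstream C_Dual epimerizes donor => D"
        elif downstream == "C_LCL":
            cfg, rule = "L", "downstream C_LCL => L donor"
        elif downstream == "C_DCL":
            cfg, rule = "D", "downstream C_DCL expects D donor"
            conflicts.append(
                f"position {i}: C_DCL in module {i + 1} expects a D donor but no "
                f"epimerization activity acts on this residue; D is unsupported"
            )
            conflict_positions.append(i)
        else:
            cfg, rule = "unresolved", f"downstream C subtype {downstream!r} carries no stereo rule"
        residues.append(PredictedResidue(i, substrate, cfg, rule=rule))
    return BackbonePrediction(
        residues=tuple(residues),
        conflicts=tuple(conflicts),
        conflict_positions=tuple(conflict_positions),
    )


@dataclass(frozen=True)
class HydroxylaseContext:
    """TauD-family beta-hydroxylases available to the cluster.

    ``standalone`` maps enzyme name -> stereo class ("3R"/"3S"/"unknown");
    ``fused`` maps extension-module index -> stereo class of the TauD
    domain fused into that module's C domain.
    """

    standalone: tuple[tuple[str, str], ...] = ()
    fused: tuple[tuple[int, str], ...] = ()

    def __post_init__(self):
        for _, cls in tuple(self.standalone) + tuple(self.fused):
            if cls not in ("3R", "3S", "unknown"):
                raise ValueError(f"stereo class must be 3R/3S/unknown, got {cls!r}")


def _diastereomer(configuration: str, c3_class: str) -> str:
    c2 = {"L": "2S", "D": "2R"}.get(configuration)
    c3 = {"3R": "3R", "3S": "3S"}.get(c3_class)
    if c2 is None or c3 is None:
        return "diastereomer unknown"
    return DIASTEREOMER_NAMES[(c2, c3)]


def assign_hydroxylation(
    arch: ModuleArchitecture,
    pred: BackbonePrediction,
    ctx: HydroxylaseContext,
) -> BackbonePrediction:
    """Annotate Asp positions with predicted beta-hydroxylation diastereomers.

    A TauD domain fused into a module's C domain hydroxylates the Asp loaded
    by that module; remaining Asp positions are assigned the stand-alone
    hydroxylase classes in order.  Asp positions beyond the available
    hydroxylases are annotated "beta-OH, diastereomer unknown".  All
    annotations are marked predicted — the division of labor between
    hydroxylases is inferred, not enzymatically demonstrated.
    """
    fused_by_module = dict(ctx.fused)
    standalone_classes = [cls for _, cls in ctx.standalone]
    asp_positions = [r.position for r in pred.residues if r.substrate == "Asp"]
    annotations: dict[int, str] = {}
    remaining = []
    for pos in asp_positions:
        if pos in fused_by_module:
            annotations[pos] = fused_by_module[pos]
        else:
            remaining.append(pos)
    for pos, cls in zip(remaining, standalone_classes):
        annotations[pos] = cls
    out = []
    for r in pred.residues:
        if r.position in annotations:
            cls = annotations[r.position]
            dia = _diastereomer(r.configuration, cls)
            out.append(
                replace(r, hydroxylation=f"beta-OH ({dia}, predicted)")
            )
        elif r.substrate == "Asp" and ctx.standalone + ctx.fused:
            out.append(replace(r, hydroxylation="beta-OH, diastereomer unknown"))
        else:
            out.append(r)
    return BackbonePrediction(
        residues=tuple(out),
        conflicts=pred.conflicts,
        conflict_positions=pred.conflict_positions,
    )


@dataclass(frozen=True)
class ReconcileReport:
    """Comparison of a backbone prediction with a hydrolysate inventory."""

    verdict: str  # consistent | consistent_with_conflicts | inconsistent | vacuous
    deltas: tuple[tuple[str, str, int, int], ...]  # (family, config, predicted, observed)
    notes: tuple[str, ...] = ()


_FAMILY_ALIASES = {"allo-Thr": "Thr", "N-OH-Orn": "Orn", "cyclo-N-OH-Orn": "Orn"}


def _family(name: str) -> str:
    return _FAMILY_ALIASES.get(name, name)


def _base_config(cfg: str) -> str:
    return cfg.split("-")[0] if cfg else cfg


def reconcile(
    pred: BackbonePrediction,
    inventory: Sequence[tuple[str, str, int]],
) -> ReconcileReport:
    """Compare predicted vs observed configuration counts per residue family.

    Residues are grouped by family (allo-Thr with Thr, hydroxylated Asp as
    beta-OH-Asp) and by base configuration letter (D-allo -> D, L-threo ->
    L).  A count mismatch that disappears when flagged conflict positions
    are flipped yields the verdict ``consistent_with_conflicts``; an empty
    inventory is ``vacuous``.
    """
    if not inventory:
        return ReconcileReport(verdict="vacuous", deltas=(),
                               notes=("empty inventory: nothing to compare",))

    def predicted_counts(flip: frozenset[int]) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for r in pred.residues:
            fam = _family(r.substrate)
            if r.hydroxylation and fam == "Asp":
                fam = "beta-OH-Asp"
            cfg = _base_config(r.configuration)
            if r.position in flip and cfg in ("L", "D"):
                cfg = "L" if cfg == "D" else "D"
            counts[(fam, cfg)] = counts.get((fam, cfg), 0) + 1
        return counts

    observed: dict[tuple[str, str], int] = {}
    for name, cfg, count in inventory:
        key = (_family(name) if _family(name) != "Asp" else "Asp", _base_config(cfg))
        if name in ("beta-OH-Asp", "b-OH-Asp"):
            key = ("beta-OH-Asp", _base_config(cfg))
        observed[key] = observed.get(key, 0) + count

    def deltas_for(flip: frozenset[int]):
        p = predicted_counts(flip)
        keys = set(p) | set(observed)
        # achiral positions are not seen in chiral-derivative chromatography
        return tuple(
            (fam, cfg, p.get((fam, cfg), 0), observed.get((fam, cfg), 0))
            for fam, cfg in sorted(keys)
            if cfg not in ("achiral", "unresolved")
            and p.get((fam, cfg), 0) != observed.get((fam, cfg), 0)
        )

    plain = deltas_for(frozenset())
    if not plain:
        return ReconcileReport(verdict="consistent", deltas=())
    flipped = deltas_for(frozenset(pred.conflict_positions))
    if not flipped:
        return ReconcileReport(
            verdict="consistent_with_conflicts",
            deltas=plain,
            notes=tuple(pred.conflicts),
        )
    return ReconcileReport(
        verdict="inconsistent",
        deltas=plain,
        notes=tuple(pred.conflicts),
    )
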