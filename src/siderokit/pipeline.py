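"""End-to-end structure elucidation: chain the analysis stages into one report.

:func:`elucidate` mirrors how an acylated peptide siderophore is actually
worked up: the MS/MS ladder is decoded into candidate residues, a proposed
structure (if any) is validated against the observed peaks, Marfey tables
yield a configuration inventory, and the NRPS domain architecture supplies
a stereochemical backbone that is reconciled against that inventory.  Every
claim in the report carries its evidence source, and conflicting evidence
is a *result* (reported in the conflicts section), not a failure.

All positions in reports are 1-based from the N-terminus.
"""

from __future__ import annotations

from typing import Optional, Sequence

from . import __version__
from .denovo import decode_ladder, sequence_consistency
from .fragments import LipopeptideStructure, PeakList, match_peaks, y_ladder
from .marfey import (
    DEFAULT_ELUTION_RULES,
    MarfeyRecord,
    assign_by_rt,
    elution_order_call,
)
from .masscore import MassMode, NOMINAL
from .nrps import (
    HydroxylaseContext,
    assign_hydroxylation,
    parse_domain_string,
    predict_backbone,
    reconcile,
)

__all__ = ["elucidate"]


def _marfey_inventory(
    standards: Sequence[MarfeyRecord],
    hydrolysate: Sequence[MarfeyRecord],
    advanced: Optional[Sequence[dict]],
    rt_tol: float,
) -> tuple[list[tuple[str, str, int]], dict]:
    result = assign_by_rt(hydrolysate, standards, rt_tol)
    counts: dict[tuple[str, str], int] = {}
    for peak, std in result.assignments:
        key = (std.analyte, std.configuration)
        counts[key] = counts.get(key, 0) + peak.count
    advanced_calls = []
    for entry in advanced or []:
        rule = DEFAULT_ELUTION_RULES.get(
            entry["analyte"], DEFAULT_ELUTION_RULES["beta-OH-Asp"]
        )
        call = elution_order_call(entry["rt_l_fdla"], entry["rt_d_fdla"], rule)
        config = call["configuration"]
        if config in ("L", "D") and entry.get("diastereomer_class"):
            config = f"{config}-{entry['diastereomer_class']}"
        advanced_calls.append({**entry, "call": config})
        if config != "indeterminate":
            key = (entry["analyte"], config)
            counts[key] = counts.get(key, 0) + 1
    inventory = [(a, c, n) for (a, c), n in sorted(counts.items())]
    section = {
        "assigned": list(result.assigned_labels()),
        "unmatched_rt": [p.rt for p in result.unmatched],
        "ambiguous_rt": [p.rt for p, _ in result.ambiguous],
        "advanced_calls": advanced_calls,
        "inventory": [
            {"analyte": a, "configuration": c, "count": n} for a, c, n in inventory
        ],
    }
    return inventory, section


def _refine_configuration(
    substrate: str, config: str, inventory: Sequence[tuple[str, str, int]]
) -> str:
    """Upgrade a bare L/D call to a fuller inventory label when unambiguous."""
    if config not in ("L", "D"):
        return config
    family = {"allo-Thr": "Thr"}.get(substrate, substrate)
    matches = {
        c for a, c, _ in inventory
        if {"allo-Thr": "Thr"}.get(a, a) == family and c.split("-")[0] == config
    }
    if len(matches) == 1 and (full := matches.pop()) != config:
        return full
    return config


def elucidate(
    peaks: PeakList,
    precursor_mz: Optional[float] = None,
    marfey_standards: Optional[Sequence[MarfeyRecord]] = None,
    marfey_hydrolysate: Optional[Sequence[MarfeyRecord]] = None,
    advanced_marfey: Optional[Sequence[dict]] = None,
    domain_string: Optional[str] = None,
    hydroxylase_context: Optional[HydroxylaseContext] = None,
    proposal: Optional[LipopeptideStructure] = None,
    mode: MassMode = NOMINAL,
    tol: float = 0.5,
    rt_tol: float = 0.2,
    seed: Optional[int] = None,
) -> dict:
    """Run the elucidation chain on whatever evidence is supplied.

    Only the peak list is mandatory.  Returns a JSON-serializable report;
    see the module docstring for the evidence-merging rules.
    """
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "index_convention": "1-based from the N-terminus",
            "mass_mode": mode.mode,
            "tolerance_da": tol,
        },
        "conflicts": [],
    }

    # 1. de novo decoding of the y ladder (C to N)
    decoded = decode_ladder(
        peaks, tol=tol, series="y", mode=mode, terminal_convention="cyclized"
    )
    if not decoded.composite_terminal:
        decoded = decode_ladder(
            peaks, tol=tol, series="y", mode=mode, terminal_convention="free"
        )
    steps_n_to_c = list(reversed(decoded.steps))
    report["sequence"] = {
        "series": "y",
        "read_direction": "C to N, reported N to C",
        "steps_n_to_c": [
            {"delta": st.delta, "candidates": [list(g) for g in st.candidates]}
            for st in steps_n_to_c
        ],
        "composite_terminal": [list(p) for p in decoded.composite_terminal],
        "uniquely_decoded_steps": decoded.score,
        "evidence": "MS/MS y-series mass differences",
    }

    # 2. validation of a proposed structure against the observed peaks
    if proposal is not None:
        ladder = y_ladder(proposal, mode)
        matches = match_peaks(ladder, peaks)
        consistency = sequence_consistency(decoded, proposal)
        report["validation"] = {
            "proposal": proposal.sequence_str(),
            "matched": matches.n_matched,
            "ladder_size": len(ladder),
            "unmatched_indices": list(matches.unmatched_indices),
            "decoding_consistent": consistency.consistent,
            "mismatches": [list(m) for m in consistency.mismatches],
        }
        if precursor_mz is not None:
            from .fragments import precursor_mz as _prec

            theo = _prec(proposal, "[M+H]+", mode)
            report["validation"]["precursor_delta"] = precursor_mz - theo
        if not consistency.consistent:
            report["conflicts"].append(
                "MS/MS decoding disagrees with the proposed structure at "
                + ", ".join(f"position {m[0]}" for m in consistency.mismatches)
            )

    # 3. Marfey configuration inventory
    inventory: list[tuple[str, str, int]] = []
    if marfey_standards and marfey_hydrolysate:
        inventory, section = _marfey_inventory(
            marfey_standards, marfey_hydrolysate, advanced_marfey, rt_tol
        )
        report["marfey"] = {**section, "evidence": "Marfey derivative retention times"}

    # 4. NRPS backbone and reconciliation
    configurations: list[dict] = []
    if domain_string:
        arch = parse_domain_string(domain_string)
        pred = predict_backbone(arch)
        if hydroxylase_context is not None:
            pred = assign_hydroxylation(arch, pred, hydroxylase_context)
        recon = reconcile(pred, inventory) if inventory else None
        resolved_conflicts = (
            recon is not None and recon.verdict == "consistent_with_conflicts"
        )
        for r in pred.residues:
            config = r.configuration
            note = ""
            if r.position in pred.conflict_positions:
                if resolved_conflicts:
                    config = "L" if config == "D" else "D"
                    note = "flipped to match the hydrolysate inventory"
                else:
                    note = "C_DCL rule output, unsupported"
            if r.hydroxylation and "(" in r.hydroxylation:
                config = r.hydroxylation.split("(")[1].split(",")[0]
            else:
                config = _refine_configuration(r.substrate, config, inventory)
            configurations.append(
                {
                    "position": r.position,
                    "substrate": r.substrate,
                    "configuration": config,
                    "hydroxylation": r.hydroxylation,
                    "rule": r.rule,
                    "assumed": r.assumed,
                    "note": note,
                    "evidence": "NRPS C-domain architecture"
                    + (" + Marfey inventory" if inventory else ""),
                }
            )
        report["nrps"] = {
            "modules": 1 + arch.n_extensions,
            "extension_modules": arch.n_extensions,
            "warnings": list(arch.warnings),
            "backbone": [r.label() for r in pred.residues],
            "reconciliation": None
            if recon is None
            else {"verdict": recon.verdict,
                  "deltas": [list(d) for d in recon.deltas],
                  "notes": list(recon.notes)},
        }
        report["conflicts"].extend(pred.conflicts)
    else:
        n_positions = len(decoded.steps) + (
            2 if any(len(p) == 2 for p in decoded.composite_terminal) else 1
        )
        for pos in range(1, n_positions + 1):
            configurations.append(
                {"position": pos, "configuration": "unresolved",
                 "evidence": "no stereochemical evidence supplied"}
            )
    report["configurations"] = configurations
    return report
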