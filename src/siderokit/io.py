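"""File I/O for the dialects the analysis modules exchange.

Peak lists travel as two-column CSV (mz, intensity) or a minimal MGF
(BEGIN IONS / PEPMASS / END IONS, via pyteomics); Marfey tables as CSV
(analyte, configuration, reagent, rt, source); alignments as FASTA
(Biopython) with labels in a two-column TSV; trees as Newick with supports
as internal node labels (scikit-bio); ladders as TSV; structures and
reports as JSON.  Parse/serialize round trips are lossless for all of
these.  Malformed inputs raise ``ValueError`` naming the offending line or
column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf
from skbio import TreeNode

from .fragments import FragmentLadder, LipopeptideStructure, PeakList
from .marfey import MarfeyRecord
from .masscore import MassMode, acyl_from_description, residue_by_name
from .phylo import LabeledAlignment

__all__ = [
    "read_peaks_csv",
    "write_peaks_csv",
    "read_peaks_mgf",
    "write_peaks_mgf",
    "write_ladder_tsv",
    "read_marfey_csv",
    "write_marfey_csv",
    "read_alignment",
    "write_alignment",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_newick",
    "write_newick",
    "structure_to_dict",
    "structure_from_dict",
    "write_report",
    "validate_report",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------- peak lists

def read_peaks_csv(path, tolerance: float = 0.5) -> PeakList:
    df = pd.read_csv(path)
    _require_columns(df, ["mz"], path)
    inten = df["intensity"] if "intensity" in df.columns else [None] * len(df)
    peaks = tuple(
        (float(mz), None if pd.isna(i) else float(i))
        for mz, i in zip(df["mz"], inten)
    )
    return PeakList(peaks=peaks, tolerance=tolerance)


def write_peaks_csv(peaks: PeakList, path) -> None:
    df = pd.DataFrame(
        {"mz": [m for m, _ in peaks.peaks],
         "intensity": [i for _, i in peaks.peaks]}
    )
    df.to_csv(path, index=False)


def read_peaks_mgf(path, tolerance: float = 0.5) -> tuple[PeakList, Optional[float]]:
    """First spectrum of a minimal MGF file; returns (peaks, pepmass or None)."""
    with _mgf.read(str(path)) as reader:
        try:
            spec = next(iter(reader))
        except StopIteration:
            raise ValueError(f"{path}: no spectra found") from None
    mz = spec["m/z array"]
    inten = spec.get("intensity array")
    peaks = tuple(
        (float(m), float(i) if inten is not None and len(inten) else None)
        for m, i in zip(mz, inten if inten is not None and len(inten) else [0.0] * len(mz))
    )
    pepmass = spec["params"].get("pepmass", (None,))[0]
    return PeakList(peaks=peaks, tolerance=tolerance), pepmass


def write_peaks_mgf(peaks: PeakList, path, pepmass: Optional[float] = None,
                    title: str = "siderokit") -> None:
    spectrum = {
        "m/z array": [m for m, _ in peaks.peaks],
        "intensity array": [i if i is not None else 1.0 for _, i in peaks.peaks],
        "params": {"title": title, **({"pepmass": pepmass} if pepmass else {})},
    }
    with open(path, "w") as fh:
        _mgf.write([spectrum], fh)


def write_ladder_tsv(ladder: FragmentLadder, path) -> None:
    df = pd.DataFrame(
        {"series": ladder.series,
         "index": [i for i, _ in ladder.entries],
         "mz": [m for _, m in ladder.entries]}
    )
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- Marfey tables

_MARFEY_COLS = ["analyte", "configuration", "reagent", "rt", "source", "count"]


def read_marfey_csv(path) -> list[MarfeyRecord]:
    df = pd.read_csv(path).fillna("")
    _require_columns(df, ["reagent", "rt"], path)
    records = []
    for _, row in df.iterrows():
        records.append(
            MarfeyRecord(
                rt=float(row["rt"]),
                reagent=str(row["reagent"]),
                analyte=str(row.get("analyte", "") or ""),
                configuration=str(row.get("configuration", "") or ""),
                source=str(row.get("source", "") or "hydrolysate"),
                count=int(row["count"]) if str(row.get("count", "")).strip() else 1,
            )
        )
    return records


def write_marfey_csv(records: Sequence[MarfeyRecord], path) -> None:
    df = pd.DataFrame(
        [
            {"analyte": r.analyte, "configuration": r.configuration,
             "reagent": r.reagent, "rt": r.rt, "source": r.source,
             "count": r.count}
            for r in records
        ],
        columns=_MARFEY_COLS,
    )
    df.to_csv(path, index=False)


# ------------------------------------------------------- alignments & trees

def read_alignment(fasta_path, labels_path=None) -> LabeledAlignment:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"{fasta_path}: no FASTA records")
    sequences = tuple((r.id, str(r.seq).upper()) for r in records)
    labels = read_labels_tsv(labels_path) if labels_path else ()
    return LabeledAlignment(sequences=sequences, labels=tuple(labels))


def write_alignment(aln: LabeledAlignment, fasta_path, labels_path=None) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.sequences
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if labels_path:
        write_labels_tsv(aln.labels, labels_path)


def read_labels_tsv(path) -> tuple[tuple[str, str], ...]:
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "label"])
    if df.isna().any().any():
        raise ValueError(f"{path}: labels TSV needs two columns (name, label)")
    return tuple((str(n), str(l)) for n, l in zip(df["name"], df["label"]))


def write_labels_tsv(labels: Sequence[tuple[str, str]], path) -> None:
    pd.DataFrame(list(labels)).to_csv(path, sep="\t", index=False, header=False)


def read_newick(path) -> TreeNode:
    tree = TreeNode.read(str(path))
    tree.assign_supports()
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


# ------------------------------------------------------ structures & reports

def structure_to_dict(s: LipopeptideStructure) -> dict:
    d = {
        "residues": [{"name": r.name, "configuration": c} for r, c in s.residues],
        "c_terminal_cyclized": s.c_terminal_cyclized,
        "name": s.name,
    }
    if s.acyl is not None:
        d["acyl"] = s.acyl.to_dict()
    return d


def structure_from_dict(d: dict) -> LipopeptideStructure:
    residues = tuple(
        (residue_by_name(r["name"]), r.get("configuration", "unknown"))
        for r in d["residues"]
    )
    acyl = None
    if "acyl" in d and d["acyl"] is not None:
        a = d["acyl"]
        acyl = acyl_from_description(
            a["carbon_count"],
            [tuple(db) for db in a.get("double_bonds", [])],
            a.get("hydroxyls", []),
        )
    return LipopeptideStructure(
        residues=residues,
        acyl=acyl,
        c_terminal_cyclized=bool(d.get("c_terminal_cyclized", False)),
        name=d.get("name", ""),
    )


#: Keys every elucidation report must carry; indices are 1-based from the
#: N-terminus throughout.
REPORT_REQUIRED_KEYS = ("provenance", "sequence", "configurations", "conflicts")


def validate_report(report: dict) -> None:
    """Light structural validation of an elucidation report."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing required key(s): {', '.join(missing)}")
    prov = report["provenance"]
    for k in ("version", "seed", "index_convention"):
        if k not in prov:
            raise ValueError(f"report provenance missing {k!r}")


def write_report(report: dict, path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
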