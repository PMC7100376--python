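"""Synthetic inputs with the statistical structure each analysis stage assumes.

Every generator is a pure function of (config, rng): the same seed
reproduces the same structures, spectra, retention-time tables and protein
families byte for byte.  What is emulated, and what is not:

* :func:`random_lipopeptide` draws acylated peptides from the siderophore
  scaffold class (fatty-acyl tail, 5-12 residues from the nonproteinogenic
  residue table, optional C-terminal lactam).
* :func:`simulate_spectrum` degrades a theoretical fragment ladder with
  Bernoulli peak dropout, Gaussian m/z jitter and Poisson-distributed decoy
  peaks drawn uniformly on [100, precursor] — a deliberately simple null
  with no intensity model, isotope envelopes or chemical noise structure.
* :func:`simulate_marfey_tables` jitters hydrolysate retention times around
  the authentic-standard values.
* :func:`simulate_protein_family` evolves a two-clade protein family by
  per-site substitution from a common root: clade ancestors diverge at the
  between-clade probability, leaves at the within-clade probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fragments import FragmentLadder, LipopeptideStructure, PeakList, precursor_mz, y_ladder, b_ladder
from .marfey import MarfeyRecord
from .masscore import AcylSpec, MassMode, NOMINAL, ResidueSpec, acyl_from_description, builtin_residue_table
from .phylo import LabeledAlignment
from .presets import MARFEY_STANDARDS_C3

__all__ = [
    "SimConfig",
    "PhyloSimConfig",
    "SimulatedSpectrum",
    "default_acyl_pool",
    "random_lipopeptide",
    "simulate_spectrum",
    "simulate_marfey_tables",
    "simulate_protein_family",
]


def default_acyl_pool() -> tuple[AcylSpec, ...]:
    """Saturated, unsaturated and 3-hydroxylated C12/C14 acyl tails."""
    return (
        acyl_from_description(12, (), (3,)),
        acyl_from_description(12, ((5, "Z"),), ()),
        acyl_from_description(12, (), ()),
        acyl_from_description(14, ((7, "Z"),), ()),
    )


@dataclass(frozen=True)
class PhyloSimConfig:
    """Two-clade protein-family simulation parameters."""

    n_per_clade: int = 8
    seq_length: int = 300
    within_clade_sub_prob: float = 0.05
    between_clade_sub_prob: float = 0.4
    n_seeds: int = 20

    def __post_init__(self):
        if not (0 <= self.within_clade_sub_prob <= 1
                and 0 <= self.between_clade_sub_prob <= 1):
            raise ValueError("substitution probabilities must be in [0, 1]")
        if min(self.n_per_clade, self.seq_length, self.n_seeds) < 1:
            raise ValueError("phylo sizes must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation configuration; one seeded stream drives a run."""

    seed: int = 0
    n_structures: int = 10
    min_residues: int = 5
    max_residues: int = 12
    peak_dropout_prob: float = 0.1
    mz_jitter_sd: float = 0.1
    decoy_peak_rate: float = 3.0
    rt_jitter_sd: float = 0.05
    phylo: PhyloSimConfig = field(default_factory=PhyloSimConfig)

    def __post_init__(self):
        if not 0 <= self.peak_dropout_prob <= 1:
            raise ValueError("peak_dropout_prob must be in [0, 1]")
        if min(self.mz_jitter_sd, self.rt_jitter_sd) < 0:
            raise ValueError("jitter standard deviations must be >= 0")
        if self.decoy_peak_rate < 0:
            raise ValueError("decoy_peak_rate must be >= 0")
        if not 1 <= self.min_residues <= self.max_residues:
            raise ValueError("need 1 <= min_residues <= max_residues")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_lipopeptide(
    cfg: SimConfig,
    rng: np.random.Generator,
    residue_pool: Optional[Sequence[ResidueSpec]] = None,
    acyl_pool: Optional[Sequence[AcylSpec]] = None,
) -> LipopeptideStructure:
    """Uniformly sampled acylated peptide with per-residue configurations.

    The C-terminus is lactamized with probability 1/2 whenever the sampled
    terminal residue permits it.
    """
    residue_pool = (
        builtin_residue_table() if residue_pool is None else list(residue_pool)
    )
    acyl_pool = (
        list(default_acyl_pool()) if acyl_pool is None else list(acyl_pool)
    )
    if not residue_pool or not acyl_pool:
        raise ValueError("residue and acyl pools must be non-empty")
    n = int(rng.integers(cfg.min_residues, cfg.max_residues + 1))
    residues = []
    for _ in range(n):
        r = residue_pool[int(rng.integers(len(residue_pool)))]
        if r.allowed_configs:
            cfg_label = r.allowed_configs[int(rng.integers(len(r.allowed_configs)))]
        else:
            cfg_label = "achiral"
        residues.append((r, cfg_label))
    acyl = acyl_pool[int(rng.integers(len(acyl_pool)))]
    cyclize = bool(residues[-1][0].lactam_capable and rng.random() < 0.5)
    return LipopeptideStructure(
        residues=tuple(residues),
        acyl=acyl,
        c_terminal_cyclized=cyclize,
        name="synthetic",
    )


@dataclass(frozen=True)
class SimulatedSpectrum:
    """A noisy peak list with its ground-truth provenance retained."""

    peaks: PeakList
    truth: FragmentLadder
    structure: LipopeptideStructure
    dropped_indices: tuple[int, ...]
    decoys: tuple[float, ...]


def simulate_spectrum(
    s: LipopeptideStructure,
    cfg: SimConfig,
    rng: np.random.Generator,
    series: str = "y",
    mode: MassMode = NOMINAL,
    tolerance: float = 0.5,
) -> SimulatedSpectrum:
    """Theoretical ladder peaks minus dropout, plus jitter and decoys."""
    ladder = y_ladder(s, mode) if series == "y" else b_ladder(s, mode)
    kept = []
    dropped = []
    for idx, mz in ladder.entries:
        if rng.random() < cfg.peak_dropout_prob:
            dropped.append(idx)
        else:
            jitter = rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd else 0.0
            kept.append(mz + jitter)
    n_decoys = int(rng.poisson(cfg.decoy_peak_rate))
    prec = precursor_mz(s, "[M+H]+", mode)
    decoys = tuple(float(x) for x in rng.uniform(100.0, prec, size=n_decoys))
    all_mz = sorted(kept + list(decoys))
    peaks = PeakList.from_mz(all_mz, tolerance=tolerance) if all_mz else PeakList(
        (), tolerance=tolerance
    )
    return SimulatedSpectrum(
        peaks=peaks,
        truth=ladder,
        structure=s,
        dropped_indices=tuple(dropped),
        decoys=decoys,
    )


def simulate_marfey_tables(
    truth_inventory: Sequence[tuple[str, str]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[MarfeyRecord], list[MarfeyRecord]]:
    """Standards at base retention times; hydrolysate peaks jittered around them.

    ``truth_inventory`` lists (analyte, configuration) pairs present in the
    hydrolysate; every entry must exist in the base standards table.
    Returns (standards, hydrolysate).
    """
    base = {(a, c): (rg, rt) for a, c, rg, rt in MARFEY_STANDARDS_C3}
    standards = [
        MarfeyRecord(rt=rt, reagent=rg, analyte=a, configuration=c, source="standard")
        for a, c, rg, rt in MARFEY_STANDARDS_C3
    ]
    hydrolysate = []
    for analyte, config in truth_inventory:
        if (analyte, config) not in base:
            raise KeyError(f"({analyte}, {config}) not in the base standards table")
        reagent, rt = base[(analyte, config)]
        jitter = rng.normal(0.0, cfg.rt_jitter_sd) if cfg.rt_jitter_sd else 0.0
        rt_obs = max(rt + jitter, 0.01)
        hydrolysate.append(MarfeyRecord(rt=rt_obs, reagent=reagent))
    return standards, hydrolysate


_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        choices = _AA20[_AA20 != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return out


def simulate_protein_family(
    phylo: PhyloSimConfig,
    rng: np.random.Generator,
    n_queries_per_clade: int = 1,
) -> tuple[LabeledAlignment, dict[str, str]]:
    """Two labeled subclades (3R/3S) plus query sequences of known origin.

    A uniform-random root sequence spawns two clade ancestors at the
    between-clade substitution probability; reference leaves and queries
    derive from their ancestor at the within-clade probability.  Returns
    the alignment (queries labeled "query") and the truth map
    query name -> clade label.
    """
    root = _AA20[rng.integers(len(_AA20), size=phylo.seq_length)]
    ancestors = {
        "3R": _mutate(root, phylo.between_clade_sub_prob, rng),
        "3S": _mutate(root, phylo.between_clade_sub_prob, rng),
    }
    sequences = []
    labels = []
    truth = {}
    for clade in ("3R", "3S"):
        for k in range(phylo.n_per_clade):
            name = f"ref_{clade}_{k + 1}"
            leaf = _mutate(ancestors[clade], phylo.within_clade_sub_prob, rng)
            sequences.append((name, "".join(leaf)))
            labels.append((name, clade))
    for clade in ("3R", "3S"):
        for k in range(n_queries_per_clade):
            name = f"query_{clade}_{k + 1}"
            leaf = _mutate(ancestors[clade], phylo.within_clade_sub_prob, rng)
            sequences.append((name, "".join(leaf)))
            labels.append((name, "query"))
            truth[name] = clade
    return LabeledAlignment(sequences=tuple(sequences), labels=tuple(labels)), truth
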