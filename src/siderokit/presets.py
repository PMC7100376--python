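"""Pinned reference inputs: the potashchelin A-D structures and assay tables.

Potashchelins A-D are acylated nonapeptide siderophores from the halophile
*Halomonas* sp. MG34.  All four share the headgroup

    beta-OH-Asp - Ser - Gly - Ser - Ser - beta-OH-Asp - Thr - Ser -
    cyclo-N(delta)-OH-Orn

and differ only in the fatty-acyl tail: 3-hydroxydodecanoyl (A),
(Z)-dodec-5-enoyl (B), dodecanoyl (C) and (Z)-tetradec-7-enoyl (D).
These fixtures, together with the published Marfey retention-time tables
and the NRPS domain string of the ptc gene cluster, are the worked example
every analysis module is exercised against.
"""

from __future__ import annotations

from .fragments import LipopeptideStructure
from .masscore import acyl_from_description, residue_by_name

__all__ = [
    "potashchelin",
    "POTASHCHELIN_NAMES",
    "MARFEY_STANDARDS_C3",
    "MARFEY_HYDROLYSATE_C3",
    "MARFEY_HYDROLYSATE_COUNTS",
    "ADVANCED_MARFEY_ERYTHRO_RT",
    "PTC_DOMAIN_STRING",
    "PTC_HYDROXYLASE_CONTEXT",
    "MARFEY_INVENTORY",
]

POTASHCHELIN_NAMES = ("A", "B", "C", "D")

# Headgroup shared by all four compounds, N- to C-terminal, with the
# configurations established by Marfey analysis and partial hydrolysis.
_HEADGROUP = (
    ("beta-OH-Asp", "L-threo"),
    ("Ser", "D"),
    ("Gly", "achiral"),
    ("Ser", "D"),
    ("Ser", "L"),
    ("beta-OH-Asp", "L-erythro"),
    ("allo-Thr", "D-allo"),
    ("Ser", "L"),
    ("N-OH-Orn", "L"),
)

_ACYLS = {
    "A": ((12, (), (3,)), "3-hydroxydodecanoyl"),
    "B": ((12, ((5, "Z"),), ()), "(Z)-dodec-5-enoyl"),
    "C": ((12, (), ()), "dodecanoyl"),
    "D": ((14, ((7, "Z"),), ()), "(Z)-tetradec-7-enoyl"),
}


def potashchelin(which: str = "A", with_configs: bool = True) -> LipopeptideStructure:
    """The pinned structure of potashchelin A, B, C or D.

    With ``with_configs=False`` every configuration label is "unknown",
    which is how the structure looks before stereochemical analysis.
    """
    which = which.upper()
    if which not in _ACYLS:
        raise KeyError(f"unknown potashchelin {which!r}; choose from {POTASHCHELIN_NAMES}")
    (carbons, dbs, ohs), _ = _ACYLS[which]
    residues = tuple(
        (residue_by_name(name), cfg if with_configs else "unknown")
        for name, cfg in _HEADGROUP
    )
    return LipopeptideStructure(
        residues=residues,
        acyl=acyl_from_description(carbons, dbs, ohs),
        c_terminal_cyclized=True,
        name=f"potashchelin {which}",
    )


# C3 Marfey standards: (analyte, configuration, reagent, retention time / min).
MARFEY_STANDARDS_C3 = (
    ("Ser", "L", "L-FDAA", 9.4),
    ("Ser", "D", "L-FDAA", 10.6),
    ("Orn", "L", "L-FDAA", 3.7),
    ("Orn", "D", "L-FDAA", 3.3),
    ("beta-OH-Asp", "L-threo", "L-FDAA", 6.0),
    ("beta-OH-Asp", "D-threo", "L-FDAA", 5.5),
    ("allo-Thr", "L-allo", "L-FDAA", 11.7),
    ("allo-Thr", "D-allo", "L-FDAA", 15.4),
)

# Retention times observed for the FDAA-derivatized total hydrolysate of the
# potashchelins.  The 10.1-min peak is the erythro-beta-OH-Asp derivative,
# for which no authentic standard exists; it stays unmatched at this stage
# and is resolved by the advanced (two-reagent) method below.
MARFEY_HYDROLYSATE_C3 = (3.7, 6.0, 9.4, 10.1, 10.6, 15.4)

# Residue multiplicity per hydrolysate peak (from peak integration): the
# nonapeptide carries two L-Ser and two D-Ser.
MARFEY_HYDROLYSATE_COUNTS = {9.4: 2, 10.6: 2}

# Advanced Marfey retention times for the erythro-beta-OH-Asp hydrolysate
# peak: L-FDLA derivative 10.5 min, D-FDLA derivative 10.0 min.
ADVANCED_MARFEY_ERYTHRO_RT = {"L-FDLA": 10.5, "D-FDLA": 10.0}

# NRPS domain string of the potashchelin (ptc) assembly line, PtcB-PtcF.
PTC_DOMAIN_STRING = (
    "FAAL-ACP-C-TauD-C-A_Asp_-PCP-"
    "C_LCL_-A_ser_-PCP-"
    "C_Dual_-A_Gly_-PCP-"
    "C_LCL_-A_Ser_-PCP-"
    "C_Dual_-A_Ser_-PCP-"
    "C_LCL_-A_Asp_-PCP-"
    "C_LCL_-A_Thr_-PCP-"
    "C_Dual_-A_Ser_-PCP-"
    "C_DCL_-A_Orn_-PCP-TE"
)

# Beta-hydroxylase context of the ptc cluster: the stand-alone TauD-family
# enzyme PtcA sits in the 3R clade of the hydroxylase phylogeny, while the
# TauD domain fused into PtcB (extension module 1) sits in the 3S clade.
PTC_HYDROXYLASE_CONTEXT = {
    "standalone": {"PtcA": "3R"},
    "fused": {1: "3S"},
}

# Residue/configuration inventory established by the Marfey analyses.
MARFEY_INVENTORY = (
    ("Ser", "L", 2),
    ("Ser", "D", 2),
    ("Orn", "L", 1),
    ("allo-Thr", "D-allo", 1),
    ("beta-OH-Asp", "L-threo", 1),
    ("beta-OH-Asp", "L-erythro", 1),
)
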