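"""Reference data for the miR-31 hairpin screening campaign.

The construct is the pre-miR-31 hairpin spanning residues 20-52
(5'-GGCAUAGCUGUUGAACUGGGAACCUGCUAUGCC-3'), whose stem closes around a
dicing-site bulge connected through a junction of base pairs to the apical
loop.  Only adenosines and cytosines are isotopically labelled, so the
observable aromatic HSQC correlations are C2-H2/C8-H8 (A) and C6-H6 (C).

This module also encodes the per-compound outcomes of the 40-compound
screening campaign against this hairpin (STD-NMR, fluorescence indicator
displacement, and HSQC follow-up), which the integration stage consumes.
Seventeen roster members were not individually named in the assay
summaries; they are carried as placeholder ids X01-X17 with the outcomes
(no usable proton spectrum, no fluorescence change) that reproduce every
reported count: 22/40 STD-testable, 7 STD binders, 4 FID hits, 11
fluorescence increases, 25 no-change compounds.
"""

from __future__ import annotations

__all__ = [
    "HAIRPIN_SEQUENCE",
    "FIRST_RESIDUE",
    "residue_labels",
    "REGION_ANNOTATION",
    "ROSTER",
    "STD_BINDERS",
    "STD_TESTABLE",
    "FID_HITS",
    "FID_INCREASE",
    "DYE_INTERACTION",
    "RNA_INTERACTION",
    "HSQC_SPECIFIC",
    "HSQC_NON_SPECIFIC",
    "HSQC_WEAK_OR_NONE",
    "TABLE_KD_UM",
]

#: miR-31 hairpin construct, residues 20-52 (5'->3').
HAIRPIN_SEQUENCE = "GGCAUAGCUGUUGAACUGGGAACCUGCUAUGCC"
FIRST_RESIDUE = 20


def residue_labels(labelled_only: bool = True) -> list[str]:
    """Residue labels like ``A40``; by default only the labelled A/C residues."""
    out = []
    for i, nt in enumerate(HAIRPIN_SEQUENCE):
        if labelled_only and nt not in "AC":
            continue
        out.append(f"{nt}{FIRST_RESIDUE + i}")
    return out


def _region_of(num: int) -> str:
    if 33 <= num <= 38:
        return "apical_loop"
    if num in (31, 32, 39, 40, 41):
        return "junction"
    if num in (28, 29, 30, 42, 43, 44):
        return "dicing_site"
    return "stem"


#: residue label -> secondary-structure region of the hairpin.
REGION_ANNOTATION = {
    f"{nt}{FIRST_RESIDUE + i}": _region_of(FIRST_RESIDUE + i)
    for i, nt in enumerate(HAIRPIN_SEQUENCE)
}

# ---------------------------------------------------------------------------
# Screening-campaign outcomes (40-compound roster).

_NAMED = [
    "A1", "A5", "A9", "A10", "A11",
    "B1", "B5", "B6", "B7", "B9", "B11", "B12",
    "C1", "C3", "C4", "C6", "C7", "C11",
    "DA1", "DA2", "RA1", "RA3", "RA4",
]
_PLACEHOLDERS = [f"X{i:02d}" for i in range(1, 18)]

#: full 40-compound roster of the campaign.
ROSTER = _NAMED + _PLACEHOLDERS

#: compounds with proton signals in their STD difference spectra.
STD_BINDERS = frozenset({"A1", "A5", "A9", "B7", "C4", "C6", "RA3"})

#: the 22 compounds with usable 1H spectra in aqueous buffer.  C11, DA1, DA2
#: and RA1 lacked detectable proton spectra (poor solubility), as did the
#: unnamed roster members.
STD_TESTABLE = frozenset(
    set(STD_BINDERS)
    | {"A10", "A11", "B1", "B5", "B6", "B9", "B11", "B12",
       "C1", "C3", "C7", "RA4", "X01", "X02", "X03"}
)

#: compounds displacing >15% of the dye in duplicate.
FID_HITS = frozenset({"DA1", "A1", "C11", "DA2"})

#: compounds that increased RNA-dye fluorescence beyond the +15% window.
FID_INCREASE = frozenset(
    {"A10", "A11", "B1", "B5", "B11", "C1", "C3", "C6", "C7", "RA1", "RA4"}
)

#: dye+ligand control exceeded the dye-only baseline (dye interaction).
DYE_INTERACTION = frozenset(
    {"A9", "A10", "A11", "B6", "B9", "B12", "C1", "C3", "C6", "C11"}
)

#: RNA+ligand control exceeded the RNA-only baseline.
RNA_INTERACTION = frozenset({"A10", "B12", "C1", "C3"})

#: HSQC perturbations localized to the junction/dicing site.
HSQC_SPECIFIC = frozenset({"C4", "A1", "DA1"})

#: HSQC perturbations across all resonances (non-specific binding).
HSQC_NON_SPECIFIC = frozenset({"RA1"})

#: HSQC-tested compounds with subtle-to-no perturbations at 10-fold excess.
HSQC_WEAK_OR_NONE = frozenset({"A5", "A9", "B7", "C6", "RA3", "C11", "DA2"})

#: apparent affinities (µM) from the titration series; None means censored
#: above 1 mM (no saturation within the tested range).
TABLE_KD_UM = {
    "DA1": 20.64,
    "C4A": 29.10,
    "C4": None,
    "A1": None,
}
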