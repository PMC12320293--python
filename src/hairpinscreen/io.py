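"""Compound records and file-format helpers.

Formats are deliberately plain: SMILES files are one record per line
(``SMILES<TAB>id``), SDF is read through RDKit, and all tabular data moves
as CSV/TSV through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from rdkit import Chem

__all__ = [
    "Compound",
    "read_smiles_file",
    "write_smiles_file",
    "read_sdf",
]


@dataclass
class Compound:
    """A screening-library member.

    ``soluble`` marks whether the compound gave a usable proton spectrum in
    aqueous buffer (poorly soluble compounds cannot be tested by
    ligand-observed NMR).  ``metadata`` carries generator bookkeeping such
    as planted-pair flags.
    """

    compound_id: str
    smiles: str
    soluble: bool = True
    metadata: dict = field(default_factory=dict)


def read_smiles_file(path: str | Path) -> list[Compound]:
    """Read a tab-separated SMILES file (``SMILES<TAB>id`` per line)."""
    compounds = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        cid = parts[1].strip() if len(parts) > 1 else f"cmpd{i + 1}"
        compounds.append(Compound(compound_id=cid, smiles=smiles))
    return compounds


def write_smiles_file(compounds: Iterable[Compound], path: str | Path) -> None:
    lines = [f"{c.smiles}\t{c.compound_id}" for c in compounds]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sdf(path: str | Path) -> list[Compound]:
    """Read an SDF file; molecule titles (or ``_Name``) become compound ids."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    compounds = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        compounds.append(
            Compound(
                compound_id=name or f"sdf{i + 1}",
                smiles=Chem.MolToSmiles(mol),
            )
        )
    return compounds


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
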