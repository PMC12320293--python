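#!/usr/bin/env python
"""Generate every synthetic input the downstream stages consume.

Writes to results/: a docking score table for the miR-31 hairpin plus two
selectivity-control hairpins (400 compounds, 8 planted hits of which 3 are
also planted control binders), an FID plate with known binders and
artifact compounds, intermediate- and fast-exchange HSQC titration series,
and a SMILES library with a planted near-duplicate pair.
"""

from pathlib import Path

from hairpinscreen.io import Compound, write_smiles_file
from hairpinscreen.synthetic import (
    SimConfig,
    gen_compound_library,
    gen_docking_table,
    gen_fid_plate,
    gen_titration,
)
from hairpinscreen.workflows import SITE_RESIDUES

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

# --- docking scores ---------------------------------------------------------
cfg = SimConfig(seed=11, n_compounds=400, n_planted_hits=8)
table, meta = gen_docking_table(cfg, n_control_binders=3)
table.to_csv(RESULTS / "docking_scores.csv")
meta.to_csv(RESULTS / "docking_planted.csv", index=False)
print(f"docking: {len(table.records)} scores over targets {sorted(table.targets)}")

# --- FID plate --------------------------------------------------------------
plate_cfg = SimConfig(seed=12, noise_cv=0.02)
panel = [
    (Compound("bindA", "Nc1nc2ccccc2s1"), 5.0, 0.0),     # strong displacer
    (Compound("bindB", "O=C(Nc1ccccc1)c1ccncc1"), 25.0, 0.0),
    (Compound("inert1", "c1ccc2[nH]cnc2c1"), None, 0.0),
    (Compound("inert2", "Cc1ccc2oc(=O)ccc2c1"), None, 0.0),
    (Compound("glow1", "Nc1nccc(-c2ccccc2)n1"), None, 1500.0),  # autofluorescent
]
plate = gen_fid_plate(panel, plate_cfg)
plate.to_csv(RESULTS / "fid_plate.csv")
print(f"plate: {len(plate.wells)} wells, {len(panel)} compounds")

# --- HSQC titrations --------------------------------------------------------
tit_int = gen_titration(
    29.10,
    SimConfig(seed=13, noise_cv=0.02, exchange_regime="intermediate",
              titration_points=(0.0, 5, 10, 20, 40, 60, 80, 100),
              titration_rna_conc_um=1.0),
    set(SITE_RESIDUES),
)
tit_int.to_tsv(RESULTS / "titration_intermediate.tsv")

tit_fast = gen_titration(
    2000.0,  # weak binder: no saturation within 0-1000 µM
    SimConfig(seed=14, noise_cv=0.02, exchange_regime="fast",
              titration_points=(0.0, 50, 100, 250, 500, 750, 1000),
              titration_rna_conc_um=100.0),
    set(SITE_RESIDUES),
)
tit_fast.to_tsv(RESULTS / "titration_fast_weak.tsv")
print("titrations: intermediate (KD 29.10 µM) and fast weak-binder series")

# --- compound library -------------------------------------------------------
library = gen_compound_library(60, seed=15)
write_smiles_file(library, RESULTS / "library.smi")
print(f"library: {len(library)} SMILES incl. planted near-duplicate pair")
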