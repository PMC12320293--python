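#!/usr/bin/env python
"""Analyse the simulated FID plate and the dye-affinity tuning curve.

First fits the dye's one-site binding curve to derive the fb0.1 working
RNA concentration, then computes %FID per compound on the plate, applies
the ±15% hit window, and reports artifact flags from the dye-only and
RNA-only controls.
"""

from pathlib import Path

import numpy as np

from hairpinscreen.fid import (
    BindingCurve,
    FIDPlate,
    fit_dye_affinity,
    one_site,
    results_to_frame,
    run_fid_stage,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

# --- assay tuning: dye affinity and working concentration -------------------
# 13 serial dilutions of RNA (0-20 µM, in nM) against 500 nM dye, 2% noise
rng = np.random.default_rng(21)
x = np.array([0, 5, 10, 20, 40, 80, 160, 320, 640, 1250, 2500, 5000, 20000.0])
y = one_site(x, 12000.0, 458.0) * rng.lognormal(sigma=0.02, size=x.size)
fit = fit_dye_affinity(BindingCurve(x, y, x_unit="nM"), fraction=0.1)
print(f"dye affinity: KD = {fit.kd:.1f} nM, Bmax = {fit.bmax:.0f} RFU")
print(f"fb0.1 working RNA concentration: {fit.fb01_conc:.1f} nM (KD/9)")

# --- plate analysis ---------------------------------------------------------
plate = FIDPlate.from_csv(RESULTS / "fid_plate.csv")
results = run_fid_stage(plate, window=15.0)
frame = results_to_frame(results)
frame.to_csv(RESULTS / "fid_results.csv", index=False)

for r in results:
    flags = f" [{';'.join(sorted(r.artifact_flags))}]" if r.artifact_flags else ""
    print(f"  {r.compound_id:8s} %FID {r.mean_percent_fid:7.1f}  {r.classification}{flags}")
n_hits = (frame.classification == "hit").sum()
print(f"{n_hits} hits / {len(frame)} compounds -> results/fid_results.csv")
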