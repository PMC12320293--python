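#!/usr/bin/env python
"""HSQC titration analysis: CSP site mapping and KD estimation.

Maps a synthetic single-point perturbation to the hairpin's structural
regions, fits the intermediate-exchange volume series (KD generated at
29.10 µM), shows the censored verdict on a weak, non-saturating
fast-exchange series, and measures estimator recovery over 100 replicate
titrations at each reported affinity (29.10 and 20.64 µM).
"""

import json
from pathlib import Path

import numpy as np

from hairpinscreen import mir31, workflows
from hairpinscreen.nmr import (
    HSQCPeak,
    TitrationSeries,
    csp_profile,
    fast_csp_series,
    fit_kd_fast,
    fit_kd_intermediate,
    intermediate_fraction_bound,
    map_binding_site,
)
from hairpinscreen.synthetic import reference_peaks

RESULTS = Path(__file__).resolve().parent.parent / "results"
SITE = set(workflows.SITE_RESIDUES)

# --- CSP mapping of a single-point perturbation -----------------------------
ref = reference_peaks()
perturbed = [
    HSQCPeak(p.residue, p.atom_pair, p.dh + 0.05, p.dc + 0.4, p.volume)
    if p.residue in SITE else p
    for p in ref
]
profile = csp_profile(ref, perturbed)
profile.to_frame().to_csv(RESULTS / "csp_profile.csv", index=False)
report = map_binding_site(profile, mir31.REGION_ANNOTATION)
print(f"CSP threshold {profile.significance_threshold:.4f} ppm; "
      f"significant {report['significant_residues']}")
print(f"binding site maps to: {report['modal_region']} "
      f"(non-specific: {report['non_specific']})")

# --- KD fits on the simulated series ----------------------------------------
tit = TitrationSeries.from_tsv(RESULTS / "titration_intermediate.tsv",
                               rna_conc_um=1.0, regime="intermediate")
x, b = intermediate_fraction_bound(tit, SITE)
fit_i = fit_kd_intermediate(x, b)
print(f"intermediate-exchange fit: KD = {fit_i} µM "
      f"(Bmax {fit_i.max_response:.3f}, NS {fit_i.ns_slope:.2e}/µM)")

tit_w = TitrationSeries.from_tsv(RESULTS / "titration_fast_weak.tsv",
                                 rna_conc_um=100.0, regime="fast")
xw, cw = fast_csp_series(tit_w, SITE)
fit_f = fit_kd_fast(xw, cw)
print(f"fast-exchange weak binder: KD = {fit_f} µM (censored: {fit_f.censored})")

# --- estimator recovery at the reported affinities --------------------------
recovery = {}
for kd_true, label in ((29.10, "kd_29.10"), (20.64, "kd_20.64")):
    fitted = workflows.kd_recovery(kd_true, seeds=range(1, 101))
    recovery[label] = {
        "kd_true_um": kd_true,
        "mean_fit_um": float(np.nanmean(fitted)),
        "median_fit_um": float(np.nanmedian(fitted)),
        "rel_bias": float((np.nanmean(fitted) - kd_true) / kd_true),
        "n": 100,
    }
    print(f"recovery at {kd_true} µM: mean fit {np.nanmean(fitted):.2f} µM "
          f"({100 * recovery[label]['rel_bias']:.1f}% bias over 100 series)")

payload = {"intermediate_fit": fit_i.to_dict(), "fast_weak_fit": fit_f.to_dict(),
           "recovery": recovery}
(RESULTS / "kd_fits.json").write_text(json.dumps(payload, indent=2))
print("-> results/csp_profile.csv, results/kd_fits.json")
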