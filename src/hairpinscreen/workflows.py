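"""Reusable end-to-end experiment routines.

These tie the generators to the estimators for the studies the package is
built around: encoding the screening campaign's per-compound outcomes into
an evidence table, and measuring KD-estimator recovery on synthetic
titrations.
"""

from __future__ import annotations

import numpy as np

from . import mir31
from .integrate import EvidenceTable, build_evidence_table
from .nmr import classify_std, fit_kd_intermediate, intermediate_fraction_bound
from .synthetic import SimConfig, gen_titration

__all__ = [
    "campaign_std_observations",
    "campaign_assay_calls",
    "campaign_evidence_table",
    "kd_recovery",
]

#: canonical ligand-binding site of the hairpin (junction + dicing site)
SITE_RESIDUES = frozenset({"A40", "A41", "C42", "C43"})


def campaign_std_observations(
    noise_sd: float = 1.0, signal_snr: float = 8.0
) -> dict[str, tuple[list[float], bool]]:
    """Synthetic STD difference-spectrum observations for the campaign roster.

    Each compound's recorded outcome (signal present / absent / no proton
    spectrum) is rendered as difference-spectrum amplitudes at the stated
    noise level, suitable for :func:`hairpinscreen.nmr.classify_std`.
    """
    obs = {}
    for cid in mir31.ROSTER:
        if cid not in mir31.STD_TESTABLE:
            obs[cid] = ([], False)
        elif cid in mir31.STD_BINDERS:
            obs[cid] = ([signal_snr * noise_sd, 0.6 * signal_snr * noise_sd], True)
        else:
            obs[cid] = ([0.0, 0.0], True)
    return obs


def campaign_assay_calls() -> tuple[dict, dict, dict]:
    """Per-compound STD/FID/HSQC calls of the 40-compound campaign.

    The STD calls are produced by running :func:`classify_std` on the
    rendered observations, not read off directly.
    """
    std = {
        cid: classify_std(amps, noise_sd=1.0, has_proton_spectrum=has)
        for cid, (amps, has) in campaign_std_observations().items()
        if has
    }
    fid = {}
    for cid in mir31.ROSTER:
        if cid in mir31.FID_HITS:
            fid[cid] = "hit"
        elif cid in mir31.FID_INCREASE:
            fid[cid] = "increase"
        else:
            fid[cid] = "no_change"
    hsqc = {}
    for cid in mir31.HSQC_SPECIFIC:
        hsqc[cid] = "specific"
    for cid in mir31.HSQC_NON_SPECIFIC:
        hsqc[cid] = "non_specific"
    for cid in mir31.HSQC_WEAK_OR_NONE:
        hsqc[cid] = "weak_or_none"
    return std, fid, hsqc


def campaign_evidence_table() -> EvidenceTable:
    """Evidence table for the full 40-compound campaign."""
    std, fid, hsqc = campaign_assay_calls()
    flags = {cid: "dye_interaction" for cid in mir31.DYE_INTERACTION}
    for cid in mir31.RNA_INTERACTION:
        flags[cid] = (flags.get(cid, "") + ";rna_interaction").lstrip(";")
    return build_evidence_table(std, fid, hsqc, mir31.ROSTER, fid_flags=flags)


def kd_recovery(
    kd_true: float,
    seeds,
    titration_points=(0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0),
    rna_conc_um: float = 1.0,
    noise_cv: float = 0.02,
    site_residues=SITE_RESIDUES,
) -> np.ndarray:
    """Fitted KDs from repeated synthetic intermediate-exchange titrations.

    One titration series is generated per seed (8 points by default, 2%
    multiplicative volume noise, excess-ligand regime at 1 µM RNA so the
    hyperbolic estimator model is well specified) and fit with
    :func:`fit_kd_intermediate`.  Censored fits are returned as NaN.
    """
    fitted = []
    for seed in seeds:
        cfg = SimConfig(
            seed=int(seed),
            noise_cv=noise_cv,
            titration_points=tuple(titration_points),
            exchange_regime="intermediate",
            titration_rna_conc_um=rna_conc_um,
        )
        series = gen_titration(kd_true, cfg, set(site_residues))
        x, b = intermediate_fraction_bound(series, set(site_residues))
        fit = fit_kd_intermediate(x, b)
        fitted.append(np.nan if fit.censored else fit.kd)
    return np.asarray(fitted)
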