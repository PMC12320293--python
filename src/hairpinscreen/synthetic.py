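"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the screening analysis can be exercised at desk scale from
these generators:

* docking score tables — near-normal background scores with favourable
  planted outliers on the primary target only;
* FID plates — well fluorescence computed from the exact competitive
  RNA/dye/ligand equilibrium (:func:`hairpinscreen.equilibrium.solve_competition`),
  plus ligand autofluorescence and multiplicative lognormal noise;
* HSQC titration series — two-state binding with the exact quadratic for
  fraction bound (not the excess-ligand hyperbola, so estimator bias is
  measurable), rendered either as population-weighted peak movement (fast
  exchange) or free/bound volume redistribution (intermediate exchange);
* compound libraries — scaffold-enumerated SMILES with planted
  near-duplicate pairs for the similarity stage.

Defaults mirror the assay conditions of the miR-31 screening campaign:
50.9 nM RNA with 500 nM dye (dye KD 458 nM, the fb0.1 working point),
ligands screened at 100 µM, titrations on 100 µM RNA up to 1 mM ligand.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mir31
from .docking import DockingTable
from .equilibrium import fraction_bound_quadratic, solve_competition
from .fid import FIDPlate
from .io import Compound
from .nmr import VALID_ATOM_PAIRS, HSQCPeak, TitrationSeries

__all__ = [
    "SimConfig",
    "gen_docking_table",
    "gen_fid_plate",
    "gen_titration",
    "gen_compound_library",
    "reference_peaks",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for all generators.

    Concentration units follow the assay they parameterize: plate species
    in nM (``rna_conc``, ``dye_conc``, ``dye_kd``), ligands and titrations
    in µM.  ``gain`` (RFU per µM of RNA·dye complex) and ``baseline`` (RFU)
    define the linear fluorescence model RFU = gain·[RNA·dye] + baseline.
    """

    seed: int = 0
    n_compounds: int = 40
    n_planted_hits: int = 0
    score_mean: float = -12.0  # kcal/mol
    score_sd: float = 3.0  # kcal/mol
    dye_kd: float = 458.0  # nM
    rna_conc: float = 50.9  # nM (plate)
    dye_conc: float = 500.0  # nM
    ligand_conc: float = 100.0  # µM (screening concentration)
    noise_cv: float = 0.02
    titration_points: tuple = (0.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    exchange_regime: str = "intermediate"
    titration_rna_conc_um: float = 100.0  # µM (HSQC sample)
    gain: float = 2.0e5  # RFU per µM RNA·dye
    baseline: float = 50.0  # RFU

    def __post_init__(self) -> None:
        if self.n_compounds < 0 or self.n_planted_hits < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_planted_hits > self.n_compounds:
            raise ConfigError("n_planted_hits must be <= n_compounds")
        for name in ("dye_kd", "rna_conc", "dye_conc", "ligand_conc",
                     "titration_rna_conc_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.score_sd <= 0:
            raise ConfigError("score_sd must be > 0")
        pts = tuple(float(p) for p in self.titration_points)
        if not pts or pts[0] != 0.0 or any(p < 0 for p in pts):
            raise ConfigError("titration_points must start at 0 and be non-negative")
        if list(pts) != sorted(pts):
            raise ConfigError("titration_points must be sorted ascending")
        object.__setattr__(self, "titration_points", pts)
        if self.exchange_regime not in ("fast", "intermediate"):
            raise ConfigError("exchange_regime must be 'fast' or 'intermediate'")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _mult_noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# docking tables


def gen_docking_table(
    cfg: SimConfig,
    target: str = "miR31",
    control_targets: tuple[str, ...] = ("miR21", "miR20b"),
    n_control_binders: int = 0,
) -> tuple[DockingTable, pd.DataFrame]:
    """Score table for one primary target plus selectivity-control targets.

    Background scores are Normal(score_mean, score_sd).  Planted hits score
    score_mean − 4·score_sd on the primary target but background on the
    controls — truncated to ±1.5 SD there, so a compound planted as
    target-selective is never a control binder by accident; the first
    ``n_control_binders`` of them are additionally planted as control
    binders (4 SD favourable on every control too), for exercising the
    counter-screen.  Returns the table and a metadata frame flagging
    planted compounds.
    """
    rng = np.random.default_rng(cfg.seed)

    def central_background() -> float:
        while True:
            z = rng.standard_normal()
            if abs(z) <= 1.5:
                return cfg.score_mean + cfg.score_sd * z
    ids = [f"cmpd{i + 1:04d}" for i in range(cfg.n_compounds)]
    planted = set(ids[: cfg.n_planted_hits])
    control_binders = set(ids[:n_control_binders])
    if n_control_binders > cfg.n_planted_hits:
        raise ConfigError("control binders must be a subset of planted hits")

    rows = []
    hit_score = cfg.score_mean - 4.0 * cfg.score_sd
    for t in (target, *control_targets):
        scores = rng.normal(cfg.score_mean, cfg.score_sd, size=cfg.n_compounds)
        for cid, s in zip(ids, scores):
            if cid in planted and t == target:
                s = hit_score + rng.normal(0.0, 0.1 * cfg.score_sd)
            elif cid in control_binders and t != target:
                s = hit_score + rng.normal(0.0, 0.1 * cfg.score_sd)
            elif cid in planted and t != target:
                s = central_background()
            rows.append({"compound_id": cid, "target_id": t, "score_kcal_mol": s})

    meta = pd.DataFrame(
        {
            "compound_id": ids,
            "planted_hit": [c in planted for c in ids],
            "planted_control_binder": [c in control_binders for c in ids],
        }
    )
    return DockingTable(pd.DataFrame(rows), primary_target=target), meta


# ---------------------------------------------------------------------------
# FID plates


def gen_fid_plate(
    compounds: list[tuple[Compound, float | None, float]],
    cfg: SimConfig,
    n_blank: int = 4,
    n_replicates: int = 2,
) -> FIDPlate:
    """Plate fluorescence from the competitive equilibrium.

    ``compounds`` holds (compound, ligand KD in µM or None for a
    non-binder, autofluorescence in RFU).  Ligand wells contain
    RNA + dye + ligand at the configured concentrations; blank wells
    RNA + dye; control wells pair each ligand with dye alone and RNA
    alone; dye-only and RNA-only wells give the control baselines.
    Autofluorescence adds to every well containing the compound.
    Multiplicative lognormal noise at ``cfg.noise_cv`` applies to all
    wells.
    """
    rng = np.random.default_rng(cfg.seed)
    rna_um = cfg.rna_conc * 1e-3
    dye_um = cfg.dye_conc * 1e-3
    kd_dye_um = cfg.dye_kd * 1e-3
    non_binder_kd = 1e9  # effectively no competition

    blank_state = solve_competition(rna_um, dye_um, 0.0, kd_dye_um, non_binder_kd)
    blank_rfu = cfg.gain * blank_state.rna_dye + cfg.baseline

    rows = []
    well = 0

    def add(role, compound_id, replicate, rfu):
        nonlocal well
        well += 1
        rows.append(
            {
                "well": f"W{well:03d}",
                "role": role,
                "compound_id": compound_id,
                "replicate": replicate,
                "rfu": rfu * _mult_noise(rng, cfg.noise_cv),
            }
        )

    for r in range(n_blank):
        add("blank", "", r + 1, blank_rfu)
    for r in range(2):
        add("dye_only", "", r + 1, cfg.baseline)
        add("rna_only", "", r + 1, cfg.baseline)

    for compound, kd_ligand, autofl in compounds:
        kd_um = non_binder_kd if kd_ligand is None else float(kd_ligand)
        state = solve_competition(rna_um, dye_um, cfg.ligand_conc, kd_dye_um, kd_um)
        ligand_rfu = cfg.gain * state.rna_dye + cfg.baseline + autofl
        for r in range(n_replicates):
            add("ligand", compound.compound_id, r + 1, ligand_rfu)
        add("dye_control", compound.compound_id, 1, cfg.baseline + autofl)
        add("rna_control", compound.compound_id, 1, cfg.baseline + autofl)

    return FIDPlate(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# HSQC titration series


def reference_peaks(seed: int = 2052) -> list[HSQCPeak]:
    """Reference (free-RNA) aromatic peak list for the labelled A/C residues.

    Positions lie in the typical aromatic ranges (A C2-H2 near 7.8/153 ppm,
    A C8-H8 near 8.3/137 ppm, C C6-H6 near 7.7/142 ppm) on a lightly
    jittered grid, so the synthetic free-RNA spectrum is fully resolved —
    by design somewhat better dispersed than a real crowded aromatic
    region, where overlap is common.
    """
    rng = np.random.default_rng(seed)
    # per atom-pair class: (dh start, dh spacing, low/high 13C rows)
    layout = {
        "C2H2": (7.40, 0.15, 151.5, 154.5),
        "C8H8": (7.90, 0.15, 136.0, 138.0),
        "C6H6": (7.20, 0.143, 140.5, 143.5),
    }
    counters: dict[str, int] = {}
    peaks = []
    for label in mir31.residue_labels(labelled_only=True):
        nt = label[0]
        for pair in sorted(VALID_ATOM_PAIRS[nt] & {"C2H2", "C6H6", "C8H8"}):
            k = counters.get(pair, 0)
            counters[pair] = k + 1
            h0, dh_step, c_lo, c_hi = layout[pair]
            peaks.append(
                HSQCPeak(
                    residue=label,
                    atom_pair=pair,
                    dh=float(h0 + k * dh_step + rng.uniform(-0.01, 0.01)),
                    dc=float((c_lo if k % 2 else c_hi) + rng.uniform(-0.1, 0.1)),
                    volume=1.0,
                )
            )
    return peaks


def gen_titration(
    kd_true: float,
    cfg: SimConfig,
    residues_at_site: set[str],
) -> TitrationSeries:
    """Two-state titration series in the configured exchange regime.

    The fraction bound at each ligand concentration comes from the exact
    two-state quadratic at ``cfg.titration_rna_conc_um`` — not the
    excess-ligand hyperbola — so the bias of hyperbola-based estimators is
    measurable.  Site residues acquire bound-state positions offset by
    0.05–0.12 ppm (1H) and 0.4–1.0 ppm (13C); off-site residues never
    move.  Fast exchange renders population-weighted positions;
    intermediate exchange renders coexisting free ((1−B)·V0) and bound
    (B·V0) peaks.  Volumes carry multiplicative noise at ``cfg.noise_cv``.
    """
    if kd_true <= 0:
        raise ConfigError("kd_true must be > 0")
    reference = reference_peaks()
    known = {p.residue for p in reference}
    unknown = set(residues_at_site) - known
    if unknown:
        raise ConfigError(f"site residues not in the labelled construct: {sorted(unknown)}")

    rng = np.random.default_rng(cfg.seed)
    # offsets clear the free-peak matching ellipse (0.05 ppm 1H, 0.5 ppm 13C)
    # so intermediate-exchange free/bound peaks are always separable
    bound_offsets = {
        (p.residue, p.atom_pair): (
            float(rng.uniform(0.05, 0.12) * rng.choice([-1.0, 1.0])),
            float(rng.uniform(0.4, 1.0) * rng.choice([-1.0, 1.0])),
        )
        for p in reference
        if p.residue in residues_at_site
    }

    points: list[tuple[float, list[HSQCPeak]]] = []
    for conc in cfg.titration_points:
        frac = (
            0.0
            if conc == 0.0
            else fraction_bound_quadratic(cfg.titration_rna_conc_um, conc, kd_true)
        )
        peaks: list[HSQCPeak] = []
        for p in reference:
            key = (p.residue, p.atom_pair)
            if key not in bound_offsets:
                peaks.append(
                    HSQCPeak(p.residue, p.atom_pair, p.dh, p.dc,
                             p.volume * _mult_noise(rng, cfg.noise_cv))
                )
                continue
            dh_off, dc_off = bound_offsets[key]
            if cfg.exchange_regime == "fast":
                peaks.append(
                    HSQCPeak(
                        p.residue, p.atom_pair,
                        p.dh + frac * dh_off, p.dc + frac * dc_off,
                        p.volume * _mult_noise(rng, cfg.noise_cv),
                    )
                )
            else:
                peaks.append(
                    HSQCPeak(p.residue, p.atom_pair, p.dh, p.dc,
                             p.volume * (1.0 - frac) * _mult_noise(rng, cfg.noise_cv))
                )
                if frac > 0.0:
                    peaks.append(
                        HSQCPeak(p.residue, p.atom_pair,
                                 p.dh + dh_off, p.dc + dc_off,
                                 p.volume * frac * _mult_noise(rng, cfg.noise_cv))
                    )
        points.append((float(conc), peaks))

    return TitrationSeries(
        reference=reference,
        points=points,
        rna_conc_um=cfg.titration_rna_conc_um,
        regime=cfg.exchange_regime,
        site_residues=set(residues_at_site),
        kd_true_um=kd_true,
    )


# ---------------------------------------------------------------------------
# compound libraries

# drug-like scaffolds with a [*] attachment point for substituent enumeration
_SCAFFOLDS = [
    "[*]c1ccc2[nH]cnc2c1",               # benzimidazole
    "[*]c1ccc2oc(=O)ccc2c1",             # coumarin
    "Nc1nccc(-c2ccc([*])cc2)n1",         # phenyl-aminopyrimidine
    "Nc1nc2ccc([*])cc2s1",               # aminobenzothiazole
    "[*]c1ccc2cc[nH]c2n1",               # azaindole
    "O=C(Nc1ccc([*])cc1)c1ccncc1",       # isonicotinic anilide
    "[*]c1ccc(CN2CCNCC2)cc1",            # benzylpiperazine
    "[*]c1ccc2[nH]c(-c3ccccc3)nc2c1",    # phenyl-benzimidazole
]
_SUBSTITUENTS = ["[H]", "C", "O", "N", "F", "Cl", "OC", "C(=O)O", "C#N", "CO"]


def _decorated(scaffold: str, sub: str) -> str:
    if sub == "[H]":
        return scaffold.replace("([*])", "").replace("[*]", "")
    return scaffold.replace("[*]", sub)


def gen_compound_library(n: int, seed: int = 0) -> list[Compound]:
    """Enumerate a library of valid SMILES with planted near-duplicate pairs.

    Scaffolds are decorated with small substituents; every even/odd index
    pair (2k, 2k+1) drawn from the same scaffold with substituents
    differing by a single heavy atom is flagged in metadata as a planted
    pair, giving the similarity stage known positives.
    """
    from rdkit import Chem, RDLogger

    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)

    RDLogger.DisableLog("rdApp.error")  # some enumerated edits are chemically invalid
    try:
        candidates = []
        for scaf in _SCAFFOLDS:
            for sub in _SUBSTITUENTS:
                mol = Chem.MolFromSmiles(_decorated(scaf, sub))
                if mol is not None:
                    candidates.append(Chem.MolToSmiles(mol))
    finally:
        RDLogger.EnableLog("rdApp.error")
    candidates = sorted(set(candidates))

    # planted near-duplicate pair: same scaffold, single-heavy-atom change
    pair_scaffold = "O=C(Nc1ccc([*])cc1)c1ccncc1"
    pair = [
        Chem.MolToSmiles(Chem.MolFromSmiles(_decorated(pair_scaffold, "C"))),
        Chem.MolToSmiles(Chem.MolFromSmiles(_decorated(pair_scaffold, "O"))),
    ]

    chosen = list(pair)
    pool = [s for s in candidates if s not in chosen]
    order = rng.permutation(len(pool))
    for idx in order:
        if len(chosen) >= n:
            break
        chosen.append(pool[idx])
    # top up with methyl homologation if the pool is exhausted
    k = 0
    while len(chosen) < n:
        smi = Chem.MolToSmiles(Chem.MolFromSmiles(_decorated(_SCAFFOLDS[k % len(_SCAFFOLDS)], "C" * (2 + k // len(_SCAFFOLDS)))))
        if smi not in chosen:
            chosen.append(smi)
        k += 1

    compounds = []
    for i, smi in enumerate(chosen):
        compounds.append(
            Compound(
                compound_id=f"lib{i + 1:04d}",
                smiles=smi,
                metadata={"planted_pair": i < 2},
            )
        )
    return compounds
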