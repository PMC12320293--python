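"""Fluorescence indicator displacement (FID) assay analysis.

A fluorogenic dye (TO-PRO-1) fluoresces when bound to the RNA hairpin; a
competing ligand displaces it and lowers the well fluorescence.  The stage
covers assay tuning (dye-affinity fit and the fb0.1 working concentration),
the % FID displacement statistic, hit classification against a ±15%
window, and artifact controls (ligand-dye and ligand-RNA interactions).

%FID = 100·(F0 − F)/F0, where F0 is the mean blank (RNA + dye) well and F
the three-component well; the plotted "fluorescence change" axis used for
visual inspection is 100 − %FID = 100·F/F0, so hits (>15% displacement)
fall below 85 on that axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "DyeAffinityFit",
    "FIDPlate",
    "FIDResult",
    "fit_dye_affinity",
    "percent_fid",
    "classify_displacement",
    "flag_artifacts",
    "run_fid_stage",
]

logger = logging.getLogger(__name__)

#: well roles recognised on a plate
ROLES = ("blank", "ligand", "dye_control", "rna_control", "dye_only", "rna_only")


class FitQualityError(RuntimeError):
    """Dye-affinity fit failed or landed outside the credible KD range."""


class PlateLayoutError(ValueError):
    """Plate is missing wells required by the analysis."""


@dataclass
class BindingCurve:
    """Saturation-binding measurement: titrant concentrations vs response.

    ``x`` carries its unit tag ("nM" or "uM") so fb0.1 is reported in the
    same unit the curve was measured in.
    """

    x: np.ndarray
    y: np.ndarray
    x_unit: str = "nM"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if (self.x < 0).any():
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")


@dataclass
class DyeAffinityFit:
    """One-site dye-affinity fit and the derived working concentration."""

    kd: float
    bmax: float
    residual_norm: float
    fb01_conc: float
    x_unit: str = "nM"


@dataclass
class FIDPlate:
    """Well-level plate data: columns well, role, compound_id, replicate, rfu."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "role", "compound_id", "replicate", "rfu"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate missing columns: {sorted(missing)}")
        bad = set(self.wells["role"].unique()) - set(ROLES)
        if bad:
            raise ValueError(f"unknown well roles: {sorted(bad)}")

    def rfu(self, role: str, compound_id: str | None = None) -> np.ndarray:
        sel = self.wells["role"] == role
        if compound_id is not None:
            sel &= self.wells["compound_id"] == compound_id
        return self.wells.loc[sel, "rfu"].to_numpy(dtype=float)

    @property
    def compound_ids(self) -> list[str]:
        ids = self.wells.loc[self.wells["role"] == "ligand", "compound_id"]
        return sorted(ids.unique())

    @classmethod
    def from_csv(cls, path) -> "FIDPlate":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.wells.to_csv(path, index=False)


@dataclass
class FIDResult:
    """Per-compound displacement statistics and classification."""

    compound_id: str
    percent_fid_replicates: list[float]
    mean_percent_fid: float
    classification: str  # hit | no_change | increase
    artifact_flags: set[str] = field(default_factory=set)


def one_site(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """One-site specific binding isotherm, Y = Bmax·X/(KD + X)."""
    return bmax * x / (kd + x)


def fit_dye_affinity(curve: BindingCurve, fraction: float = 0.1) -> DyeAffinityFit:
    """Fit a one-site binding curve and derive the fb working concentration.

    The RNA concentration at which a fraction ``f`` of the dye signal is
    attained on the fitted curve is X = f/(1−f)·KD (KD/9 for f = 0.1); this
    is the assay's sensitivity-tuned working concentration.

    Requires >= 4 points whose positive concentrations span at least one
    order of magnitude.  KD outside [min(x>0)/100, 100·max(x)] raises
    :class:`FitQualityError`.
    """
    if len(curve.x) < 4:
        raise ValueError("need >= 4 points to fit a binding curve")
    pos = curve.x[curve.x > 0]
    if len(pos) == 0 or pos.max() / pos.min() < 10.0:
        raise ValueError("concentrations must span at least one order of magnitude")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")

    bmax0 = float(curve.y.max()) or 1.0
    kd0 = float(np.median(pos))
    try:
        popt, _ = curve_fit(
            one_site, curve.x, curve.y, p0=[bmax0, kd0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitQualityError(f"dye-affinity fit did not converge: {exc}") from exc
    bmax, kd = float(popt[0]), float(popt[1])
    if not pos.min() / 100.0 <= kd <= 100.0 * pos.max():
        raise FitQualityError(
            f"fitted KD {kd:.3g} {curve.x_unit} outside the credible range "
            f"[{pos.min() / 100:.3g}, {100 * pos.max():.3g}]"
        )
    resid = curve.y - one_site(curve.x, bmax, kd)
    return DyeAffinityFit(
        kd=kd,
        bmax=bmax,
        residual_norm=float(np.linalg.norm(resid)),
        fb01_conc=fraction / (1.0 - fraction) * kd,
        x_unit=curve.x_unit,
    )


def percent_fid(f: float, f0: float) -> float:
    """Percent indicator displacement, 100·(F0 − F)/F0.

    Negative values mean the well fluorescence rose above the blank.
    """
    if f0 <= 0:
        raise ValueError("blank fluorescence F0 must be positive")
    if f < 0:
        raise ValueError("well fluorescence must be >= 0")
    return 100.0 * (f0 - f) / f0


def classify_displacement(replicate_percents: list[float], window: float = 15.0) -> str:
    """Classify a compound from its per-replicate %FID values.

    ``hit`` requires every replicate above +window (displacement confirmed
    in duplicate); ``increase`` means the mean fell below −window
    (fluorescence rose); anything else is ``no_change``.
    """
    reps = np.asarray(replicate_percents, dtype=float)
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates to classify")
    if np.all(reps > window):
        return "hit"
    if reps.mean() < -window:
        return "increase"
    return "no_change"


def flag_artifacts(
    result: FIDResult,
    dye_control_delta: float | None,
    rna_control_delta: float | None,
    window: float = 15.0,
) -> FIDResult:
    """Attach dye-/RNA-interaction flags from the no-RNA / no-dye controls.

    Deltas are percent changes of the control wells against their dye-only
    or RNA-only baselines.  Flags annotate but never change the
    classification; missing controls leave flags unset with a warning.
    """
    flags = set(result.artifact_flags)
    for delta, flag in (
        (dye_control_delta, "dye_interaction"),
        (rna_control_delta, "rna_interaction"),
    ):
        if delta is None:
            warnings.warn(
                f"{result.compound_id}: missing control for {flag}; flag omitted",
                stacklevel=2,
            )
            continue
        if delta > window:
            flags.add(flag)
    return FIDResult(
        compound_id=result.compound_id,
        percent_fid_replicates=list(result.percent_fid_replicates),
        mean_percent_fid=result.mean_percent_fid,
        classification=result.classification,
        artifact_flags=flags,
    )


def _percent_delta(values: np.ndarray, baseline: np.ndarray) -> float | None:
    if len(values) == 0 or len(baseline) == 0:
        return None
    base = float(baseline.mean())
    if base <= 0:
        return None
    return 100.0 * (float(values.mean()) - base) / base


def run_fid_stage(plate: FIDPlate, window: float = 15.0) -> list[FIDResult]:
    """Analyse a full plate: %FID per replicate, classification, artifacts.

    F0 is the mean of the blank (RNA + dye) wells of this plate; no
    cross-plate normalisation is applied.
    """
    blanks = plate.rfu("blank")
    if len(blanks) == 0:
        raise PlateLayoutError("plate has no blank (RNA + dye) wells")
    f0 = float(blanks.mean())

    dye_only = plate.rfu("dye_only")
    rna_only = plate.rfu("rna_only")

    results = []
    for cid in plate.compound_ids:
        reps = plate.rfu("ligand", cid)
        if len(reps) < 2:
            raise PlateLayoutError(f"compound {cid} has fewer than 2 ligand wells")
        percents = [percent_fid(float(f), f0) for f in reps]
        result = FIDResult(
            compound_id=cid,
            percent_fid_replicates=percents,
            mean_percent_fid=float(np.mean(percents)),
            classification=classify_displacement(percents, window=window),
        )
        result = flag_artifacts(
            result,
            _percent_delta(plate.rfu("dye_control", cid), dye_only),
            _percent_delta(plate.rfu("rna_control", cid), rna_only),
            window=window,
        )
        results.append(result)
    return results


def results_to_frame(results: list[FIDResult]) -> pd.DataFrame:
    """Tabulate stage results (one row per compound)."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "mean_percent_fid": [r.mean_percent_fid for r in results],
            "sd_percent_fid": [
                float(np.std(r.percent_fid_replicates, ddof=1)) for r in results
            ],
            "classification": [r.classification for r in results],
            "flags": [";".join(sorted(r.artifact_flags)) for r in results],
        }
    )
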