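"""HSQC titration analysis: peak matching, CSP mapping, KD estimation.

Two exchange regimes are handled, declared by the user rather than
auto-detected:

* **fast exchange** — each site peak moves continuously; the observed shift
  is the population-weighted average of free and bound positions, and the
  chemical shift perturbation (CSP) as a function of ligand concentration
  is fit to a one-site isotherm.
* **intermediate exchange** — free and bound peaks coexist; binding
  redistributes volume from the free to the bound peak, so the fraction
  bound B = V_bound/(V_bound + V_free) is measured per titration point and
  fit to B(X) = Bmax·X/(KD + X) + NS·X, where the linear NS term absorbs
  non-saturable, nonspecific association.

CSP is the carbon-weighted Euclidean distance a correlation peak moves,
sqrt(ΔδH² + (α·ΔδC)²), with α = 0.25 by default (standard aromatic-carbon
scaling).  A fit whose isotherm does not approach saturation within the
tested concentration range is reported censored (">max tested"), mirroring
how non-saturating titrations are reported in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HSQCPeak",
    "CSPProfile",
    "KdFit",
    "TitrationSeries",
    "match_peaks",
    "compute_csp",
    "csp_profile",
    "map_binding_site",
    "fraction_bound",
    "intermediate_fraction_bound",
    "fast_csp_series",
    "fit_kd_intermediate",
    "fit_kd_fast",
    "classify_std",
    "dmso_control_check",
]

#: atom pairs observable per nucleotide under A/C labelling
VALID_ATOM_PAIRS = {"A": {"C2H2", "C8H8"}, "C": {"C6H6"}, "U": {"C6H6"}, "G": {"C8H8"}}

QUANTIFIED = "quantified"
OVERLAPPED = "overlapped"
NOT_DETECTED = "not_detected"


class PeakIdentityError(ValueError):
    """Peaks compared across different residues or atom pairs."""


@dataclass(frozen=True)
class HSQCPeak:
    """One aromatic HSQC correlation: residue label, atom pair, position, volume."""

    residue: str  # e.g. "A40"
    atom_pair: str  # C2H2 | C6H6 | C8H8
    dh: float  # 1H shift, ppm
    dc: float  # 13C shift, ppm
    volume: float = 1.0

    def __post_init__(self) -> None:
        nt = self.residue[0]
        allowed = VALID_ATOM_PAIRS.get(nt)
        if allowed is not None and self.atom_pair not in allowed:
            raise ValueError(
                f"atom pair {self.atom_pair} invalid for nucleotide {nt} "
                f"({self.residue})"
            )
        if self.volume < 0:
            raise ValueError("peak volume must be >= 0")


@dataclass
class CSPProfile:
    """Per-residue CSPs with quantification status and significance calls."""

    csp: dict[str, float]  # residue -> max CSP over atom pairs (ppm)
    status: dict[str, str]  # residue -> quantified|overlapped|not_detected
    significance_threshold: float
    significant_residues: set[str]
    per_peak: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue": r,
                "csp_ppm": self.csp.get(r, np.nan),
                "status": s,
                "significant": r in self.significant_residues,
            }
            for r, s in sorted(self.status.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class KdFit:
    """Binding-affinity estimate from a titration series.

    ``kd`` is None when the series is censored (``censor_bound`` holds the
    upper concentration tested, reported as ">bound").  ``ci_halfwidth`` is
    the 1.96·SE asymptotic half-width from the least-squares covariance.
    """

    kd: float | None
    regime: str  # fast | intermediate
    max_response: float  # Bmax (fraction) or CSPmax (ppm)
    ns_slope: float | None = None  # per-µM, intermediate regime only
    ci_halfwidth: float | None = None
    censor_bound: float | None = None

    @property
    def censored(self) -> bool:
        return self.kd is None

    def __str__(self) -> str:
        if self.censored:
            return f">{self.censor_bound:g}"
        return f"{self.kd:.4g}"

    def to_dict(self) -> dict:
        return {
            "kd_um": self.kd,
            "censored": self.censored,
            "censor_bound_um": self.censor_bound,
            "regime": self.regime,
            "max_response": self.max_response,
            "ns_slope_per_um": self.ns_slope,
            "ci_halfwidth_um": self.ci_halfwidth,
        }


@dataclass
class TitrationSeries:
    """Ordered ligand concentrations (µM), each with an HSQC peak list."""

    reference: list[HSQCPeak]
    points: list[tuple[float, list[HSQCPeak]]]
    rna_conc_um: float
    regime: str = "intermediate"
    site_residues: set[str] = field(default_factory=set)
    kd_true_um: float | None = None

    def concentrations(self) -> list[float]:
        return [c for c, _ in self.points]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for conc, peaks in self.points:
            for p in peaks:
                rows.append(
                    {
                        "residue": p.residue,
                        "atom_pair": p.atom_pair,
                        "dh_ppm": p.dh,
                        "dc_ppm": p.dc,
                        "volume": p.volume,
                        "ligand_conc_um": conc,
                    }
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        rna_conc_um: float,
        regime: str = "intermediate",
    ) -> "TitrationSeries":
        points = []
        for conc, sub in frame.groupby("ligand_conc_um", sort=True):
            peaks = [
                HSQCPeak(r.residue, r.atom_pair, r.dh_ppm, r.dc_ppm, r.volume)
                for r in sub.itertuples()
            ]
            points.append((float(conc), peaks))
        if not points or points[0][0] != 0.0:
            raise ValueError("titration series must start at 0 ligand")
        return cls(
            reference=points[0][1],
            points=points,
            rna_conc_um=rna_conc_um,
            regime=regime,
        )

    @classmethod
    def from_tsv(cls, path, rna_conc_um: float, regime: str = "intermediate"):
        return cls.from_frame(pd.read_csv(path, sep="\t"), rna_conc_um, regime)


# ---------------------------------------------------------------------------
# peak matching and CSP


def _ellipse_dist(ref: HSQCPeak, obs: HSQCPeak, radius_h: float, radius_c: float) -> float:
    return np.hypot((ref.dh - obs.dh) / radius_h, (ref.dc - obs.dc) / radius_c)


def match_peaks(
    reference: list[HSQCPeak],
    observed: list[HSQCPeak],
    radius_h: float = 0.05,
    radius_c: float = 0.5,
) -> dict[tuple[str, str], object]:
    """Assign observed peaks to reference peaks by position.

    For each reference peak the observed peaks inside the search ellipse
    (Δh/radius_h)² + (Δc/radius_c)² <= 1 are collected: exactly one
    uncontested candidate gives a match; none marks the reference peak
    ``not_detected`` (it moved out of the window or broadened away); two or
    more, or a candidate contested by another reference peak, marks it
    ``overlapped`` (cannot be quantified).

    Returns a dict keyed by (residue, atom_pair) whose values are either a
    matched :class:`HSQCPeak` or one of the status strings.
    """
    if not reference or not observed:
        raise ValueError("peak lists must be non-empty")

    candidates: dict[int, list[int]] = {}
    for i, ref in enumerate(reference):
        candidates[i] = [
            j
            for j, obs in enumerate(observed)
            if _ellipse_dist(ref, obs, radius_h, radius_c) <= 1.0
        ]

    claim_count: dict[int, int] = {}
    for js in candidates.values():
        if len(js) == 1:
            claim_count[js[0]] = claim_count.get(js[0], 0) + 1

    out: dict[tuple[str, str], object] = {}
    for i, ref in enumerate(reference):
        key = (ref.residue, ref.atom_pair)
        js = candidates[i]
        if len(js) == 0:
            out[key] = NOT_DETECTED
        elif len(js) > 1 or claim_count.get(js[0], 0) > 1:
            out[key] = OVERLAPPED
        else:
            out[key] = observed[js[0]]
    return out


def compute_csp(ref: HSQCPeak, obs: HSQCPeak, alpha: float = 0.25) -> float:
    """Carbon-weighted chemical shift perturbation, sqrt(ΔδH² + (α·ΔδC)²)."""
    if (ref.residue, ref.atom_pair) != (obs.residue, obs.atom_pair):
        raise PeakIdentityError(
            f"cannot compare {ref.residue}/{ref.atom_pair} with "
            f"{obs.residue}/{obs.atom_pair}"
        )
    return float(np.hypot(ref.dh - obs.dh, alpha * (ref.dc - obs.dc)))


def csp_profile(
    reference: list[HSQCPeak],
    perturbed: list[HSQCPeak],
    alpha: float = 0.25,
    radius_h: float = 0.15,
    radius_c: float = 1.5,
) -> CSPProfile:
    """Per-residue CSP profile with a mean + 1·SD significance threshold.

    A residue's CSP is the maximum over its quantifiable atom pairs
    (conservative for site mapping).  Residues whose peaks are all
    overlapped or undetected are excluded from both the threshold
    computation and the significance set.
    """
    matches = match_peaks(reference, perturbed, radius_h=radius_h, radius_c=radius_c)
    ref_by_key = {(p.residue, p.atom_pair): p for p in reference}

    per_peak_rows = []
    residue_csps: dict[str, list[float]] = {}
    residue_status: dict[str, list[str]] = {}
    for key, match in matches.items():
        residue, atom_pair = key
        if isinstance(match, HSQCPeak):
            csp = compute_csp(ref_by_key[key], match, alpha=alpha)
            status = QUANTIFIED
            residue_csps.setdefault(residue, []).append(csp)
        else:
            csp = np.nan
            status = match
        residue_status.setdefault(residue, []).append(status)
        per_peak_rows.append(
            {"residue": residue, "atom_pair": atom_pair, "csp_ppm": csp, "status": status}
        )

    csp_by_residue: dict[str, float] = {}
    status_by_residue: dict[str, str] = {}
    for residue, statuses in residue_status.items():
        if residue in residue_csps:
            csp_by_residue[residue] = max(residue_csps[residue])
            status_by_residue[residue] = QUANTIFIED
        elif OVERLAPPED in statuses:
            status_by_residue[residue] = OVERLAPPED
        else:
            status_by_residue[residue] = NOT_DETECTED

    if not csp_by_residue:
        warnings.warn("no quantifiable peaks; empty CSP profile", stacklevel=2)
        return CSPProfile({}, status_by_residue, np.nan, set(),
                          pd.DataFrame(per_peak_rows))

    values = np.array(list(csp_by_residue.values()))
    threshold = float(values.mean() + values.std(ddof=0))
    significant = {r for r, v in csp_by_residue.items() if v > threshold}
    return CSPProfile(
        csp=csp_by_residue,
        status=status_by_residue,
        significance_threshold=threshold,
        significant_residues=significant,
        per_peak=pd.DataFrame(per_peak_rows),
    )


def map_binding_site(
    profile: CSPProfile,
    site_annotation: dict[str, str],
    global_floor_ppm: float = 0.02,
    global_fraction: float = 0.75,
) -> dict:
    """Group significant residues by structural region.

    Returns per-region counts, the modal region (ties joined with "/"),
    and a ``non_specific`` flag raised when at least ``global_fraction`` of
    all quantified residues show CSPs above ``global_floor_ppm`` — the
    signature of excess-ligand, whole-molecule perturbation rather than a
    localized site.
    """
    counts: dict[str, int] = {}
    for residue in sorted(profile.significant_residues):
        region = site_annotation.get(residue, "unannotated")
        counts[region] = counts.get(region, 0) + 1

    modal = None
    if counts:
        top = max(counts.values())
        modal = "/".join(sorted(r for r, c in counts.items() if c == top))

    quantified = [r for r, s in profile.status.items() if s == QUANTIFIED]
    perturbed = [r for r in quantified if profile.csp[r] > global_floor_ppm]
    non_specific = bool(quantified) and (
        len(perturbed) / len(quantified) >= global_fraction
    )

    return {
        "region_counts": counts,
        "modal_region": modal,
        "significant_residues": sorted(profile.significant_residues),
        "non_specific": non_specific,
    }


# ---------------------------------------------------------------------------
# fraction bound and KD fits


def fraction_bound(v_bound: float, v_free: float) -> float:
    """Fraction bound from bound- and free-peak volumes, V_B/(V_B + V_I)."""
    if v_bound < 0 or v_free < 0:
        raise ValueError("peak volumes must be >= 0")
    total = v_bound + v_free
    if total == 0:
        raise ValueError("fraction bound undefined: both peak volumes are zero")
    return v_bound / total


def intermediate_fraction_bound(
    series: TitrationSeries,
    site_residues: set[str] | None = None,
    radius_h: float = 0.05,
    radius_c: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract mean fraction bound per titration point from peak volumes.

    At each point, peaks of a site residue/atom pair are split into the
    free peak (within the matching ellipse of the reference position) and
    the bound peak (any other peak of the same correlation); fraction
    bound is averaged over site correlations.
    """
    site = site_residues if site_residues is not None else series.site_residues
    if not site:
        raise ValueError("site residues required to pool fraction bound")
    ref_by_key = {(p.residue, p.atom_pair): p for p in series.reference}

    x, b = [], []
    for conc, peaks in series.points:
        fracs = []
        for key, ref in ref_by_key.items():
            if key[0] not in site:
                continue
            group = [p for p in peaks if (p.residue, p.atom_pair) == key]
            if not group:
                continue
            v_free = sum(
                p.volume for p in group
                if _ellipse_dist(ref, p, radius_h, radius_c) <= 1.0
            )
            v_bound = sum(
                p.volume for p in group
                if _ellipse_dist(ref, p, radius_h, radius_c) > 1.0
            )
            if v_free + v_bound > 0:
                fracs.append(fraction_bound(v_bound, v_free))
        x.append(conc)
        b.append(float(np.mean(fracs)) if fracs else 0.0)
    return np.asarray(x), np.asarray(b)


def fast_csp_series(
    series: TitrationSeries,
    site_residues: set[str] | None = None,
    alpha: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean site CSP per titration point for an assigned fast-exchange series.

    Uses the peak labels (residue, atom pair) to pair each observed peak
    with its reference correlation, so it applies to assigned series where
    each correlation appears once per point.
    """
    site = site_residues if site_residues is not None else series.site_residues
    if not site:
        raise ValueError("site residues required to pool CSPs")
    ref_by_key = {(p.residue, p.atom_pair): p for p in series.reference}

    x, csps = [], []
    for conc, peaks in series.points:
        vals = []
        for p in peaks:
            key = (p.residue, p.atom_pair)
            if key[0] in site and key in ref_by_key:
                vals.append(compute_csp(ref_by_key[key], p, alpha=alpha))
        x.append(conc)
        csps.append(float(np.mean(vals)) if vals else 0.0)
    return np.asarray(x), np.asarray(csps)


def _isotherm_ns(x: np.ndarray, bmax: float, kd: float, ns: float) -> np.ndarray:
    return bmax * x / (kd + x) + ns * x


def fit_kd_intermediate(x, b) -> KdFit:
    """Fit fraction bound vs ligand concentration (µM) with a linear NS term.

    Model: B(X) = Bmax·X/(KD + X) + NS·X with Bmax in (0, 1] and NS >= 0.
    B at X=0 is treated as 0.  A fitted KD beyond the highest tested
    concentration is reported censored (">max(x)").
    """
    x = np.asarray(x, dtype=float)
    b = np.asarray(b, dtype=float).copy()
    if len(x) < 4:
        raise ValueError("need >= 4 titration points")
    if 0.0 not in x:
        raise ValueError("titration must include a 0-ligand point")
    b[x == 0.0] = 0.0

    xmax = float(x.max())
    bmax0 = min(max(float(b.max()), 1e-3), 1.0)
    half = bmax0 / 2.0
    above = x[b >= half]
    kd0 = float(above.min()) if len(above) and above.min() > 0 else xmax / 2.0
    try:
        popt, pcov = curve_fit(
            _isotherm_ns, x, b, p0=[bmax0, kd0, 0.0],
            bounds=([1e-9, 1e-9, 0.0], [1.0, np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"intermediate-exchange KD fit failed: {exc}") from exc
    bmax, kd, ns = (float(v) for v in popt)
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan

    if kd > xmax:
        return KdFit(kd=None, regime="intermediate", max_response=bmax,
                     ns_slope=ns, censor_bound=xmax)
    return KdFit(kd=kd, regime="intermediate", max_response=bmax,
                 ns_slope=ns, ci_halfwidth=1.96 * se)


def _isotherm(x: np.ndarray, cmax: float, kd: float) -> np.ndarray:
    return cmax * x / (kd + x)


def fit_kd_fast(x, csp, saturation_fraction: float = 0.8) -> KdFit:
    """Fit CSP vs ligand concentration (µM) to a one-site isotherm.

    If the fitted curve at the highest tested concentration stays below
    ``saturation_fraction`` of CSPmax (the titration never approached
    saturation) or KD exceeds the tested range, the result is censored.
    """
    x = np.asarray(x, dtype=float)
    csp = np.asarray(csp, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 titration points")
    if 0.0 not in x:
        raise ValueError("titration must include a 0-ligand point")

    xmax = float(x.max())
    cmax0 = max(float(csp.max()), 1e-6)
    try:
        popt, pcov = curve_fit(
            _isotherm, x, csp, p0=[cmax0, xmax / 4.0],
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"fast-exchange KD fit failed: {exc}") from exc
    cmax, kd = float(popt[0]), float(popt[1])
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan

    attained = xmax / (kd + xmax)  # fraction of CSPmax reached at xmax
    if kd > xmax or attained < saturation_fraction:
        return KdFit(kd=None, regime="fast", max_response=cmax, censor_bound=xmax)
    return KdFit(kd=kd, regime="fast", max_response=cmax, ci_halfwidth=1.96 * se)


# ---------------------------------------------------------------------------
# STD and DMSO controls


def classify_std(
    std_amplitudes,
    noise_sd: float,
    has_proton_spectrum: bool = True,
    snr_min: float = 3.0,
) -> str:
    """Binder / non-binder / untestable call from an STD difference spectrum.

    A compound without a usable proton spectrum (insoluble in the assay
    buffer) is ``untestable``.  Otherwise any difference-spectrum amplitude
    reaching ``snr_min`` times the noise counts as an observed signal and
    the compound is a ``binder``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not has_proton_spectrum:
        return "untestable"
    amps = np.asarray(list(std_amplitudes), dtype=float)
    if len(amps) and (amps >= snr_min * noise_sd).any():
        return "binder"
    return "non_binder"


def dmso_control_check(
    reference: list[HSQCPeak],
    dmso: list[HSQCPeak],
    alpha: float = 0.25,
    tolerance: float = 0.02,
) -> dict:
    """Check that the co-solvent alone does not perturb the RNA structure.

    Passes when the largest CSP between the 0% and 2% DMSO spectra stays
    at or below ``tolerance`` ppm; otherwise reports offending residues.
    Assigned lists (identical residue/atom-pair keys) are paired by label,
    so even peaks that moved far are quantified; unassigned lists fall
    back to position matching.
    """
    ref_by_key = {(p.residue, p.atom_pair): p for p in reference}
    dmso_by_key = {(p.residue, p.atom_pair): p for p in dmso}
    if set(ref_by_key) == set(dmso_by_key):
        matches: dict = dmso_by_key
    else:
        matches = match_peaks(reference, dmso)
    csps = {
        key: compute_csp(ref_by_key[key], m, alpha=alpha)
        for key, m in matches.items()
        if isinstance(m, HSQCPeak)
    }
    max_csp = max(csps.values()) if csps else 0.0
    offenders = sorted({k[0] for k, v in csps.items() if v > tolerance})
    return {
        "passed": max_csp <= tolerance,
        "max_csp_ppm": max_csp,
        "offending_residues": offenders,
    }
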