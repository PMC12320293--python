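"""Multi-assay evidence integration and hit-rate accounting.

The final call is set-based, mirroring how orthogonal screens are combined
in practice: a compound is a validated binder if any assay gave positive
evidence — an STD difference-spectrum signal, a confirmed dye
displacement, or HSQC perturbations (specific or non-specific).  An HSQC
result of "weak or none" (no perturbation even at 10-fold ligand excess)
is negative evidence and never validates a compound.  Compounds untested
in every assay are inconclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["EvidenceTable", "HitRateReport", "build_evidence_table", "hit_rates", "summarize"]

STD_LEVELS = {"binder", "non_binder", "untestable"}
FID_LEVELS = {"hit", "no_change", "increase"}
HSQC_LEVELS = {"specific", "non_specific", "weak_or_none", "not_tested"}

_POSITIVE_HSQC = {"specific", "non_specific"}


@dataclass
class EvidenceTable:
    """Per-compound evidence from all assay stages plus the final call.

    ``frame`` columns: compound_id, std, fid, fid_flags, hsqc, final_call.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"compound_id", "std", "fid", "fid_flags", "hsqc", "final_call"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"evidence table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    def calls(self, column: str, value: str) -> set[str]:
        sel = self.frame[column] == value
        return set(self.frame.loc[sel, "compound_id"])

    @classmethod
    def from_csv(cls, path) -> "EvidenceTable":
        frame = pd.read_csv(path, keep_default_na=False)
        return cls(frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class HitRateReport:
    """Hit rates (%) per assay and combined, over the full roster."""

    n_compounds: int
    std_rate: float
    fid_rate: float
    dual_rate: float
    overall_rate: float
    std_binders: int
    fid_hits: int
    dual_hits: int
    validated_binders: int

    def to_dict(self) -> dict:
        return {
            "n_compounds": self.n_compounds,
            "std_rate_percent": self.std_rate,
            "fid_rate_percent": self.fid_rate,
            "dual_rate_percent": self.dual_rate,
            "overall_rate_percent": self.overall_rate,
            "std_binders": self.std_binders,
            "fid_hits": self.fid_hits,
            "dual_hits": self.dual_hits,
            "validated_binders": self.validated_binders,
            "std_rate_rounded_percent": round(self.std_rate),
        }


def _final_call(std: str, fid: str, hsqc: str) -> str:
    if std == "binder" or fid == "hit" or hsqc in _POSITIVE_HSQC:
        return "validated_binder"
    tested = std != "untestable" or fid != "not_tested" or hsqc != "not_tested"
    return "non_binder" if tested else "inconclusive"


def build_evidence_table(
    std_results: dict[str, str],
    fid_results: dict[str, str],
    hsqc_results: dict[str, str],
    roster: list[str],
    fid_flags: dict[str, str] | None = None,
) -> EvidenceTable:
    """Outer-join assay calls on the compound roster.

    Missing evidence defaults to ``untestable`` (STD), ``not_tested``
    (FID/HSQC).  Evidence for a compound outside the roster is an error.
    """
    if not roster:
        raise ValueError("roster must be non-empty")
    roster_set = set(roster)
    for name, mapping, levels in (
        ("std", std_results, STD_LEVELS),
        ("fid", fid_results, FID_LEVELS),
        ("hsqc", hsqc_results, HSQC_LEVELS),
    ):
        unknown = set(mapping) - roster_set
        if unknown:
            raise ValueError(f"{name} evidence for unknown compounds: {sorted(unknown)}")
        bad = set(mapping.values()) - levels
        if bad:
            raise ValueError(f"invalid {name} levels: {sorted(bad)}")

    fid_flags = fid_flags or {}
    rows = []
    for cid in roster:
        std = std_results.get(cid, "untestable")
        fid = fid_results.get(cid, "not_tested")
        hsqc = hsqc_results.get(cid, "not_tested")
        rows.append(
            {
                "compound_id": cid,
                "std": std,
                "fid": fid,
                "fid_flags": fid_flags.get(cid, ""),
                "hsqc": hsqc,
                "final_call": _final_call(std, fid, hsqc),
            }
        )
    return EvidenceTable(pd.DataFrame(rows))


def hit_rates(table: EvidenceTable) -> HitRateReport:
    """Per-assay and combined hit rates over the roster.

    ``dual_rate`` counts the union of STD binders and FID hits;
    ``overall_rate`` additionally counts compounds validated only by HSQC.
    """
    n = len(table)
    if n == 0:
        raise ValueError("evidence table is empty")
    std = table.calls("std", "binder")
    fid = table.calls("fid", "hit")
    validated = table.calls("final_call", "validated_binder")
    dual = std | fid
    return HitRateReport(
        n_compounds=n,
        std_rate=100.0 * len(std) / n,
        fid_rate=100.0 * len(fid) / n,
        dual_rate=100.0 * len(dual) / n,
        overall_rate=100.0 * len(validated) / n,
        std_binders=len(std),
        fid_hits=len(fid),
        dual_hits=len(dual),
        validated_binders=len(validated),
    )


def summarize(table: EvidenceTable, report: HitRateReport, out_dir=None) -> dict:
    """Machine-readable summary plus a human-readable table.

    The per-compound records round-trip losslessly: rebuilding an
    EvidenceTable from the summary and recomputing rates reproduces the
    report.  Optionally writes ``evidence.csv`` and ``report.json`` into
    ``out_dir``.
    """
    records = []
    for row in table.frame.itertuples():
        rec = {
            "compound_id": row.compound_id,
            "std": row.std,
            "fid": row.fid,
            "hsqc": row.hsqc,
            "final_call": row.final_call,
        }
        if row.fid_flags:
            rec["fid_flags"] = row.fid_flags
        records.append(rec)
    summary = {"compounds": records, "rates": report.to_dict()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "evidence.csv")
        (out / "report.json").write_text(json.dumps(summary, indent=2))
    return summary


def table_from_summary(summary: dict) -> EvidenceTable:
    """Rebuild the evidence table from a :func:`summarize` payload."""
    rows = []
    for rec in summary["compounds"]:
        rows.append(
            {
                "compound_id": rec["compound_id"],
                "std": rec["std"],
                "fid": rec["fid"],
                "fid_flags": rec.get("fid_flags", ""),
                "hsqc": rec["hsqc"],
                "final_call": rec["final_call"],
            }
        )
    return EvidenceTable(pd.DataFrame(rows))
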