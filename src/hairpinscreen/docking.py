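"""Docking-score triage with selectivity counter-screening.

Scores are predicted binding energies in kcal/mol; more negative is more
favourable.  Hits against a target are compounds whose score lies at least
``k_sd`` sample standard deviations below the library mean for that target.
A counter-screen removes hits that satisfy the same rule on any control
RNA, enriching for target selectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DockingTable", "HitList", "select_hits", "selectivity_filter", "rank_and_take"]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than two scores available for a target."""


@dataclass
class DockingTable:
    """Per-compound, per-target docking scores.

    ``records`` has columns ``compound_id``, ``target_id``,
    ``score_kcal_mol``; at most one score per (compound, target).
    """

    records: pd.DataFrame
    primary_target: str | None = None

    def __post_init__(self) -> None:
        required = {"compound_id", "target_id", "score_kcal_mol"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"docking table missing columns: {sorted(missing)}")
        if self.records.duplicated(["compound_id", "target_id"]).any():
            raise ValueError("more than one score per (compound, target)")
        if not np.isfinite(self.records["score_kcal_mol"]).all():
            raise ValueError("non-finite docking scores")

    def scores_for(self, target: str) -> pd.Series:
        sub = self.records[self.records["target_id"] == target]
        return sub.set_index("compound_id")["score_kcal_mol"]

    @property
    def targets(self) -> set[str]:
        return set(self.records["target_id"].unique())

    @classmethod
    def from_csv(cls, path, primary_target: str | None = None) -> "DockingTable":
        return cls(pd.read_csv(path), primary_target=primary_target)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class HitList:
    """Ordered docking hits with the statistics that defined them."""

    compound_ids: list[str]
    scores: dict[str, float]
    threshold: float
    mean: float
    sd: float
    target: str
    eliminated_by_control: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.compound_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "score_kcal_mol": [self.scores[c] for c in self.compound_ids],
                "rank": np.arange(1, len(self.compound_ids) + 1),
            }
        )

    def summary(self) -> dict:
        return {
            "target": self.target,
            "mean_kcal_mol": self.mean,
            "sd_kcal_mol": self.sd,
            "threshold_kcal_mol": self.threshold,
            "n_hits": len(self.compound_ids),
            "eliminated_by_control": [list(t) for t in self.eliminated_by_control],
        }


def _hit_ids(scores: pd.Series, k_sd: float) -> tuple[set[str], float, float, float]:
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        # degenerate library: no compound is distinguishable, admit none
        return set(), mean - k_sd * sd, mean, sd
    threshold = mean - k_sd * sd
    return set(scores.index[scores <= threshold]), threshold, mean, sd


def select_hits(table: DockingTable, target: str, k_sd: float = 2.0) -> HitList:
    """Select compounds scoring at least ``k_sd`` sample SD below the mean.

    Mean and SD (ddof=1) are computed over all compounds scored against
    ``target``; hits are sorted most-favourable first with a lexicographic
    tie-break on compound id.
    """
    scores = table.scores_for(target)
    if len(scores) < 2:
        raise InsufficientDataError(
            f"need >= 2 scores for target {target!r}, got {len(scores)}"
        )
    ids, threshold, mean, sd = _hit_ids(scores, k_sd)
    ordered = sorted(ids, key=lambda c: (scores[c], c))
    return HitList(
        compound_ids=ordered,
        scores={c: float(scores[c]) for c in ordered},
        threshold=threshold,
        mean=mean,
        sd=sd,
        target=target,
    )


def selectivity_filter(
    hits: HitList,
    table: DockingTable,
    control_targets: list[str],
    k_sd: float = 2.0,
    per_compound: bool = False,
) -> HitList:
    """Drop hits that also pass the hit rule on any control target.

    Each control's rule is computed over all compounds scored against that
    control.  With ``per_compound=True`` the alternative reading is used
    instead: a hit is dropped when its control score is more favourable
    than its primary-target score.  Hits lacking a control score are
    retained with a logged warning.
    """
    missing = set(control_targets) - table.targets
    if missing:
        raise ValueError(f"control targets absent from table: {sorted(missing)}")

    eliminated: list[tuple[str, str]] = list(hits.eliminated_by_control)
    drop: set[str] = set()
    for control in control_targets:
        control_scores = table.scores_for(control)
        if per_compound:
            control_hits = None
        else:
            control_hits, *_ = _hit_ids(control_scores, k_sd)
        for cid in hits.compound_ids:
            if cid in drop:
                continue
            if cid not in control_scores.index:
                logger.warning(
                    "hit %s has no score on control %s; retained", cid, control
                )
                continue
            if per_compound:
                also_bound = control_scores[cid] < hits.scores[cid]
            else:
                also_bound = cid in control_hits
            if also_bound:
                drop.add(cid)
                eliminated.append((cid, control))

    kept = [c for c in hits.compound_ids if c not in drop]
    return HitList(
        compound_ids=kept,
        scores={c: hits.scores[c] for c in kept},
        threshold=hits.threshold,
        mean=hits.mean,
        sd=hits.sd,
        target=hits.target,
        eliminated_by_control=eliminated,
    )


def rank_and_take(hits: HitList, n: int) -> HitList:
    """Keep the ``n`` most favourable hits (ties broken by compound id)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    kept = hits.compound_ids[:n]
    return HitList(
        compound_ids=kept,
        scores={c: hits.scores[c] for c in kept},
        threshold=hits.threshold,
        mean=hits.mean,
        sd=hits.sd,
        target=hits.target,
        eliminated_by_control=list(hits.eliminated_by_control),
    )
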