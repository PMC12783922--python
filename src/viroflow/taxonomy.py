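"""Consensus taxonomy across five classification tools.

Each tool's call is first screened by its own acceptance rule:

* vConTACT2: more than half of the vOTU's proteins assigned to one viral
  family, with the worst supporting bit score >= 50
* BLASTn (viral genome homology): top best hit at >= 90% identity and
  >= 75% alignment coverage
* geNomad: taxonomy taken as reported (default-parameter run)
* PhaGCN2: prediction score strictly > 0.5
* VPF-Class: membership ratio >= 0.5 and confidence >= 0.75

Accepted lineages are then integrated hierarchically in the priority
order vConTACT2 > BLASTn > geNomad > PhaGCN2 > VPF-Class.  When tools
conflict at a lower rank but share a higher one, the shared higher rank
wins (lowest common ancestor); when a pair of accepted lineages shares
no rank at all, the highest-priority tool's lineage is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .lineage import EMPTY_LINEAGE, RANK_LABELS, RankedLineage, lca, lca_all
from .records import VOTURecord

#: Integration priority, highest first.
TOOL_PRIORITY = ("vcontact2", "blastn", "genomad", "phagcn2", "vpfclass")

VCONTACT2_MIN_BITSCORE = 50.0
BLASTN_MIN_IDENTITY = 90.0
BLASTN_MIN_COVERAGE = 75.0
PHAGCN2_MIN_SCORE = 0.5          # strict >
VPFCLASS_MIN_MEMBERSHIP = 0.5    # inclusive
VPFCLASS_MIN_CONFIDENCE = 0.75   # inclusive

#: Ranks reported by the classification summary.
SUMMARY_RANKS = ("realm", "kingdom", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class ToolAssignment:
    """One tool's taxonomy call for one vOTU, with its evidence scores."""

    votu_id: str
    tool: str
    lineage: RankedLineage
    evidence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tool not in TOOL_PRIORITY:
            raise ValueError(f"unknown taxonomy tool: {self.tool!r}")


# ---------------------------------------------------------------------------
# per-tool acceptance rules
# ---------------------------------------------------------------------------

def accept_vcontact2(a: ToolAssignment) -> Optional[RankedLineage]:
    """Accept when >50% of proteins back one family at bit score >= 50."""
    total = a.evidence.get("protein_total", 0)
    assigned = a.evidence.get("protein_assigned_to_family", 0)
    bitscore = a.evidence.get("min_bitscore", 0.0)
    if total <= 0:
        return None
    if assigned / total > 0.5 and bitscore >= VCONTACT2_MIN_BITSCORE:
        return a.lineage
    return None


def accept_blastn(a: ToolAssignment) -> Optional[RankedLineage]:
    """Accept the top best hit at >= 90% identity and >= 75% coverage."""
    if (
        a.evidence.get("hit_rank", 0) == 1
        and a.evidence.get("pct_identity", 0.0) >= BLASTN_MIN_IDENTITY
        and a.evidence.get("pct_coverage", 0.0) >= BLASTN_MIN_COVERAGE
    ):
        return a.lineage
    return None


def accept_genomad(a: ToolAssignment) -> Optional[RankedLineage]:
    """geNomad lineages are pre-accepted; an empty lineage is no call."""
    return a.lineage if not a.lineage.is_empty else None


def accept_phagcn2(a: ToolAssignment) -> Optional[RankedLineage]:
    if a.evidence.get("score", 0.0) > PHAGCN2_MIN_SCORE:
        return a.lineage
    return None


def accept_vpfclass(a: ToolAssignment) -> Optional[RankedLineage]:
    if (
        a.evidence.get("membership_ratio", 0.0) >= VPFCLASS_MIN_MEMBERSHIP
        and a.evidence.get("confidence", 0.0) >= VPFCLASS_MIN_CONFIDENCE
    ):
        return a.lineage
    return None


_ACCEPT = {
    "vcontact2": accept_vcontact2,
    "blastn": accept_blastn,
    "genomad": accept_genomad,
    "phagcn2": accept_phagcn2,
    "vpfclass": accept_vpfclass,
}


def accept(a: ToolAssignment) -> Optional[RankedLineage]:
    """Dispatch to the tool-specific acceptance rule."""
    lin = _ACCEPT[a.tool](a)
    if lin is not None and lin.is_empty:
        return None
    return lin


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(
    accepted: Mapping[str, RankedLineage] | Sequence[tuple[str, RankedLineage]],
    mode: str = "lca",
) -> RankedLineage:
    """Integrate accepted per-tool lineages into one consensus lineage.

    ``accepted`` maps tool name -> accepted lineage (at most one per
    tool).  With ``mode="lca"`` (default): no accepted lineage yields the
    empty lineage; one yields that lineage; several yield their LCA when
    every pair shares at least their topmost mutually named rank, and
    otherwise — a pair that agrees on no rank at all — the
    highest-priority tool's lineage.  With ``mode="first-accept"`` the
    highest-priority accepted lineage is returned unconditionally.
    """
    items = dict(accepted)
    unknown = set(items) - set(TOOL_PRIORITY)
    if unknown:
        raise ValueError(f"unknown taxonomy tool(s): {sorted(unknown)}")
    ordered = [(t, items[t]) for t in TOOL_PRIORITY if t in items and not items[t].is_empty]
    if not ordered:
        return EMPTY_LINEAGE
    if mode == "first-accept":
        return ordered[0][1]
    if mode != "lca":
        raise ValueError(f"unknown integration mode: {mode!r}")
    if len(ordered) == 1:
        return ordered[0][1]
    lineages = [lin for _, lin in ordered]
    for i, a in enumerate(lineages):
        for b in lineages[i + 1 :]:
            if lca(a, b).is_empty:
                # top-rank conflict: fall back to the priority order
                return ordered[0][1]
    return lca_all(lineages)


def integrate_assignments(
    assignments: Iterable[ToolAssignment], mode: str = "lca"
) -> dict[str, RankedLineage]:
    """Screen and integrate raw tool assignments, one lineage per vOTU."""
    accepted_by_votu: dict[str, dict[str, RankedLineage]] = {}
    for a in assignments:
        lin = accept(a)
        accepted_by_votu.setdefault(a.votu_id, {})
        if lin is not None:
            if a.tool in accepted_by_votu[a.votu_id]:
                raise ValueError(
                    f"vOTU {a.votu_id}: more than one accepted {a.tool} assignment"
                )
            accepted_by_votu[a.votu_id][a.tool] = lin
    return {
        votu: integrate(tool_map, mode=mode)
        for votu, tool_map in accepted_by_votu.items()
    }


def best_blastn_hit(rows: pd.DataFrame) -> pd.DataFrame:
    """Mark the top best hit per vOTU: highest bitscore, tie -> lowest
    e-value, then first in file; returns the table with ``hit_rank`` set."""
    out = rows.copy().reset_index(drop=True)
    out["_file_order"] = range(len(out))
    out = out.sort_values(
        ["votu_id", "bitscore", "evalue", "_file_order"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    out["hit_rank"] = out.groupby("votu_id").cumcount() + 1
    return out.sort_values("_file_order").drop(columns="_file_order").reset_index(drop=True)


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def classification_summary(
    votus: Sequence[VOTURecord] | Mapping[str, RankedLineage],
) -> pd.DataFrame:
    """Counts and percentages of vOTUs classified at each rank.

    Family-level membership is reported twice: ``family`` counts only
    vOTUs with a named family, while ``family_or_subfamily`` also counts
    vOTUs resolved only to a subfamily — the bookkeeping that folds
    subfamily names into family-level tallies.
    """
    if isinstance(votus, Mapping):
        lineages = list(votus.values())
    else:
        lineages = [v.lineage for v in votus]
    total = len(lineages)
    rows = []
    for rank in SUMMARY_RANKS:
        n = sum(lin.name_at(rank) is not None for lin in lineages)
        rows.append({"rank": rank, "count": n})
    n_fam_or_sub = sum(
        lin.name_at("family") is not None or lin.name_at("subfamily") is not None
        for lin in lineages
    )
    rows.append({"rank": "family_or_subfamily", "count": n_fam_or_sub})
    n_any = sum(not lin.is_empty for lin in lineages)
    rows.append({"rank": "any", "count": n_any})
    df = pd.DataFrame(rows)
    df["total"] = total
    df["percent"] = 100.0 * df["count"] / total if total else 0.0
    return df
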