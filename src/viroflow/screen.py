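"""Viral-contig screening across four prediction tools.

Each upstream predictor reports candidate viral contigs with its own
score semantics; a contig is retained when it is at least 10 kb long and
at least one tool accepts it:

* geNomad: virus score >= 0.8
* VirSorter2: max score strictly > 0.9
* DeepVirFinder: score >= 0.9 and p < 0.05
* VIBRANT: every reported contig (the tool pre-filters internally)

The accepted sets are merged (union), mirroring how candidate vContigs
from the four pipelines are pooled before quality checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

TOOLS = ("genomad", "virsorter2", "deepvirfinder", "vibrant")

GENOMAD_MIN_SCORE = 0.8       # inclusive
VIRSORTER2_MIN_SCORE = 0.9    # exclusive (strict >)
DVF_MIN_SCORE = 0.9           # inclusive
DVF_MAX_P = 0.05              # exclusive (p < 0.05)
MIN_CONTIG_LENGTH = 10_000


@dataclass(frozen=True)
class PredictorHit:
    """One tool's viral call for one contig."""

    contig_id: str
    tool: str
    length_bp: int
    score: Optional[float] = None
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown predictor tool: {self.tool!r}")
        if self.length_bp < 0:
            raise ValueError(
                f"contig {self.contig_id}: negative length {self.length_bp}"
            )
        if self.tool != "vibrant" and self.score is None:
            raise ValueError(
                f"contig {self.contig_id}: {self.tool} hit is missing a score"
            )
        if self.tool == "deepvirfinder" and self.p_value is None:
            raise ValueError(
                f"contig {self.contig_id}: deepvirfinder hit is missing a p-value"
            )
        if self.tool != "deepvirfinder" and self.p_value is not None:
            raise ValueError(
                f"contig {self.contig_id}: p-value only applies to deepvirfinder"
            )


def hit_passes(hit: PredictorHit) -> bool:
    """Apply the per-tool score threshold (length not considered here)."""
    if hit.tool == "genomad":
        return hit.score >= GENOMAD_MIN_SCORE
    if hit.tool == "virsorter2":
        return hit.score > VIRSORTER2_MIN_SCORE
    if hit.tool == "deepvirfinder":
        return hit.score >= DVF_MIN_SCORE and hit.p_value < DVF_MAX_P
    # vibrant: every reported contig counts as a hit
    return True


def screen_contigs(
    hits: Iterable[PredictorHit], min_len: int = MIN_CONTIG_LENGTH
) -> set[str]:
    """Union of contigs accepted by at least one tool, at the length floor.

    A contig passes iff its length is >= ``min_len`` and any of its hits
    satisfies that tool's acceptance rule.
    """
    passed: set[str] = set()
    for hit in hits:
        if hit.length_bp >= min_len and hit_passes(hit):
            passed.add(hit.contig_id)
    return passed


def hits_from_tables(
    genomad: pd.DataFrame | None = None,
    virsorter2: pd.DataFrame | None = None,
    deepvirfinder: pd.DataFrame | None = None,
    vibrant: pd.DataFrame | None = None,
) -> list[PredictorHit]:
    """Convert per-tool dialect tables (see :mod:`viroflow.tables`) to hits."""
    hits: list[PredictorHit] = []
    if genomad is not None:
        for row in genomad.itertuples(index=False):
            hits.append(
                PredictorHit(row.contig_id, "genomad", int(row.length_bp), float(row.score))
            )
    if virsorter2 is not None:
        for row in virsorter2.itertuples(index=False):
            hits.append(
                PredictorHit(row.contig_id, "virsorter2", int(row.length_bp), float(row.score))
            )
    if deepvirfinder is not None:
        for row in deepvirfinder.itertuples(index=False):
            hits.append(
                PredictorHit(
                    row.contig_id,
                    "deepvirfinder",
                    int(row.length_bp),
                    float(row.score),
                    p_value=float(row.p_value),
                )
            )
    if vibrant is not None:
        for row in vibrant.itertuples(index=False):
            hits.append(PredictorHit(row.contig_id, "vibrant", int(row.length_bp)))
    return hits
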