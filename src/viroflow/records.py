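"""Shared domain records used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .lineage import EMPTY_LINEAGE, RankedLineage

#: CheckV's five completeness tiers.
QUALITY_TIERS = ("Complete", "High", "Medium", "Low", "Not-determined")

#: Final lifestyle vocabulary.
LIFESTYLES = ("lytic", "lysogenic", "undetermined")


@dataclass
class VOTURecord:
    """A dereplicated viral OTU (species-like unit at >=95% ANI / >=85% AF).

    The representative is the longest member contig; ties break toward the
    lexicographically smallest contig id.
    """

    votu_id: str
    representative_contig: str
    member_contigs: list[str]
    length_bp: int
    quality_tier: str = "Not-determined"
    lineage: RankedLineage = field(default_factory=RankedLineage)
    lifestyle: str = "undetermined"

    def __post_init__(self) -> None:
        if self.length_bp < 10_000:
            raise ValueError(
                f"vOTU {self.votu_id}: length {self.length_bp} below the 10 kb floor"
            )
        if self.quality_tier not in QUALITY_TIERS:
            raise ValueError(
                f"vOTU {self.votu_id}: unknown quality tier {self.quality_tier!r}"
            )
        if self.lifestyle not in LIFESTYLES:
            raise ValueError(
                f"vOTU {self.votu_id}: unknown lifestyle {self.lifestyle!r}"
            )
        if self.representative_contig not in self.member_contigs:
            raise ValueError(
                f"vOTU {self.votu_id}: representative not among members"
            )


@dataclass(frozen=True)
class SampleEnvironment:
    """Physicochemical context of one sediment sample.

    pH is unitless, EC is electrical conductivity, TN / NH4_N / NO3_N /
    TP / TOC are mass fractions of total nitrogen, ammonium-N, nitrate-N,
    total phosphorus and total organic carbon, and WT is water
    temperature in deg C.
    """

    sample_id: str
    pH: float
    EC: float
    TN: float
    NH4_N: float
    NO3_N: float
    TP: float
    TOC: float
    WT: float

    def __post_init__(self) -> None:
        import math

        for name in ("pH", "EC", "TN", "NH4_N", "NO3_N", "TP", "TOC", "WT"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(
                    f"sample {self.sample_id}: non-finite {name} value {v!r}"
                )


ENV_VARIABLES = ("pH", "EC", "TN", "NH4_N", "NO3_N", "TP", "TOC", "WT")


@dataclass(frozen=True)
class VirusHostLink:
    """A predicted virus-host pairing passed in from an upstream host
    predictor run at a confidence cutoff of 90."""

    votu_id: str
    host_genome_id: str
    host_lineage: RankedLineage = EMPTY_LINEAGE
    confidence: float = 90.0

    def __post_init__(self) -> None:
        if self.confidence < 90:
            raise ValueError(
                f"link {self.votu_id}-{self.host_genome_id}: confidence "
                f"{self.confidence} below the 90 cutoff"
            )
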