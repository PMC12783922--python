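"""Ranked viral lineages and lowest-common-ancestor resolution.

Lineages follow the ICTV-style ladder realm > kingdom > phylum > class >
order > family > subfamily > genus.  A lineage names a contiguous run of
ranks (leading ranks may be unresolved, but no gap may separate two named
ranks), and two lineages are comparable at a rank only when both name it.
The fully unclassified (empty) lineage is a first-class value distinct
from "not evaluated".
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from functools import reduce
from typing import Iterable, Optional

#: Ordered rank vocabulary, highest first.  Subfamily sits between family
#: and genus so that subfamily-only classifications (e.g. *Queuovirinae*)
#: can be counted either strictly or folded into family-level tallies.
RANKS: tuple[str, ...] = (
    "realm",
    "kingdom",
    "phylum",
    "class_",
    "order",
    "family",
    "subfamily",
    "genus",
)

#: Rank names as they appear in serialized tables (no trailing underscore).
RANK_LABELS: tuple[str, ...] = tuple(r.rstrip("_") for r in RANKS)


def _clean(name: Optional[str]) -> Optional[str]:
    if name is None:
        return None
    name = name.strip()
    return name or None


@dataclass(frozen=True)
class RankedLineage:
    """A taxonomic lineage with optional names at each of the eight ranks.

    Taxon names are matched case-sensitively after whitespace trimming;
    no synonym resolution is attempted.
    """

    realm: Optional[str] = None
    kingdom: Optional[str] = None
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    subfamily: Optional[str] = None
    genus: Optional[str] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            object.__setattr__(self, f.name, _clean(getattr(self, f.name)))

    # -- basic queries -------------------------------------------------
    def name_at(self, rank: str) -> Optional[str]:
        if rank == "class":
            rank = "class_"
        if rank not in RANKS:
            raise KeyError(f"unknown rank: {rank!r}")
        return getattr(self, rank)

    def names(self) -> tuple[Optional[str], ...]:
        return tuple(getattr(self, r) for r in RANKS)

    @property
    def is_empty(self) -> bool:
        return all(n is None for n in self.names())

    def depth(self) -> int:
        """Number of named ranks."""
        return sum(n is not None for n in self.names())

    def deepest_rank(self) -> Optional[str]:
        """Label of the deepest named rank, or None if empty."""
        deepest = None
        for label, name in zip(RANK_LABELS, self.names()):
            if name is not None:
                deepest = label
        return deepest

    def is_contiguous(self) -> bool:
        """True when the named ranks form one unbroken run (no internal gap).

        Subfamily is an optional rank: a lineage naming family and genus
        but no subfamily has no gap.
        """
        names = [
            n
            for rank, n in zip(RANKS, self.names())
            if not (rank == "subfamily" and n is None)
        ]
        started = ended = False
        for n in names:
            if n is not None:
                if ended:
                    return False
                started = True
            elif started:
                ended = True
        return True

    def is_ancestor_or_equal(self, other: "RankedLineage") -> bool:
        """True when every rank this lineage names is named identically in *other*."""
        return all(
            a is None or a == b for a, b in zip(self.names(), other.names())
        )

    def truncated(self, rank: str) -> "RankedLineage":
        """Copy of this lineage with all ranks below *rank* dropped."""
        if rank == "class":
            rank = "class_"
        idx = RANKS.index(rank)
        return RankedLineage(
            **{r: getattr(self, r) for r in RANKS[: idx + 1]}
        )

    # -- serialization -------------------------------------------------
    def to_string(self) -> str:
        """Semicolon-joined ``rank=name`` pairs for the named ranks."""
        parts = [
            f"{label}={name}"
            for label, name in zip(RANK_LABELS, self.names())
            if name is not None
        ]
        return ";".join(parts)

    @classmethod
    def from_string(cls, text: str) -> "RankedLineage":
        text = (text or "").strip()
        if not text:
            return cls()
        kwargs: dict[str, str] = {}
        for part in text.split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                raise ValueError(f"malformed lineage component: {part!r}")
            label, name = part.split("=", 1)
            label = label.strip()
            if label == "class":
                label = "class_"
            if label not in RANKS:
                raise ValueError(f"unknown rank in lineage string: {label!r}")
            kwargs[label] = name
        return cls(**kwargs)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string() or "<unclassified>"


#: The fully unclassified lineage.
EMPTY_LINEAGE = RankedLineage()


def lca(a: RankedLineage, b: RankedLineage) -> RankedLineage:
    """Lowest common ancestor of two lineages.

    Walks the ranks from realm downward and keeps the shared prefix: a
    rank named identically by both is retained, a rank named by neither
    is skipped, and the walk stops at the first rank where the two
    lineages disagree or where only one of them resolves a name.  Two
    lineages that conflict at their topmost mutually named rank therefore
    collapse to the empty lineage, and ``lca(x, EMPTY_LINEAGE)`` is empty
    for every ``x``.  The operation is commutative and associative, so it
    folds over any number of lineages in any order.
    """
    kwargs: dict[str, str] = {}
    for rank, na, nb in zip(RANKS, a.names(), b.names()):
        if na is None and nb is None:
            continue
        if na is None or nb is None or na != nb:
            break
        kwargs[rank] = na
    return RankedLineage(**kwargs)


def lca_all(lineages: Iterable[RankedLineage]) -> RankedLineage:
    """Fold :func:`lca` over an iterable of lineages (empty iterable -> empty)."""
    lineages = list(lineages)
    if not lineages:
        return EMPTY_LINEAGE
    return reduce(lca, lineages)
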