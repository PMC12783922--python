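"""Greedy centroid dereplication of viral contigs into vOTUs.

Contigs are sorted by length descending (ties broken by contig id
ascending) and processed in that order: a contig joins the first
existing centroid it matches at >= 95% ANI and >= 85% alignment
fraction, otherwise it founds a new cluster and becomes its centroid.
Because centroids are founded in length order, every representative is
the longest member of its cluster, and representatives are mutually
below the clustering thresholds in founding order.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .records import VOTURecord
from .similarity import PairwiseSimilarity, all_vs_all

ANI_MIN = 95.0
AF_MIN = 85.0


class MissingPairError(KeyError):
    """The similarity set does not cover a required contig pair."""


def _sim_lookup(
    sims: Iterable[PairwiseSimilarity],
) -> dict[frozenset, tuple[float, float]]:
    table: dict[frozenset, tuple[float, float]] = {}
    for s in sims:
        table[s.key] = (s.ani_pct, s.af_pct)
    return table


def greedy_cluster(
    sims: Iterable[PairwiseSimilarity],
    lengths: Mapping[str, int],
    ani_min: float = ANI_MIN,
    af_min: float = AF_MIN,
    votu_prefix: str = "vOTU",
) -> list[VOTURecord]:
    """Cluster contigs into vOTUs by the greedy centroid rule.

    ``sims`` must cover every unordered pair of ids in ``lengths``;
    a missing pair raises :class:`MissingPairError`.  The output order
    follows centroid founding order (longest first), which is invariant
    to the order of ``sims`` rows.
    """
    table = _sim_lookup(sims)
    order = sorted(lengths, key=lambda c: (-lengths[c], c))

    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for contig in order:
        placed = False
        for centroid in centroids:
            pair = frozenset((contig, centroid))
            if pair not in table:
                raise MissingPairError(
                    f"similarity missing for pair ({contig}, {centroid})"
                )
            ani, af = table[pair]
            if ani >= ani_min and af >= af_min:
                members[centroid].append(contig)
                placed = True
                break
        if not placed:
            centroids.append(contig)
            members[contig] = [contig]

    width = max(4, len(str(len(centroids))))
    votus = []
    for i, centroid in enumerate(centroids, start=1):
        votus.append(
            VOTURecord(
                votu_id=f"{votu_prefix}_{i:0{width}d}",
                representative_contig=centroid,
                member_contigs=members[centroid],
                length_bp=int(lengths[centroid]),
            )
        )
    return votus


def dereplicate(
    sequences: Mapping[str, str],
    ani_min: float = ANI_MIN,
    af_min: float = AF_MIN,
    **ani_kwargs,
) -> list[VOTURecord]:
    """All-vs-all ANI followed by greedy clustering, from raw sequences."""
    sims = all_vs_all(dict(sequences), **ani_kwargs)
    lengths = {cid: len(seq) for cid, seq in sequences.items()}
    return greedy_cluster(sims, lengths, ani_min=ani_min, af_min=af_min)
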