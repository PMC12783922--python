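"""Pairwise ANI / alignment-fraction estimation for contig dereplication.

ANI here is the length-weighted identity over accepted local alignment
blocks, and the alignment fraction (AF) is the proportion of the
*shorter* sequence covered by those blocks — the convention used when
clustering viral contigs into vOTUs at 95% ANI / 85% AF.

The block finder tiles the shorter sequence into fixed windows and
aligns each window end-to-free against the longer sequence (edlib infix
mode).  A window becomes an accepted block when its best placement
reaches the block identity floor; unrelated sequences produce no
accepted blocks and therefore AF = 0.  ``N`` bases never match anything,
including other ``N`` s.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

_VALID = re.compile(r"^[ACGTN]+$")
_CIGAR_OP = re.compile(r"(\d+)([=XIDM])")

#: Window length used to tile the shorter sequence into candidate blocks.
BLOCK_WINDOW = 500
#: Minimum identity for a window to count as a real alignment block.
BLOCK_MIN_IDENTITY = 0.80


@dataclass(frozen=True)
class PairwiseSimilarity:
    """ANI/AF of one ordered pair; symmetric by construction because both
    quantities are computed on the shorter sequence."""

    query_id: str
    target_id: str
    ani_pct: float  # 0-100, identity over accepted blocks
    af_pct: float   # 0-100, accepted-block cover of the shorter sequence

    @property
    def key(self) -> frozenset:
        return frozenset((self.query_id, self.target_id))


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence: {label}")
    seq = seq.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence {label} contains invalid characters: {bad}")
    return seq


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment columns) from an extended edlib cigar."""
    matches = columns = 0
    for count, op in _CIGAR_OP.findall(cigar):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def pairwise_ani(
    seq_a: str,
    seq_b: str,
    query_id: str = "a",
    target_id: str = "b",
    window: int = BLOCK_WINDOW,
    block_min_identity: float = BLOCK_MIN_IDENTITY,
) -> PairwiseSimilarity:
    """Estimate ANI and alignment fraction between two nucleotide sequences."""
    seq_a = _check_sequence(seq_a, query_id)
    seq_b = _check_sequence(seq_b, target_id)

    # operate on (shorter, longer); the result is order-independent
    if len(seq_a) <= len(seq_b):
        short, long_ = seq_a, seq_b
    else:
        short, long_ = seq_b, seq_a

    # lowercase n in the query so N never matches, even against another N
    short = short.replace("N", "n")

    total_matches = 0
    total_columns = 0
    covered = 0
    for start in range(0, len(short), window):
        chunk = short[start : start + window]
        res = edlib.align(chunk, long_, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        matches, columns = _cigar_stats(res["cigar"])
        if columns == 0:
            continue
        identity = matches / columns
        if identity >= block_min_identity:
            total_matches += matches
            total_columns += columns
            covered += len(chunk)

    if total_columns == 0:
        ani = 0.0
        af = 0.0
    else:
        ani = 100.0 * total_matches / total_columns
        af = 100.0 * covered / len(short)
    return PairwiseSimilarity(query_id, target_id, ani_pct=ani, af_pct=af)


_SKETCH_K = 16
_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)
_SKETCH_KEEP = 8  # keep ~1/8 of k-mers (minimizer-style hash sampling)


def _kmer_sketch(seq: str, k: int = _SKETCH_K) -> np.ndarray:
    """Sorted array of hash-sampled k-mer codes (2-bit packed)."""
    if len(seq) < k:
        return np.empty(0, dtype=np.uint64)
    vals = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.zeros(len(seq) - k + 1, dtype=np.uint64)
    # A->0 C->1 G->2 T->3; N collapses onto A (harmless for a prescreen)
    lut = np.zeros(256, dtype=np.uint64)
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    base = lut[vals]
    for i in range(k):
        code = (code << np.uint64(2)) | base[i : len(base) - k + 1 + i]
    hashed = code * _HASH_MULT
    keep = code[hashed < np.uint64(2**64 // _SKETCH_KEEP)]
    return np.unique(keep)


def all_vs_all(
    sequences: dict[str, str],
    prescreen: bool = True,
    min_shared_kmers: int = 3,
    **kwargs,
) -> list[PairwiseSimilarity]:
    """Pairwise similarities for every unordered pair of named sequences.

    With ``prescreen`` (default) a shared-k-mer sketch test skips the
    alignment for clearly unrelated pairs — any pair near the 95% ANI
    clustering threshold shares thousands of sampled 16-mers, while
    unrelated pairs share essentially none.  Skipped pairs are reported
    with ANI = AF = 0 so downstream clustering still sees every pair.
    """
    ids = sorted(sequences)
    sketches = (
        {cid: _kmer_sketch(sequences[cid].upper()) for cid in ids} if prescreen else {}
    )
    sims: list[PairwiseSimilarity] = []
    for i, qid in enumerate(ids):
        for tid in ids[i + 1 :]:
            if prescreen:
                shared = np.intersect1d(
                    sketches[qid], sketches[tid], assume_unique=True
                ).size
                if shared < min_shared_kmers:
                    sims.append(PairwiseSimilarity(qid, tid, 0.0, 0.0))
                    continue
            sims.append(
                pairwise_ani(sequences[qid], sequences[tid], qid, tid, **kwargs)
            )
    return sims
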