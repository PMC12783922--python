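"""Curation of auxiliary metabolic gene (AMG) candidates.

Candidates arrive as DRAM-v-style rows (auxiliary score 1-5 plus
single-letter category flags).  Curation proceeds in four independent
checks:

* confidence filter — auxiliary_score <= 3 and a metabolic flag set of
  M alone or M together with E and/or K;
* viral-context (flank) check — a viral hallmark or viral-like gene
  within a window on each existing side of the candidate;
* novelty — the candidate protein fails to cluster with any reference
  AMG protein at >= 30% identity over >= 60% bidirectional coverage;
* host redundancy / contamination — protein-level homology of the AMG
  to the linked host's proteome, guarded by a nucleotide-level check
  that the host genome is not carrying the vOTU itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

VALID_FLAGS = frozenset("MEKVAPFTB")
METABOLIC_FLAGS = frozenset("MEK")

VIRAL_CATEGORIES = ("viral-hallmark", "viral-like")
GENE_CATEGORIES = VIRAL_CATEGORIES + ("other",)

NOVELTY_MIN_ID = 0.30
NOVELTY_MIN_COV = 0.60
HOST_HOMOLOG_MIN_ID = 40.0   # percent, strict >
HOST_MIN_QCOV = 60.0         # percent of the viral query aligned


class FlagError(ValueError):
    """An AMG row carries a flag letter outside the DRAM-v vocabulary."""


@dataclass(frozen=True)
class AMGCandidate:
    gene_id: str
    votu_id: str
    ko_id: str
    auxiliary_score: int
    amg_flags: frozenset[str]
    position_on_contig: int
    protein_seq: str = ""
    neighborhood: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        bad = self.amg_flags - VALID_FLAGS
        if bad:
            raise FlagError(
                f"gene {self.gene_id}: unknown amg_flag letter(s) {sorted(bad)}"
            )
        if not 1 <= self.auxiliary_score <= 5:
            raise ValueError(
                f"gene {self.gene_id}: auxiliary_score {self.auxiliary_score} outside 1..5"
            )
        for _, cat in self.neighborhood:
            if cat not in GENE_CATEGORIES:
                raise ValueError(
                    f"gene {self.gene_id}: unknown neighborhood category {cat!r}"
                )


def parse_flags(text: str, gene_id: str = "?") -> frozenset[str]:
    """Parse a DRAM-v flag string like ``MEK`` or ``M;E``."""
    letters = frozenset(c for c in text.upper() if c.isalpha())
    bad = letters - VALID_FLAGS
    if bad:
        raise FlagError(f"gene {gene_id}: unknown amg_flag letter(s) {sorted(bad)}")
    return letters


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    pct_identity: float
    query_coverage_pct: float
    bitscore: float


# ---------------------------------------------------------------------------
# confidence filter
# ---------------------------------------------------------------------------

def passes_filter(cand: AMGCandidate, max_auxiliary_score: int = 3) -> bool:
    return (
        cand.auxiliary_score <= max_auxiliary_score
        and "M" in cand.amg_flags
        and cand.amg_flags <= METABOLIC_FLAGS
    )


def filter_amgs(
    cands: Iterable[AMGCandidate], max_auxiliary_score: int = 3
) -> list[AMGCandidate]:
    """Retain confident metabolic candidates: auxiliary_score <= 3 and a
    flag set of M, optionally with E and/or K, and nothing else."""
    return [c for c in cands if passes_filter(c, max_auxiliary_score)]


# ---------------------------------------------------------------------------
# flank inspection
# ---------------------------------------------------------------------------

def check_flanks(cand: AMGCandidate, window: int = 3) -> bool:
    """True when each existing flank carries viral context near the AMG.

    A flank "exists" when at least one gene lies on that side of the
    candidate; an existing flank passes when a viral-hallmark or
    viral-like gene sits within ``window`` gene positions.  Candidates at
    a contig end are judged on the existing side only; a candidate with
    no neighbors at all has no viral context and fails.
    """
    pos = cand.position_on_contig
    left = [g for g in cand.neighborhood if g[0] < pos]
    right = [g for g in cand.neighborhood if g[0] > pos]
    if not left and not right:
        return False

    def side_ok(genes: Sequence[tuple[int, str]]) -> bool:
        return any(
            cat in VIRAL_CATEGORIES and abs(idx - pos) <= window
            for idx, cat in genes
        )

    if left and not side_ok(left):
        return False
    if right and not side_ok(right):
        return False
    return True


# ---------------------------------------------------------------------------
# protein alignment (shared by novelty and host redundancy)
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


_PROTEIN_ALIGNER = _aligner()


def align_proteins(query: str, subject: str) -> tuple[float, float, float, float]:
    """Best local alignment of two protein sequences.

    Returns ``(identity, query_coverage, subject_coverage, score)`` with
    identity and coverages as fractions in [0, 1].  Identity is matches
    over alignment columns (gap columns included); coverage is the
    aligned span of each sequence over its length.
    """
    if not query or not subject:
        raise ValueError("empty protein sequence")
    alignments = _PROTEIN_ALIGNER.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0.0, 0.0
    aln = alignments[0]
    blocks_q, blocks_s = aln.aligned
    if len(blocks_q) == 0:
        return 0.0, 0.0, 0.0, float(aln.score)
    matches = 0
    paired = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        paired += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
    span_q = blocks_q[-1][1] - blocks_q[0][0]
    span_s = blocks_s[-1][1] - blocks_s[0][0]
    columns = paired + (span_q - paired) + (span_s - paired)
    identity = matches / columns if columns else 0.0
    return (
        identity,
        span_q / len(query),
        span_s / len(subject),
        float(aln.score),
    )


# ---------------------------------------------------------------------------
# novelty against a reference AMG protein set
# ---------------------------------------------------------------------------

def novelty(
    cands: Iterable[AMGCandidate],
    reference_proteins: Mapping[str, str],
    min_id: float = NOVELTY_MIN_ID,
    min_cov: float = NOVELTY_MIN_COV,
) -> pd.DataFrame:
    """Classify each candidate as ``known`` or ``novel``.

    A candidate is known when it aligns to at least one reference AMG
    protein at >= ``min_id`` identity with >= ``min_cov`` coverage of
    *both* sequences (bidirectional coverage); otherwise it is novel.
    The matching reference (cluster seed) is reported when found.
    """
    rows = []
    for cand in cands:
        status = "novel"
        best_ref = ""
        best_id = 0.0
        for ref_id, ref_seq in reference_proteins.items():
            ident, cov_q, cov_s, _ = align_proteins(cand.protein_seq, ref_seq)
            if ident >= min_id and cov_q >= min_cov and cov_s >= min_cov:
                status = "known"
                if ident > best_id:
                    best_id = ident
                    best_ref = ref_id
        rows.append(
            {
                "gene_id": cand.gene_id,
                "status": status,
                "reference": best_ref,
                "identity": best_id if status == "known" else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# host redundancy and contamination
# ---------------------------------------------------------------------------

def host_redundancy(
    amg_protein: str,
    host_proteome: Mapping[str, str],
    min_qcov: float = HOST_MIN_QCOV,
    homolog_min_id: float = HOST_HOMOLOG_MIN_ID,
) -> str:
    """Relatedness of an AMG to its host's proteome.

    ``identical`` — some host protein matches at 100% identity over
    >= 60% of the viral query; ``homologous`` — > 40% identity over
    >= 60% of the query; ``absent`` otherwise.
    """
    best = "absent"
    for seq in host_proteome.values():
        ident, cov_q, _, _ = align_proteins(amg_protein, seq)
        if cov_q * 100.0 < min_qcov:
            continue
        if ident >= 1.0:
            return "identical"
        if ident * 100.0 > homolog_min_id:
            best = "homologous"
    return best


def _min_exact_hit_length(m: int, n: int, evalue: float) -> int:
    """Shortest exact nucleotide match significant at the e-value cutoff.

    Karlin-Altschul with megablast-like parameters (match +1, K = 0.46,
    lambda = 1.28): E = K m n exp(-lambda L).
    """
    K, lam = 0.46, 1.28
    return max(1, math.ceil(math.log(K * m * n / evalue) / lam))


def contamination_check(
    votu_seq: str,
    host_genome_seqs: Iterable[str],
    evalue: float = 1e-3,
) -> bool:
    """True when the host genome carries an exact copy of part of the vOTU.

    Mirrors a 100%-identity, full-HSP-coverage nucleotide search: any
    exact shared substring long enough to be significant at ``evalue``
    flags the vOTU-host pair as integrated/contaminated, and such pairs
    are excluded from host-redundancy interpretation.
    """
    votu_seq = votu_seq.upper()
    for host in host_genome_seqs:
        host = host.upper()
        k = _min_exact_hit_length(len(votu_seq), len(host), evalue)
        if k > min(len(votu_seq), len(host)):
            continue
        host_kmers = {host[i : i + k] for i in range(len(host) - k + 1)}
        if any(
            votu_seq[i : i + k] in host_kmers
            for i in range(len(votu_seq) - k + 1)
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# combined curation table
# ---------------------------------------------------------------------------

def curate(
    cands: Sequence[AMGCandidate],
    reference_proteins: Mapping[str, str] | None = None,
    host_proteomes: Mapping[str, Mapping[str, str]] | None = None,
    host_genomes: Mapping[str, str] | None = None,
    votu_hosts: Mapping[str, str] | None = None,
    votu_seqs: Mapping[str, str] | None = None,
    flank_window: int = 3,
) -> pd.DataFrame:
    """Run every curation check and return one row per candidate.

    Host-level columns are filled only for candidates whose vOTU has a
    host link (``votu_hosts``); a contaminated vOTU-host pair masks the
    redundancy verdict (reported as ``excluded``).
    """
    nov = None
    if reference_proteins is not None:
        nov = novelty(cands, reference_proteins).set_index("gene_id")

    rows = []
    contaminated_cache: dict[tuple[str, str], bool] = {}
    for cand in cands:
        row = {
            "gene_id": cand.gene_id,
            "votu_id": cand.votu_id,
            "ko_id": cand.ko_id,
            "retained": passes_filter(cand),
            "flank_ok": check_flanks(cand, window=flank_window),
            "novelty": nov.loc[cand.gene_id, "status"] if nov is not None else "",
            "host_redundancy": "",
            "contaminated": "",
        }
        host = (votu_hosts or {}).get(cand.votu_id)
        if host is not None and host_genomes and votu_seqs:
            key = (cand.votu_id, host)
            if key not in contaminated_cache:
                contaminated_cache[key] = contamination_check(
                    votu_seqs[cand.votu_id], [host_genomes[host]]
                )
            contam = contaminated_cache[key]
            row["contaminated"] = str(contam)
            if host_proteomes and host in host_proteomes:
                if contam:
                    row["host_redundancy"] = "excluded"
                else:
                    row["host_redundancy"] = host_redundancy(
                        cand.protein_seq, host_proteomes[host]
                    )
        rows.append(row)
    return pd.DataFrame(rows)
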