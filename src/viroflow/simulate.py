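"""Seeded generators for every input the pipeline consumes.

The scenario emulates a six-sample proglacial-lake sediment virome
study: clusters of viral contigs (>= 10 kb) with known vOTU structure,
per-tool prediction tables whose evidence scores straddle each
acceptance threshold at configured rates, lifestyle evidence with a
planted lytic/lysogenic/undetermined mixture, a DRAM-v-style AMG table
with planted known/novel/host-derived genes, metagenome and
metatranscriptome count tables with a planted active fraction, and an
environment table with planted monotone virus-host-variable
associations.  Every planted fact is recorded in ``Scenario.truth`` so
each downstream stage can be scored automatically.

Environment associations are injected by rank-preserving assignment of
counts (a planted feature's counts across samples are sorted against the
variable's ranks), so the planted Spearman correlation is exact by
construction.  Contig mutation is substitution-only by default, which
keeps the ANI ground truth simple (an indel rate is configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .lineage import RankedLineage
from .records import ENV_VARIABLES
from .tables import write_table

BASES = np.array(list("ACGT"))
AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SAMPLE_IDS = (
    "Jan_inlet",
    "Jan_mid",
    "Jan_outlet",
    "May_inlet",
    "May_mid",
    "May_outlet",
)

#: CheckV tier mixture observed in sediment vOTU sets (low-quality heavy).
QUALITY_MIXTURE = {
    "Low": 0.838,
    "Medium": 0.095,
    "Complete": 0.036,
    "High": 0.029,
    "Not-determined": 0.002,
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Knobs of one synthetic study; defaults mirror the emulated design
    (six samples, 95/85 clusterable contigs, 82/11/7 lifestyle mixture,
    15% transcriptionally active features)."""

    seed: int = 0
    # community structure
    n_votus: int = 220
    extra_member_rate: float = 0.36     # Poisson rate of extra contigs per cluster
    within_divergence: float = 0.02     # substitutions/site inside a cluster
    indel_rate: float = 0.0
    min_length: int = 10_000
    max_length: int = 60_000
    n_samples: int = 6
    # screening evidence
    tool_report_rate: float = 0.9       # chance a predictor reports a contig
    screen_pass_rate: float = 0.8       # chance reported evidence passes the cutoff
    guarantee_detection: bool = True    # force >= 1 passing tool per contig
    # taxonomy
    classified_fraction: float = 0.95
    subfamily_rate: float = 0.5
    tax_report_rate: float = 0.9
    tax_accept_rate: float = 0.8
    tax_error_rate: float = 0.05        # sibling-family error, shared order
    tax_disjoint_rate: float = 0.01     # cross-realm error
    # lifestyle
    lifestyle_mixture: tuple[float, float, float] = (0.822, 0.106, 0.072)
    checkv_detect: float = 0.8
    marker_detect: float = 0.5
    vibrant_detect: float = 1.0
    bacphlip_detect: float = 1.0
    # AMGs
    n_amg_known: int = 20
    n_amg_novel: int = 10
    n_amg_reject: int = 20              # rows failing the confidence filter
    n_amg_host_identical: int = 4
    n_reference_proteins: int = 30
    protein_length: tuple[int, int] = (150, 300)
    known_divergence: float = 0.5       # planted identity ~ 1 - divergence
    flank_fail_rate: float = 0.2
    flank_window: int = 3
    # hosts
    n_hosts: int = 12
    host_genome_length: int = 100_000
    host_proteome_size: int = 20
    contaminated_fraction: float = 0.15
    link_rate: float = 0.3              # fraction of vOTUs with a host link
    # abundance / activity
    nb_dispersion: float = 0.3
    covfrac_fail_rate: float = 0.05
    active_fraction: float = 0.15
    # environment associations
    planted_pairs: int = 3
    planted_variables: tuple[str, ...] = ("NH4_N",)
    planted_sign: int = -1

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.lifestyle_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("lifestyle mixture must sum to 1")
        for p in (
            self.tool_report_rate,
            self.screen_pass_rate,
            self.classified_fraction,
            self.tax_error_rate,
            self.active_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        if self.n_samples == len(SAMPLE_IDS):
            return SAMPLE_IDS
        return tuple(f"S{i+1}" for i in range(self.n_samples))


@dataclass
class Scenario:
    """All generated inputs plus the ground truth that produced them."""

    cfg: ScenarioConfig
    sequences: dict[str, str]
    lengths: dict[str, int]
    predictor_tables: dict[str, pd.DataFrame]
    checkv_quality: pd.DataFrame
    taxonomy_tables: dict[str, pd.DataFrame]
    vibrant_lifestyle: pd.DataFrame
    bacphlip_scores: pd.DataFrame
    gene_annotations: pd.DataFrame
    amg_table: pd.DataFrame
    amg_neighborhoods: pd.DataFrame
    amg_proteins: dict[str, str]
    reference_proteins: dict[str, str]
    host_genomes: dict[str, str]
    host_proteomes: dict[str, dict[str, str]]
    links: pd.DataFrame
    counts_virus: pd.DataFrame
    counts_virus_tx: pd.DataFrame
    counts_host: pd.DataFrame
    counts_amg_tx: pd.DataFrame
    environment: pd.DataFrame
    truth: dict[str, object]

    def write(self, outdir: str | Path) -> None:
        """Emit the scenario as FASTA + dialect TSVs + a truth/ directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "contigs.fasta", self.sequences)
        _write_fasta(out / "amg_proteins.faa", self.amg_proteins)
        _write_fasta(out / "reference_amgs.faa", self.reference_proteins)
        _write_fasta(out / "host_genomes.fasta", self.host_genomes)
        for tool, df in self.predictor_tables.items():
            write_table(df, out / f"{tool}_hits.tsv", f"{tool}_hits")
        write_table(self.checkv_quality, out / "checkv_quality.tsv", "checkv_quality")
        for tool, df in self.taxonomy_tables.items():
            write_table(df, out / f"{tool}_tax.tsv", f"{tool}_tax")
        write_table(self.vibrant_lifestyle, out / "vibrant_lifestyle.tsv", "vibrant_lifestyle")
        write_table(self.bacphlip_scores, out / "bacphlip.tsv", "bacphlip_scores")
        write_table(self.gene_annotations, out / "annotations.tsv", "gene_annotations")
        write_table(self.amg_table, out / "dramv_amgs.tsv", "dramv_amgs")
        write_table(
            self.amg_neighborhoods, out / "amg_neighborhoods.tsv", "gene_neighborhood"
        )
        write_table(self.links, out / "links.tsv", "virus_host_links")
        write_table(self.counts_virus, out / "counts_virus.tsv", "feature_counts")
        write_table(self.counts_virus_tx, out / "counts_virus_tx.tsv", "feature_counts")
        write_table(self.counts_host, out / "counts_host.tsv", "feature_counts")
        write_table(self.counts_amg_tx, out / "counts_amg_tx.tsv", "feature_counts")
        write_table(self.environment, out / "environment.tsv", "environment")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for name, obj in self.truth.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(truth_dir / f"{name}.tsv", sep="\t", index=False)


def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning an ordered id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int, alphabet=BASES) -> str:
    return "".join(rng.choice(alphabet, size=length))


def mutate_sequence(
    rng: np.random.Generator,
    seq: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
    alphabet=BASES,
) -> str:
    """Point-mutate a sequence; substitutions always change the base."""
    arr = np.array(list(seq))
    n = len(arr)
    hit = rng.random(n) < substitution_rate
    idx = np.nonzero(hit)[0]
    k = len(alphabet)
    for i in idx:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    out = "".join(arr)
    if indel_rate > 0:
        pieces = []
        i = 0
        for i, ch in enumerate(out):
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    continue  # deletion
                pieces.append(ch + alphabet[rng.integers(k)])
            else:
                pieces.append(ch)
        out = "".join(pieces)
    return out


# ---------------------------------------------------------------------------
# community (contigs + cluster truth)
# ---------------------------------------------------------------------------

def gen_community(cfg: ScenarioConfig, rng: np.random.Generator):
    """Clusters of >= 10 kb contigs mutated from cluster seeds.

    Returns (sequences, lengths, clusters truth frame).  Cluster members
    carry ``within_divergence`` substitutions relative to the seed, so at
    the default 2% they stay well inside the 95/85 clustering gate while
    distinct seeds stay far outside it.
    """
    sequences: dict[str, str] = {}
    rows = []
    contig_no = 0
    for c in range(cfg.n_votus):
        size = 1 + rng.poisson(cfg.extra_member_rate)
        # log-uniform lengths: most vOTUs sit in the 10-60 kb band
        length = int(
            math.exp(
                rng.uniform(math.log(cfg.min_length), math.log(cfg.max_length))
            )
        )
        seed_seq = random_sequence(rng, length)
        member_ids = []
        for m in range(size):
            contig_no += 1
            cid = f"contig_{contig_no:05d}"
            if m == 0:
                seq = seed_seq
            else:
                seq = mutate_sequence(
                    rng, seed_seq, cfg.within_divergence, cfg.indel_rate
                )
                # members are trimmed a little so the seed stays longest
                trim = int(rng.integers(10, max(11, length // 100)))
                seq = seq[: max(cfg.min_length, len(seq) - trim)]
            sequences[cid] = seq
            member_ids.append(cid)
        rep = max(member_ids, key=lambda c_: (len(sequences[c_]), c_))
        rep = min(
            [m for m in member_ids if len(sequences[m]) == len(sequences[rep])]
        )
        for cid in member_ids:
            rows.append(
                {
                    "contig_id": cid,
                    "cluster_id": f"cluster_{c+1:04d}",
                    "representative": rep,
                }
            )
    lengths = {cid: len(s) for cid, s in sequences.items()}
    clusters = pd.DataFrame(
        rows, columns=["contig_id", "cluster_id", "representative"]
    )
    return sequences, lengths, clusters


# ---------------------------------------------------------------------------
# predictor hit tables
# ---------------------------------------------------------------------------

def gen_predictor_tables(cfg: ScenarioConfig, rng: np.random.Generator, lengths):
    """Per-tool hit tables with threshold-straddling scores.

    Each tool reports each contig with probability ``tool_report_rate``;
    a reported score passes that tool's cutoff with probability
    ``screen_pass_rate``.  With ``guarantee_detection`` a contig missed
    by all four tools gets a passing geNomad score so the community
    survives screening intact.
    """
    tabs = {t: [] for t in ("genomad", "virsorter2", "deepvirfinder", "vibrant")}
    screen_truth = []
    for cid, length in lengths.items():
        any_pass = False
        if rng.random() < cfg.tool_report_rate:
            ok = rng.random() < cfg.screen_pass_rate
            score = rng.uniform(0.8, 1.0) if ok else rng.uniform(0.0, 0.8 - 1e-9)
            tabs["genomad"].append(
                {"contig_id": cid, "length_bp": length, "score": round(score, 4)}
            )
            any_pass |= ok
        if rng.random() < cfg.tool_report_rate:
            ok = rng.random() < cfg.screen_pass_rate
            score = rng.uniform(0.9 + 1e-6, 1.0) if ok else rng.uniform(0.0, 0.9)
            tabs["virsorter2"].append(
                {"contig_id": cid, "length_bp": length, "score": round(score, 6)}
            )
            any_pass |= ok
        if rng.random() < cfg.tool_report_rate:
            ok = rng.random() < cfg.screen_pass_rate
            if ok:
                score, p = rng.uniform(0.9, 1.0), rng.uniform(0.0, 0.0499)
            elif rng.random() < 0.5:
                score, p = rng.uniform(0.0, 0.9 - 1e-9), rng.uniform(0.0, 0.0499)
            else:
                score, p = rng.uniform(0.9, 1.0), rng.uniform(0.05, 1.0)
            tabs["deepvirfinder"].append(
                {
                    "contig_id": cid,
                    "length_bp": length,
                    "score": round(score, 4),
                    "p_value": round(p, 5),
                }
            )
            any_pass |= ok
        if rng.random() < cfg.tool_report_rate * cfg.screen_pass_rate:
            tabs["vibrant"].append({"contig_id": cid, "length_bp": length})
            any_pass = True
        if cfg.guarantee_detection and not any_pass:
            tabs["genomad"].append(
                {
                    "contig_id": cid,
                    "length_bp": length,
                    "score": round(rng.uniform(0.85, 1.0), 4),
                }
            )
            any_pass = True
        screen_truth.append(
            {"contig_id": cid, "passes": any_pass and length >= cfg.min_length}
        )
    tables = {
        tool: pd.DataFrame(
            rows,
            columns=["contig_id", "length_bp", "score", "p_value"][
                : (4 if tool == "deepvirfinder" else (2 if tool == "vibrant" else 3))
            ],
        )
        for tool, rows in tabs.items()
    }
    return tables, pd.DataFrame(screen_truth)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_RANK_SUFFIX = {
    "realm": "viria",
    "kingdom": "virae",
    "phylum": "viricota",
    "class_": "viricetes",
    "order": "virales",
    "family": "viridae",
    "subfamily": "virinae",
    "genus": "virus",
}


def build_taxonomy(
    n_realms: int = 2,
    phyla_per_kingdom: int = 2,
    orders_per_class: int = 2,
    families_per_order: int = 3,
    genera_per_family: int = 2,
) -> list[RankedLineage]:
    """A small ICTV-shaped reference tree, returned as genus-level lineages."""
    lineages = []
    g = 0
    for r in range(n_realms):
        realm = f"Syn{r+1}{_RANK_SUFFIX['realm']}"
        kingdom = f"Syn{r+1}{_RANK_SUFFIX['kingdom']}"
        for p in range(phyla_per_kingdom):
            phylum = f"Syn{r+1}{p+1}{_RANK_SUFFIX['phylum']}"
            class_ = f"Syn{r+1}{p+1}{_RANK_SUFFIX['class_']}"
            for o in range(orders_per_class):
                order = f"Syn{r+1}{p+1}{o+1}{_RANK_SUFFIX['order']}"
                for f_ in range(families_per_order):
                    family = f"Syn{r+1}{p+1}{o+1}{f_+1}{_RANK_SUFFIX['family']}"
                    subfamily = f"Syn{r+1}{p+1}{o+1}{f_+1}{_RANK_SUFFIX['subfamily']}"
                    for ge in range(genera_per_family):
                        g += 1
                        lineages.append(
                            RankedLineage(
                                realm=realm,
                                kingdom=kingdom,
                                phylum=phylum,
                                class_=class_,
                                order=order,
                                family=family,
                                subfamily=subfamily,
                                genus=f"Syn{g}{_RANK_SUFFIX['genus']}",
                            )
                        )
    return lineages


_TAX_TOOLS = ("vcontact2", "blastn", "genomad", "phagcn2", "vpfclass")
_TOOL_DEPTH = {
    "vcontact2": "family",
    "blastn": "genus",
    "genomad": "genus",
    "phagcn2": "family",
    "vpfclass": "family",
}


def _strip_subfamily(lin: RankedLineage, keep: bool) -> RankedLineage:
    if keep:
        return lin
    d = {r: lin.name_at(r) for r in ("realm", "kingdom", "phylum", "class", "order", "family", "genus")}
    return RankedLineage(
        realm=d["realm"], kingdom=d["kingdom"], phylum=d["phylum"],
        class_=d["class"], order=d["order"], family=d["family"], genus=d["genus"],
    )


def _sibling_family(lin: RankedLineage, pool: list[RankedLineage], rng) -> RankedLineage:
    """A lineage from a different family under the same order (if any)."""
    sibs = [
        l for l in pool
        if l.order == lin.order and l.family != lin.family
    ]
    return sibs[rng.integers(len(sibs))] if sibs else lin


def _other_realm(lin: RankedLineage, pool: list[RankedLineage], rng) -> RankedLineage:
    others = [l for l in pool if l.realm != lin.realm]
    return others[rng.integers(len(others))] if others else lin


def gen_taxonomy_tables(
    cfg: ScenarioConfig, rng: np.random.Generator, votu_ids: list[str]
):
    """Five taxonomy dialect tables plus per-vOTU/per-tool truth.

    A classified vOTU gets a genus-level true lineage; each tool reports
    the truth (truncated to the tool's depth) with probability
    ``1 - tax_error_rate - tax_disjoint_rate``, a sibling-family error
    otherwise, and evidence scores drawn to pass its acceptance rule
    with probability ``tax_accept_rate``.
    """
    pool = build_taxonomy()
    truth_rows = []
    lineage_truth: dict[str, RankedLineage] = {}
    tabs: dict[str, list] = {t: [] for t in _TAX_TOOLS}

    for votu in votu_ids:
        if rng.random() >= cfg.classified_fraction:
            lineage_truth[votu] = RankedLineage()
            continue
        true_lin = pool[rng.integers(len(pool))]
        true_lin = _strip_subfamily(true_lin, rng.random() < cfg.subfamily_rate)
        lineage_truth[votu] = true_lin

        for tool in _TAX_TOOLS:
            if rng.random() >= cfg.tax_report_rate:
                continue
            u = rng.random()
            if u < cfg.tax_disjoint_rate:
                reported, err = _other_realm(true_lin, pool, rng), "disjoint"
            elif u < cfg.tax_disjoint_rate + cfg.tax_error_rate:
                reported, err = _sibling_family(true_lin, pool, rng), "family"
            else:
                reported, err = true_lin, "none"
            reported = _strip_subfamily(reported, true_lin.subfamily is not None)
            reported = reported.truncated(_TOOL_DEPTH[tool])
            accepted = rng.random() < cfg.tax_accept_rate
            row = {"votu_id": votu, "lineage": reported.to_string()}
            if tool == "vcontact2":
                total = int(rng.integers(6, 30))
                if accepted:
                    assigned = int(rng.integers(total // 2 + 1, total + 1))
                    bit = round(rng.uniform(50, 300), 1)
                else:
                    if rng.random() < 0.5:
                        assigned = int(rng.integers(0, total // 2 + 1))
                        bit = round(rng.uniform(50, 300), 1)
                    else:
                        assigned = int(rng.integers(total // 2 + 1, total + 1))
                        bit = round(rng.uniform(5, 49.9), 1)
                row.update(
                    protein_total=total,
                    protein_assigned_to_family=assigned,
                    min_bitscore=bit,
                )
            elif tool == "blastn":
                if accepted:
                    ident = round(rng.uniform(90, 100), 2)
                    cov = round(rng.uniform(75, 100), 2)
                elif rng.random() < 0.5:
                    ident = round(rng.uniform(60, 89.9), 2)
                    cov = round(rng.uniform(75, 100), 2)
                else:
                    ident = round(rng.uniform(90, 100), 2)
                    cov = round(rng.uniform(20, 74.9), 2)
                row.update(
                    pct_identity=ident,
                    pct_coverage=cov,
                    hit_rank=1,
                    bitscore=round(rng.uniform(100, 2000), 1),
                    evalue=float(f"{rng.uniform(1e-30, 1e-5):.2e}"),
                )
            elif tool == "genomad":
                if not accepted:
                    continue  # geNomad "rejection" = no taxonomy reported
            elif tool == "phagcn2":
                row["score"] = round(
                    rng.uniform(0.5 + 1e-6, 1.0) if accepted else rng.uniform(0.0, 0.5),
                    4,
                )
            elif tool == "vpfclass":
                if accepted:
                    mr, conf = rng.uniform(0.5, 1.0), rng.uniform(0.75, 1.0)
                elif rng.random() < 0.5:
                    mr, conf = rng.uniform(0.0, 0.499), rng.uniform(0.75, 1.0)
                else:
                    mr, conf = rng.uniform(0.5, 1.0), rng.uniform(0.0, 0.749)
                row.update(membership_ratio=round(mr, 4), confidence=round(conf, 4))
            tabs[tool].append(row)
            truth_rows.append(
                {"votu_id": votu, "tool": tool, "accepted": accepted, "error": err}
            )

    columns = {
        "vcontact2": ["votu_id", "lineage", "protein_total", "protein_assigned_to_family", "min_bitscore"],
        "blastn": ["votu_id", "lineage", "pct_identity", "pct_coverage", "hit_rank", "bitscore", "evalue"],
        "genomad": ["votu_id", "lineage"],
        "phagcn2": ["votu_id", "lineage", "score"],
        "vpfclass": ["votu_id", "lineage", "membership_ratio", "confidence"],
    }
    tables = {
        tool: pd.DataFrame(rows, columns=columns[tool]) for tool, rows in tabs.items()
    }
    tool_truth = pd.DataFrame(
        truth_rows, columns=["votu_id", "tool", "accepted", "error"]
    )
    return tables, lineage_truth, tool_truth


# ---------------------------------------------------------------------------
# lifestyle evidence
# ---------------------------------------------------------------------------

_MARKER_TEXTS = (
    "site-specific integrase",
    "DNA invertase",
    "serine recombinase family protein",
    "IS3 family transposase",
    "CI repressor protein",
    "Cro repressor",
    "chromosome partitioning protein ParA",
    "partition protein ParB",
)
_NEUTRAL_TEXTS = (
    "terminase large subunit",
    "major capsid protein",
    "tail fiber protein",
    "DNA polymerase",
    "hypothetical protein",
    "portal protein",
)


def gen_lifestyle_evidence(
    cfg: ScenarioConfig, rng: np.random.Generator, votu_ids: list[str]
):
    """Planted lifestyles and the four evidence streams that reflect them."""
    labels = ("lytic", "lysogenic", "undetermined")
    mix = np.asarray(cfg.lifestyle_mixture)
    assigned = rng.choice(len(labels), size=len(votu_ids), p=mix)
    lifestyle_truth = {v: labels[i] for v, i in zip(votu_ids, assigned)}

    provirus: dict[str, bool] = {}
    vib_rows, bac_rows, ann_rows = [], [], []
    gene_no = 0
    for votu in votu_ids:
        truth = lifestyle_truth[votu]
        provirus[votu] = bool(
            truth == "lysogenic" and rng.random() < cfg.checkv_detect
        )
        # every vOTU carries a few neutral annotations
        for _ in range(int(rng.integers(1, 4))):
            gene_no += 1
            ann_rows.append(
                {
                    "votu_id": votu,
                    "gene_id": f"gene_{gene_no:05d}",
                    "description": _NEUTRAL_TEXTS[rng.integers(len(_NEUTRAL_TEXTS))],
                }
            )
        if truth == "lysogenic" and rng.random() < cfg.marker_detect:
            gene_no += 1
            ann_rows.append(
                {
                    "votu_id": votu,
                    "gene_id": f"gene_{gene_no:05d}",
                    "description": _MARKER_TEXTS[rng.integers(len(_MARKER_TEXTS))],
                }
            )
        if truth in ("lytic", "lysogenic") and rng.random() < cfg.vibrant_detect:
            vib_rows.append({"votu_id": votu, "call": truth})
        if truth == "lytic":
            if rng.random() < cfg.bacphlip_detect:
                score = rng.uniform(0.0, 0.1 - 1e-9)
            else:
                score = rng.uniform(0.2, 0.8)
        elif truth == "lysogenic":
            if rng.random() < cfg.bacphlip_detect:
                score = rng.uniform(0.9, 1.0)
            else:
                score = rng.uniform(0.2, 0.8)
        else:
            score = rng.uniform(0.2, 0.8)
        bac_rows.append({"votu_id": votu, "temperate_score": round(score, 4)})

    vibrant = pd.DataFrame(vib_rows, columns=["votu_id", "call"])
    bacphlip = pd.DataFrame(bac_rows, columns=["votu_id", "temperate_score"])
    annotations = pd.DataFrame(ann_rows, columns=["votu_id", "gene_id", "description"])
    return lifestyle_truth, provirus, vibrant, bacphlip, annotations


# ---------------------------------------------------------------------------
# AMGs, hosts, links
# ---------------------------------------------------------------------------

_KO_POOL = (
    "K00958", "K01011", "K00390", "K02439", "K00860", "K01738",
    "K00799", "K01424", "K00266", "K02078",
)


def gen_amg_inputs(
    cfg: ScenarioConfig, rng: np.random.Generator, votu_ids: list[str]
):
    """DRAM-v-style AMG rows plus proteins, references, hosts and links."""
    # reference AMG protein set
    reference = {
        f"refAMG_{i+1:03d}": random_sequence(
            rng, int(rng.integers(*cfg.protein_length)), AMINO_ACIDS
        )
        for i in range(cfg.n_reference_proteins)
    }

    # hosts: genomes + proteomes
    host_ids = [f"MAG_{i+1:03d}" for i in range(cfg.n_hosts)]
    host_genomes = {
        h: random_sequence(rng, cfg.host_genome_length) for h in host_ids
    }
    host_proteomes = {
        h: {
            f"{h}_p{j+1:03d}": random_sequence(
                rng, int(rng.integers(*cfg.protein_length)), AMINO_ACIDS
            )
            for j in range(cfg.host_proteome_size)
        }
        for h in host_ids
    }

    # links: a fraction of vOTUs get a host
    linked = [v for v in votu_ids if rng.random() < cfg.link_rate] if votu_ids else []
    link_rows = [
        {
            "votu_id": v,
            "host_genome_id": host_ids[int(rng.integers(len(host_ids)))],
            "host_lineage": "",
            "confidence": round(rng.uniform(90, 100), 1),
        }
        for v in linked
    ]
    links = pd.DataFrame(
        link_rows, columns=["votu_id", "host_genome_id", "host_lineage", "confidence"]
    )
    votu_hosts = dict(zip(links["votu_id"], links["host_genome_id"]))

    def retained_flags() -> str:
        return ["M", "ME", "MK", "MEK"][int(rng.integers(4))]

    def rejected_row() -> tuple[int, str]:
        if rng.random() < 0.5:
            return int(rng.integers(4, 6)), retained_flags()  # score too high
        bad = ["MV", "V", "MA", "T", "MEKB"][int(rng.integers(5))]
        return int(rng.integers(1, 4)), bad  # flag outside {M,E,K}

    rows, truth_rows = [], []
    proteins: dict[str, str] = {}
    gene_no = 0
    n_true = cfg.n_amg_known + cfg.n_amg_novel + cfg.n_amg_host_identical
    ref_ids = list(reference)
    total_rows = (n_true + cfg.n_amg_reject) if votu_ids else 0
    for i in range(total_rows):
        gene_no += 1
        gid = f"AMG_{gene_no:04d}"
        votu = votu_ids[int(rng.integers(len(votu_ids)))]
        if i < cfg.n_amg_known:
            src = reference[ref_ids[int(rng.integers(len(ref_ids)))]]
            seq = mutate_sequence(rng, src, cfg.known_divergence, alphabet=AMINO_ACIDS)
            kind = "known"
        elif i < cfg.n_amg_known + cfg.n_amg_novel:
            seq = random_sequence(
                rng, int(rng.integers(*cfg.protein_length)), AMINO_ACIDS
            )
            kind = "novel"
        elif i < n_true:
            # exact copy of a host protein (host-identical AMG)
            host = votu_hosts.get(votu)
            if host is None:
                host = host_ids[int(rng.integers(len(host_ids)))]
                votu_hosts[votu] = host
                links = pd.concat(
                    [
                        links,
                        pd.DataFrame(
                            [
                                {
                                    "votu_id": votu,
                                    "host_genome_id": host,
                                    "host_lineage": "",
                                    "confidence": 95.0,
                                }
                            ]
                        ),
                    ],
                    ignore_index=True,
                )
            pkeys = list(host_proteomes[host])
            seq = host_proteomes[host][pkeys[int(rng.integers(len(pkeys)))]]
            kind = "host_identical"
        else:
            seq = random_sequence(
                rng, int(rng.integers(*cfg.protein_length)), AMINO_ACIDS
            )
            kind = "reject"
        proteins[gid] = seq

        if kind == "reject":
            score, flags = rejected_row()
        else:
            score, flags = int(rng.integers(1, 4)), retained_flags()
        position = int(rng.integers(6, 20))
        flank_ok = not (rng.random() < cfg.flank_fail_rate)
        rows.append(
            {
                "gene_id": gid,
                "votu_id": votu,
                "ko_id": _KO_POOL[int(rng.integers(len(_KO_POOL)))],
                "auxiliary_score": score,
                "amg_flags": flags,
                "gene_index": position,
                "annotation": "putative auxiliary metabolic protein",
            }
        )
        truth_rows.append(
            {
                "gene_id": gid,
                "votu_id": votu,
                "kind": kind,
                "retained": kind != "reject",
                "flank_ok": flank_ok,
                "position": position,
            }
        )

    amg_table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "votu_id", "ko_id", "auxiliary_score",
            "amg_flags", "gene_index", "annotation",
        ],
    )
    amg_truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "votu_id", "kind", "retained", "flank_ok", "position"],
    )
    return amg_table, amg_truth, proteins, reference, host_genomes, host_proteomes, links


def gen_neighborhoods(
    cfg: ScenarioConfig, rng: np.random.Generator, amg_truth: pd.DataFrame
) -> dict[str, tuple[tuple[int, str], ...]]:
    """Gene-category neighborhoods realizing each AMG's planted flank truth."""
    out: dict[str, tuple[tuple[int, str], ...]] = {}
    for row in amg_truth.itertuples(index=False):
        pos = row.position
        genes = []
        for offset in range(-cfg.flank_window - 2, cfg.flank_window + 3):
            if offset == 0 or pos + offset < 1:
                continue
            genes.append([pos + offset, "other"])
        if row.flank_ok:
            left = int(rng.integers(1, cfg.flank_window + 1))
            right = int(rng.integers(1, cfg.flank_window + 1))
            cats = ("viral-hallmark", "viral-like")
            for g in genes:
                if g[0] == pos - left:
                    g[1] = cats[int(rng.integers(2))]
                if g[0] == pos + right:
                    g[1] = cats[int(rng.integers(2))]
        out[row.gene_id] = tuple((int(i), c) for i, c in genes)
    return out


# ---------------------------------------------------------------------------
# contamination planting
# ---------------------------------------------------------------------------

def plant_contamination(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    sequences: dict[str, str],
    host_genomes: dict[str, str],
    links: pd.DataFrame,
) -> pd.DataFrame:
    """Embed exact vOTU fragments into a fraction of linked host genomes."""
    rows = []
    for r in links.itertuples(index=False):
        contaminated = rng.random() < cfg.contaminated_fraction
        if contaminated:
            seq = sequences[r.votu_id]
            frag_len = min(5000, len(seq))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            host = host_genomes[r.host_genome_id]
            ins = int(rng.integers(0, len(host)))
            host_genomes[r.host_genome_id] = host[:ins] + frag + host[ins:]
        rows.append(
            {
                "votu_id": r.votu_id,
                "host_genome_id": r.host_genome_id,
                "contaminated": contaminated,
            }
        )
    return pd.DataFrame(
        rows, columns=["votu_id", "host_genome_id", "contaminated"]
    )


# ---------------------------------------------------------------------------
# counts + environment
# ---------------------------------------------------------------------------

def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial counts with var = mu + dispersion * mu^2."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _env_table(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    samples = cfg.sample_ids
    n = len(samples)
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "pH": np.round(rng.normal(8.3, 0.4, n), 2),
            "EC": np.round(rng.lognormal(math.log(150), 0.4, n), 1),
            "TN": np.round(rng.uniform(0.5, 1.5, n), 3),
            "NH4_N": np.round(rng.uniform(2.0, 15.0, n), 2),
            "NO3_N": np.round(rng.uniform(1.0, 10.0, n), 2),
            "TP": np.round(rng.uniform(0.3, 0.8, n), 3),
            "TOC": np.round(rng.uniform(2.0, 10.0, n), 2),
            "WT": np.round(
                np.concatenate(
                    [rng.uniform(0.5, 3.0, n - n // 2), rng.uniform(4.0, 8.0, n // 2)]
                ),
                2,
            ),
        }
    )
    # re-draw any variable with tied values so planted rank links are exact
    for var in ENV_VARIABLES:
        while df[var].duplicated().any():
            df[var] = df[var] + np.round(rng.uniform(0, 0.01, n), 4)
    return df


def _counts_frame(
    cfg, rng, feature_ids, lengths, samples, base_mean=200.0
) -> pd.DataFrame:
    df = pd.DataFrame(
        {"feature_id": feature_ids, "length_bp": [lengths[f] for f in feature_ids]}
    )
    for s in samples:
        mu = rng.lognormal(math.log(base_mean), 1.5, len(feature_ids))
        counts = _nb_counts(rng, mu, cfg.nb_dispersion)
        covfrac = np.where(
            counts > 0,
            np.where(
                rng.random(len(counts)) < cfg.covfrac_fail_rate,
                rng.uniform(0.0, 0.05, len(counts)),
                rng.uniform(0.5, 1.0, len(counts)),
            ),
            0.0,
        )
        df[f"count_{s}"] = counts.astype(int)
        df[f"covfrac_{s}"] = np.round(covfrac, 3)
    return df


def _plant_monotone(
    df: pd.DataFrame,
    feature_id: str,
    env: pd.DataFrame,
    variable: str,
    sign: int,
    rng: np.random.Generator,
) -> None:
    """Overwrite one feature's counts with a rank-preserving pattern.

    Counts follow a geometric ladder assigned by the variable's sample
    ranks, so the feature's abundance (and its TPM, which the ladder's
    dynamic range protects against denominator wobble) is perfectly
    monotone in the variable.
    """
    samples = list(env["sample_id"])
    values = env.set_index("sample_id")[variable]
    order = values.rank().astype(int)  # 1..n, distinct by construction
    base = float(rng.uniform(8, 15))
    idx = df.index[df["feature_id"] == feature_id][0]
    for s in samples:
        r = order[s] if sign > 0 else (len(samples) + 1 - order[s])
        # factor-6 steps dominate any between-sample denominator wobble
        df.loc[idx, f"count_{s}"] = int(round(base * 6 ** (r - 1)))
        df.loc[idx, f"covfrac_{s}"] = round(float(rng.uniform(0.6, 1.0)), 3)


def gen_counts_env(
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    votu_ids: list[str],
    votu_lengths: dict[str, int],
    host_ids: list[str],
    host_lengths: dict[str, int],
    amg_votus: dict[str, str],
    links: pd.DataFrame,
):
    """Count tables (metagenome + metatranscriptome), environment table,
    planted activity truth and planted pair-variable associations."""
    samples = list(cfg.sample_ids)
    env = _env_table(cfg, rng)

    counts_virus = _counts_frame(cfg, rng, votu_ids, votu_lengths, samples)
    counts_host = _counts_frame(cfg, rng, host_ids, host_lengths, samples)

    # planted associations: pick linked pairs, force monotone patterns
    planted = []
    if cfg.planted_pairs and len(links):
        pool = links.sample(
            n=min(cfg.planted_pairs, len(links)),
            random_state=int(rng.integers(2**31)),
        )
        for i, r in enumerate(pool.itertuples(index=False)):
            var = cfg.planted_variables[i % len(cfg.planted_variables)]
            _plant_monotone(counts_virus, r.votu_id, env, var, cfg.planted_sign, rng)
            _plant_monotone(counts_host, r.host_genome_id, env, var, cfg.planted_sign, rng)
            planted.append(
                {
                    "votu_id": r.votu_id,
                    "host_genome_id": r.host_genome_id,
                    "variable": var,
                    "sign": cfg.planted_sign,
                }
            )
    associations = pd.DataFrame(
        planted, columns=["votu_id", "host_genome_id", "variable", "sign"]
    )

    # transcript counts: planted active fraction, zeros elsewhere (MAPQ>=30
    # filtering upstream is assumed; counts arrive pre-filtered)
    active_flags = rng.random(len(votu_ids)) < cfg.active_fraction
    active_truth = dict(zip(votu_ids, (bool(a) for a in active_flags)))
    tx = pd.DataFrame(
        {"feature_id": votu_ids, "length_bp": [votu_lengths[f] for f in votu_ids]}
    )
    for s in samples:
        counts = np.zeros(len(votu_ids), dtype=int)
        for j, v in enumerate(votu_ids):
            if active_truth[v] and rng.random() < 0.6:
                counts[j] = max(1, int(_nb_counts(rng, np.array([50.0]), cfg.nb_dispersion)[0]))
        tx[f"count_{s}"] = counts
        tx[f"covfrac_{s}"] = np.where(counts > 0, 0.8, 0.0)
    # guarantee every active feature has >= 1 positive sample
    for j, v in enumerate(votu_ids):
        if active_truth[v] and all(tx.loc[j, f"count_{s}"] == 0 for s in samples):
            s = samples[int(rng.integers(len(samples)))]
            tx.loc[j, f"count_{s}"] = int(rng.integers(1, 100))
            tx.loc[j, f"covfrac_{s}"] = 0.8

    # AMG transcript counts follow the parent vOTU's activity
    amg_ids = list(amg_votus)
    amg_tx = pd.DataFrame(
        {"feature_id": amg_ids, "length_bp": [900] * len(amg_ids)}
    )
    for s in samples:
        parent = [amg_votus[g] for g in amg_ids]
        parent_counts = tx.set_index("feature_id").loc[parent, f"count_{s}"].to_numpy()
        scale = rng.uniform(0.0, 0.3, len(amg_ids))
        counts = np.floor(parent_counts * scale).astype(int)
        amg_tx[f"count_{s}"] = counts
        amg_tx[f"covfrac_{s}"] = np.where(counts > 0, 0.8, 0.0)

    return counts_virus, counts_host, tx, amg_tx, env, active_truth, associations


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def simulate(cfg: ScenarioConfig) -> Scenario:
    """Generate a complete, internally consistent synthetic study."""
    rng = np.random.default_rng(cfg.seed)

    sequences, lengths, clusters = gen_community(cfg, rng)
    predictor_tables, screen_truth = gen_predictor_tables(cfg, rng, lengths)

    votu_ids = sorted(clusters["representative"].unique())
    votu_lengths = {v: lengths[v] for v in votu_ids}

    taxonomy_tables, lineage_truth, tool_truth = gen_taxonomy_tables(
        cfg, rng, votu_ids
    )
    (
        lifestyle_truth,
        provirus,
        vibrant_lifestyle,
        bacphlip_scores,
        gene_annotations,
    ) = gen_lifestyle_evidence(cfg, rng, votu_ids)

    (
        amg_table,
        amg_truth,
        amg_proteins,
        reference_proteins,
        host_genomes,
        host_proteomes,
        links,
    ) = gen_amg_inputs(cfg, rng, votu_ids)
    neighborhoods = gen_neighborhoods(cfg, rng, amg_truth)
    amg_neighborhoods = pd.DataFrame(
        [
            {"amg_gene_id": gid, "gene_index": idx, "category": cat}
            for gid, genes in neighborhoods.items()
            for idx, cat in genes
        ],
        columns=["amg_gene_id", "gene_index", "category"],
    )
    contamination = plant_contamination(cfg, rng, sequences, host_genomes, links)

    # CheckV quality table (per contig; provirus evidence on representatives)
    tiers = list(QUALITY_MIXTURE)
    tier_p = np.array(list(QUALITY_MIXTURE.values()))
    tier_p = tier_p / tier_p.sum()
    rep_of = dict(zip(clusters["contig_id"], clusters["representative"]))
    qual_rows = []
    rep_tier = {v: tiers[int(rng.choice(len(tiers), p=tier_p))] for v in votu_ids}
    for cid in sequences:
        rep = rep_of[cid]
        qual_rows.append(
            {
                "contig_id": cid,
                "length_bp": lengths[cid],
                "quality_tier": rep_tier[rep],
                "provirus": "Yes" if provirus[rep] else "No",
            }
        )
    checkv_quality = pd.DataFrame(
        qual_rows, columns=["contig_id", "length_bp", "quality_tier", "provirus"]
    )

    host_ids = sorted(host_genomes)
    host_lengths = {h: len(host_genomes[h]) for h in host_ids}
    amg_votus = dict(zip(amg_truth["gene_id"], amg_truth["votu_id"]))
    (
        counts_virus,
        counts_host,
        counts_virus_tx,
        counts_amg_tx,
        environment,
        active_truth,
        associations,
    ) = gen_counts_env(
        cfg, rng, votu_ids, votu_lengths, host_ids, host_lengths, amg_votus, links
    )

    truth: dict[str, object] = {
        "clusters": clusters,
        "screen": screen_truth,
        "tool_truth": tool_truth,
        "lineages": pd.DataFrame(
            {
                "votu_id": list(lineage_truth),
                "lineage": [l.to_string() for l in lineage_truth.values()],
            }
        ),
        "lifestyles": pd.DataFrame(
            {
                "votu_id": list(lifestyle_truth),
                "lifestyle": list(lifestyle_truth.values()),
            }
        ),
        "amg": amg_truth,
        "contamination": contamination,
        "active": pd.DataFrame(
            {"votu_id": list(active_truth), "active": list(active_truth.values())}
        ),
        "associations": associations,
        "_lineage_objects": lineage_truth,
        "_neighborhoods": neighborhoods,
        "_provirus": provirus,
    }

    return Scenario(
        cfg=cfg,
        sequences=sequences,
        lengths=lengths,
        predictor_tables=predictor_tables,
        checkv_quality=checkv_quality,
        taxonomy_tables=taxonomy_tables,
        vibrant_lifestyle=vibrant_lifestyle,
        bacphlip_scores=bacphlip_scores,
        gene_annotations=gene_annotations,
        amg_table=amg_table,
        amg_neighborhoods=amg_neighborhoods,
        amg_proteins=amg_proteins,
        reference_proteins=reference_proteins,
        host_genomes=host_genomes,
        host_proteomes=host_proteomes,
        links=links,
        counts_virus=counts_virus,
        counts_virus_tx=counts_virus_tx,
        counts_host=counts_host,
        counts_amg_tx=counts_amg_tx,
        environment=environment,
        truth=truth,
    )
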