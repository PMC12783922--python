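"""End-to-end orchestration of a synthetic scenario, with truth scoring.

``run_pipeline`` drives every stage in order — screening, dereplication,
consensus taxonomy, lifestyle consensus, AMG curation, TPM/activity and
the ecology screen — on a :class:`~viroflow.simulate.Scenario`, and
scores each stage against the scenario's recorded ground truth into a
machine-readable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import abundance as ab
from . import amg as amg_mod
from . import ecology, lifestyle, screen, taxonomy
from .derep import greedy_cluster
from .lineage import RankedLineage
from .records import VOTURecord
from .similarity import all_vs_all
from .simulate import Scenario


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Pair-counting agreement between two partitions (1 = identical)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists differ in length")
    n = len(labels_a)
    if n < 2:
        return 1.0
    ct: dict[tuple, int] = {}
    ra: dict = {}
    cb: dict = {}
    for a, b in zip(labels_a, labels_b):
        ct[(a, b)] = ct.get((a, b), 0) + 1
        ra[a] = ra.get(a, 0) + 1
        cb[b] = cb.get(b, 0) + 1
    sum_ct = sum(comb(v, 2) for v in ct.values())
    sum_a = sum(comb(v, 2) for v in ra.values())
    sum_b = sum(comb(v, 2) for v in cb.values())
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ct - expected) / (max_index - expected)


@dataclass
class PipelineResult:
    passed_contigs: set[str]
    votus: list[VOTURecord]
    consensus_lineages: dict[str, RankedLineage]
    classification: pd.DataFrame
    lifestyle_calls: dict[str, lifestyle.LifestyleCall]
    amg_curation: pd.DataFrame
    virus_tpm: pd.DataFrame
    virus_tx_tpm: pd.DataFrame
    host_tpm: pd.DataFrame
    amg_tx_tpm: pd.DataFrame
    active: pd.Series
    alpha: pd.DataFrame
    pair_table: pd.DataFrame
    report: dict = field(default_factory=dict)

    def write_report(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)


def _candidates_from_scenario(scn: Scenario) -> list[amg_mod.AMGCandidate]:
    nbh: dict[str, list[tuple[int, str]]] = {}
    for row in scn.amg_neighborhoods.itertuples(index=False):
        nbh.setdefault(row.amg_gene_id, []).append(
            (int(row.gene_index), row.category)
        )
    cands = []
    for row in scn.amg_table.itertuples(index=False):
        cands.append(
            amg_mod.AMGCandidate(
                gene_id=row.gene_id,
                votu_id=row.votu_id,
                ko_id=row.ko_id,
                auxiliary_score=int(row.auxiliary_score),
                amg_flags=amg_mod.parse_flags(row.amg_flags, row.gene_id),
                position_on_contig=int(row.gene_index),
                protein_seq=scn.amg_proteins[row.gene_id],
                neighborhood=tuple(sorted(nbh.get(row.gene_id, ()))),
            )
        )
    return cands


def run_pipeline(scn: Scenario, integrate_mode: str = "lca") -> PipelineResult:
    """Run every stage on a scenario and score it against the truth."""
    cfg = scn.cfg
    report: dict = {"config": {"seed": cfg.seed, "n_contigs": len(scn.sequences)}}

    # -- 1. screening ---------------------------------------------------
    hits = screen.hits_from_tables(
        genomad=scn.predictor_tables["genomad"],
        virsorter2=scn.predictor_tables["virsorter2"],
        deepvirfinder=scn.predictor_tables["deepvirfinder"],
        vibrant=scn.predictor_tables["vibrant"],
    )
    passed = screen.screen_contigs(hits, min_len=cfg.min_length)
    truth_screen = scn.truth["screen"]
    truth_pass = set(truth_screen.loc[truth_screen["passes"], "contig_id"])
    n = len(scn.sequences)
    report["screen"] = {
        "n_passed": len(passed),
        "n_truth": len(truth_pass),
        "accuracy": (n - len(passed ^ truth_pass)) / n if n else 1.0,
    }

    # -- 2. dereplication ----------------------------------------------
    seqs = {c: scn.sequences[c] for c in passed}
    sims = all_vs_all(seqs)
    lengths = {c: len(s) for c, s in seqs.items()}
    votus = greedy_cluster(sims, lengths)
    clusters = scn.truth["clusters"]
    truth_label = dict(zip(clusters["contig_id"], clusters["cluster_id"]))
    pred_label = {
        m: v.votu_id for v in votus for m in v.member_contigs
    }
    shared = sorted(pred_label)
    ari = adjusted_rand_index(
        [truth_label[c] for c in shared], [pred_label[c] for c in shared]
    )
    truth_parts = {}
    for c in shared:
        truth_parts.setdefault(truth_label[c], set()).add(c)
    pred_parts = {}
    for c in shared:
        pred_parts.setdefault(pred_label[c], set()).add(c)
    exact = sum(1 for p in truth_parts.values() if p in pred_parts.values())
    report["derep"] = {
        "n_votus": len(votus),
        "n_truth_clusters": len(truth_parts),
        "ari": ari,
        "exact_cluster_recovery": exact / len(truth_parts) if truth_parts else 1.0,
    }

    # -- 3. taxonomy consensus -----------------------------------------
    assignments = []
    for tool, table in scn.taxonomy_tables.items():
        evid_cols = [c for c in table.columns if c not in ("votu_id", "lineage")]
        for row in table.itertuples(index=False):
            assignments.append(
                taxonomy.ToolAssignment(
                    votu_id=row.votu_id,
                    tool=tool,
                    lineage=RankedLineage.from_string(row.lineage),
                    evidence={c: float(getattr(row, c)) for c in evid_cols},
                )
            )
    consensus_lineages = taxonomy.integrate_assignments(
        assignments, mode=integrate_mode
    )
    truth_lineages: dict[str, RankedLineage] = scn.truth["_lineage_objects"]
    for votu_id in truth_lineages:
        consensus_lineages.setdefault(votu_id, RankedLineage())
    classification = taxonomy.classification_summary(consensus_lineages)

    fam_total = fam_correct = 0
    for votu_id, true_lin in truth_lineages.items():
        if true_lin.name_at("family") is None:
            continue
        fam_total += 1
        if consensus_lineages[votu_id].name_at("family") == true_lin.name_at("family"):
            fam_correct += 1
    report["taxonomy"] = {
        "n_classified": int(
            sum(1 for l in consensus_lineages.values() if not l.is_empty)
        ),
        "family_accuracy": fam_correct / fam_total if fam_total else float("nan"),
        "percent_family_or_subfamily": float(
            classification.loc[
                classification["rank"] == "family_or_subfamily", "percent"
            ].iloc[0]
        ),
    }

    # -- 4. lifestyle ---------------------------------------------------
    provirus_by_contig = dict(
        zip(scn.checkv_quality["contig_id"], scn.checkv_quality["provirus"])
    )
    ann_by_votu: dict[str, list[str]] = {}
    for row in scn.gene_annotations.itertuples(index=False):
        ann_by_votu.setdefault(row.votu_id, []).append(row.description)
    vib = dict(zip(scn.vibrant_lifestyle["votu_id"], scn.vibrant_lifestyle["call"]))
    bac = dict(
        zip(scn.bacphlip_scores["votu_id"], scn.bacphlip_scores["temperate_score"])
    )
    votu_ids = sorted(truth_lineages)
    evidence = [
        lifestyle.LifestyleEvidence(
            votu_id=v,
            checkv_provirus=provirus_by_contig.get(v) == "Yes",
            marker_genes=tuple(ann_by_votu.get(v, ())),
            vibrant_call=vib.get(v),
            bacphlip_temperate_score=(
                float(bac[v]) if v in bac else None
            ),
        )
        for v in votu_ids
    ]
    calls = lifestyle.call_lifestyles(evidence)
    truth_ls = dict(
        zip(scn.truth["lifestyles"]["votu_id"], scn.truth["lifestyles"]["lifestyle"])
    )
    finals = {v: c.final for v, c in calls.items()}
    n_ls = len(truth_ls)
    acc = sum(1 for v in truth_ls if finals.get(v) == truth_ls[v]) / n_ls
    report["lifestyle"] = {
        "accuracy": acc,
        "lytic_fraction": sum(1 for f in finals.values() if f == "lytic") / n_ls,
        "lysogenic_fraction": sum(1 for f in finals.values() if f == "lysogenic")
        / n_ls,
    }

    # -- 5. AMG curation ------------------------------------------------
    cands = _candidates_from_scenario(scn)
    votu_hosts = dict(zip(scn.links["votu_id"], scn.links["host_genome_id"]))
    curated = amg_mod.curate(
        cands,
        reference_proteins=scn.reference_proteins,
        host_proteomes=scn.host_proteomes,
        host_genomes=scn.host_genomes,
        votu_hosts=votu_hosts,
        votu_seqs=scn.sequences,
        flank_window=cfg.flank_window,
    )
    amg_truth = scn.truth["amg"].set_index("gene_id")
    merged = curated.set_index("gene_id").join(
        amg_truth[["kind", "retained", "flank_ok"]], rsuffix="_truth"
    )
    retained_ok = (merged["retained"] == merged["retained_truth"]).mean()
    flank_ok = (merged["flank_ok"] == merged["flank_ok_truth"]).mean()
    true_amgs = merged[merged["kind"].isin(["known", "novel"])]
    nov_ok = (true_amgs["novelty"] == true_amgs["kind"]).mean()
    host_ident = merged[merged["kind"] == "host_identical"]
    ident_ok = (
        host_ident["host_redundancy"].isin(["identical", "excluded"]).mean()
        if len(host_ident)
        else float("nan")
    )
    contam_truth = scn.truth["contamination"]
    contam_ok = []
    for r in contam_truth.itertuples(index=False):
        found = amg_mod.contamination_check(
            scn.sequences[r.votu_id], [scn.host_genomes[r.host_genome_id]]
        )
        contam_ok.append(found == r.contaminated)
    report["amg"] = {
        "n_candidates": len(cands),
        "n_retained": int(merged["retained"].sum()),
        "filter_accuracy": float(retained_ok),
        "flank_accuracy": float(flank_ok),
        "novelty_accuracy": float(nov_ok),
        "n_novel": int((merged["retained"] & (merged["novelty"] == "novel")).sum()),
        "host_identical_detected": float(ident_ok),
        "contamination_accuracy": float(np.mean(contam_ok)) if contam_ok else 1.0,
    }

    # -- 6. abundance & activity ---------------------------------------
    virus_tpm = ab.tpm(scn.counts_virus)
    host_tpm = ab.tpm(scn.counts_host)
    virus_tx_tpm = ab.tpm(scn.counts_virus_tx, min_covered_fraction=0.0)
    amg_tx_tpm = ab.tpm(scn.counts_amg_tx, min_covered_fraction=0.0)
    active = ab.activity(virus_tx_tpm)
    truth_active = dict(
        zip(scn.truth["active"]["votu_id"], scn.truth["active"]["active"])
    )
    agree = sum(
        1 for v, flag in truth_active.items() if bool(active.get(v)) == bool(flag)
    )
    report["activity"] = {
        "active_fraction": float(active.mean()),
        "truth_fraction": float(np.mean(list(truth_active.values()))),
        "accuracy": agree / len(truth_active),
    }

    # -- 7. ecology -----------------------------------------------------
    alpha = ecology.alpha_diversity_table(virus_tpm)
    env = scn.environment.set_index("sample_id")
    pair_table = ecology.screen_pairs(virus_tpm, host_tpm, scn.links, env)
    planted = scn.truth["associations"]
    recovered = 0
    for r in planted.itertuples(index=False):
        row = pair_table[
            (pair_table["votu_id"] == r.votu_id)
            & (pair_table["host_id"] == r.host_genome_id)
            & (pair_table["variable"] == r.variable)
        ]
        if len(row) and bool(row["flagged"].iloc[0]) and (
            np.sign(row["rho_virus"].iloc[0]) == r.sign
        ):
            recovered += 1
    n_flagged = int(pair_table["flagged"].sum())
    report["ecology"] = {
        "n_planted": len(planted),
        "planted_recovered": recovered,
        "n_flagged": n_flagged,
        "mean_richness": float(alpha["richness"].mean()),
        "mean_shannon": float(alpha["shannon"].mean()),
    }

    return PipelineResult(
        passed_contigs=passed,
        votus=votus,
        consensus_lineages=consensus_lineages,
        classification=classification,
        lifestyle_calls=calls,
        amg_curation=curated,
        virus_tpm=virus_tpm,
        virus_tx_tpm=virus_tx_tpm,
        host_tpm=host_tpm,
        amg_tx_tpm=amg_tx_tpm,
        active=active,
        alpha=alpha,
        pair_table=pair_table,
        report=report,
    )
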