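"""The scenario generator: determinism, parseability, planted truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from viroflow import ScenarioConfig, pairwise_ani, read_table, simulate
from viroflow.simulate import gen_community, read_fasta


def test_fixed_seed_reproduces_byte_identical_outputs(tmp_path):
    cfg = ScenarioConfig(seed=42, n_votus=10)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate(cfg).write(d1)
    simulate(cfg).write(d2)
    for f in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f


def test_different_seeds_differ(tmp_path):
    a = simulate(ScenarioConfig(seed=1, n_votus=5))
    b = simulate(ScenarioConfig(seed=2, n_votus=5))
    assert a.sequences != b.sequences


def test_all_emitted_tables_parse_through_their_readers(tmp_path, small_scenario):
    out = tmp_path / "scn"
    small_scenario.write(out)
    dialect_files = {
        "genomad_hits.tsv": "genomad_hits",
        "virsorter2_hits.tsv": "virsorter2_hits",
        "deepvirfinder_hits.tsv": "deepvirfinder_hits",
        "vibrant_hits.tsv": "vibrant_hits",
        "checkv_quality.tsv": "checkv_quality",
        "vcontact2_tax.tsv": "vcontact2_tax",
        "blastn_tax.tsv": "blastn_tax",
        "genomad_tax.tsv": "genomad_tax",
        "phagcn2_tax.tsv": "phagcn2_tax",
        "vpfclass_tax.tsv": "vpfclass_tax",
        "vibrant_lifestyle.tsv": "vibrant_lifestyle",
        "bacphlip.tsv": "bacphlip_scores",
        "annotations.tsv": "gene_annotations",
        "dramv_amgs.tsv": "dramv_amgs",
        "amg_neighborhoods.tsv": "gene_neighborhood",
        "links.tsv": "virus_host_links",
        "counts_virus.tsv": "feature_counts",
        "counts_virus_tx.tsv": "feature_counts",
        "counts_host.tsv": "feature_counts",
        "counts_amg_tx.tsv": "feature_counts",
        "environment.tsv": "environment",
    }
    for fname, dialect in dialect_files.items():
        df = read_table(out / fname, dialect)
        assert isinstance(df, pd.DataFrame)
    seqs = read_fasta(out / "contigs.fasta")
    assert seqs == small_scenario.sequences


def test_zero_divergence_collapses_clusters_and_lengths_hold():
    cfg = ScenarioConfig(seed=3, n_votus=6, within_divergence=0.0)
    seqs, lengths, clusters = gen_community(cfg, np.random.default_rng(3))
    assert min(lengths.values()) >= cfg.min_length
    for _, grp in clusters.groupby("cluster_id"):
        members = list(grp["contig_id"])
        rep = grp["representative"].iloc[0]
        for m in members:
            sim = pairwise_ani(seqs[m], seqs[rep])
            assert sim.ani_pct == 100.0

    # high divergence pushes members outside the 95% gate (truth recorded)
    cfg_hi = ScenarioConfig(
        seed=3, n_votus=6, within_divergence=0.10, extra_member_rate=1.5
    )
    seqs_hi, _, clusters_hi = gen_community(cfg_hi, np.random.default_rng(3))
    multi = clusters_hi.groupby("cluster_id").filter(lambda g: len(g) > 1)
    checked = 0
    for _, grp in multi.groupby("cluster_id"):
        rep = grp["representative"].iloc[0]
        for m in grp["contig_id"]:
            if m == rep:
                continue
            assert pairwise_ani(seqs_hi[m], seqs_hi[rep]).ani_pct < 95.0
            checked += 1
    assert checked > 0


def test_empty_community_is_valid(tmp_path):
    cfg = ScenarioConfig(seed=0, n_votus=0)
    seqs, lengths, clusters = gen_community(cfg, np.random.default_rng(0))
    assert seqs == {} and lengths == {}
    assert len(clusters) == 0
    scn = simulate(cfg)
    scn.write(tmp_path / "empty")
    assert read_fasta(tmp_path / "empty" / "contigs.fasta") == {}


def test_screening_scores_straddle_thresholds_at_configured_rate():
    """Reported geNomad scores pass the 0.8 cutoff at ~screen_pass_rate."""
    cfg = ScenarioConfig(
        seed=9, n_votus=400, extra_member_rate=0.0, screen_pass_rate=0.7,
        guarantee_detection=False,
    )
    scn = simulate(cfg)
    g = scn.predictor_tables["genomad"]
    rate = (g["score"] >= 0.8).mean()
    n = len(g)
    ci = 3 * np.sqrt(0.7 * 0.3 / n)
    assert rate == pytest.approx(0.7, abs=ci)


def test_lifestyle_mixture_and_activity_truth_recorded():
    cfg = ScenarioConfig(seed=13, n_votus=300, extra_member_rate=0.0)
    scn = simulate(cfg)
    ls = scn.truth["lifestyles"]["lifestyle"]
    assert ls.value_counts(normalize=True)["lytic"] == pytest.approx(0.822, abs=0.08)
    active = scn.truth["active"]["active"]
    assert active.mean() == pytest.approx(0.15, abs=0.07)
    # inactive features have strictly zero transcript counts
    tx = scn.counts_virus_tx.set_index("feature_id")
    count_cols = [c for c in tx.columns if c.startswith("count_")]
    for votu, flag in zip(scn.truth["active"]["votu_id"], active):
        if not flag:
            assert (tx.loc[votu, count_cols] == 0).all()
        else:
            assert (tx.loc[votu, count_cols] > 0).any()
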