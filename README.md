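# viroflow

**Multi-tool integration for sediment virome analysis.**

Viral metagenomics leans on a stack of single-purpose tools: four viral
predictors find candidate contigs, CheckV grades and trims them, five
classifiers each offer a (frequently conflicting) taxonomy, four methods
weigh in on lytic vs lysogenic lifestyle, DRAM-v nominates auxiliary
metabolic genes (AMGs), and coverage tools turn read mappings into
abundances. The published answers — how many vOTUs, what fraction
lysogenic, which AMGs are novel, which virus–host pairs track ammonium —
live in the *integration rules* between those tools, which are usually
described in a Methods section and never shipped as code.

`viroflow` implements that integration layer as a tested, reusable
library for researchers analysing environmental (here: proglacial-lake
sediment) viromes:

- **Screening** — a contig ≥ 10 kb is viral if any tool accepts it:
  geNomad score ≥ 0.8, VirSorter2 score > 0.9, DeepVirFinder score ≥ 0.9
  with *p* < 0.05, or any VIBRANT call; accepted sets are merged.
- **Dereplication** — greedy centroid clustering into vOTUs at ≥ 95%
  ANI over ≥ 85% alignment fraction of the shorter contig
  (longest-contig-first, as in the CheckV clustering scripts).
- **Consensus taxonomy** — per-tool acceptance rules (vConTACT2 > 50%
  of proteins at bit score ≥ 50; BLASTn top hit ≥ 90% id / ≥ 75% cov;
  PhaGCN2 > 0.5; VPF-Class 0.5 / 0.75), then hierarchical integration in
  the priority order vConTACT2 > BLASTn > geNomad > PhaGCN2 > VPF-Class,
  with rank conflicts resolved by the lowest common ancestor (LCA).
- **Lifestyle** — CheckV provirus boundaries and lysogeny-marker
  annotations (integrase, invertase, serine recombinase, transposase,
  CI/Cro repressor, parA/B) argue for lysogeny; VIBRANT and BACPHLIP
  (temperate score ≥ 0.9) call either way; two agreeing methods decide,
  otherwise the priority CheckV > annotation > VIBRANT > BACPHLIP.
- **AMG curation** — DRAM-v confidence filter (auxiliary_score ≤ 3,
  flags `M` or `M`+`E`/`K`), viral-context flank check, novelty against
  a reference AMG protein set (≥ 30% identity over ≥ 60% bidirectional
  coverage ⇒ known), host-redundancy (BLASTp-style, > 40% id over 60%
  of the viral query) guarded by a nucleotide contamination check.
- **Abundance & activity** — TPM per sample over features passing a
  covered-fraction gate (10% for metagenomes),
  `TPM_i = (c_i/L_i) / Σ_j (c_j/L_j) × 10⁶`; a feature is active when
  its transcript TPM exceeds zero in any sample; AMGs inherit their
  vOTU's metagenomic abundance.
- **Ecology** — richness, Shannon *H′* and Pielou evenness; Spearman ρ
  with an *exact* permutation p-value at n ≤ 8 samples; a virus–host
  pair is flagged for an environmental variable only when both partners
  reach |ρ| ≥ 0.80 at *p* < 0.05 with consistent signs.
- **Simulation** — a seeded generator (`viroflow.simulate`) that emits
  every input table with recorded ground truth, so each stage is
  testable end-to-end without any sequencing data.

## Worked example

Integrating a taxonomy conflict (`examples/02_consensus_taxonomy.py`):

```text
family conflict, shared order -> realm=Duplodnaviria;kingdom=Heunggongvirae;phylum=Uroviricota;class=Caudoviricetes;order=Synvirales
  (Peduoviridae vs Kyanoviridae collapses to their common order)

no shared rank at all -> realm=Duplodnaviria;...;family=Peduoviridae
  (highest-priority tool, vConTACT2, wins the arbitration)
```

Two tools that disagree at family but agree above back off to the
deepest shared rank; tools with no common rank at all are arbitrated by
the stated priority order.

Screening the environment for virus–host associations
(`examples/06_environment_correlations.py`):

```text
virus vs NH4+-N: Spearman rho=-1.00, exact p=0.0028
pair screen: rho_virus=-1.00, rho_host=-1.00, flagged=True
```

With six samples the exact permutation null has 720 orderings, so a
perfectly monotone association attains p = 2/720 ≈ 0.0028 — small
enough to clear the p < 0.05 gate that the asymptotic approximation
handles poorly at this n.

A full simulated study (`examples/07_full_pipeline.py`) prints a
per-stage score report; on the default 6-sample scenario every planted
fact is recovered:

```text
"derep":    {"ari": 1.0, "n_votus": 60, ...}
"lifestyle":{"accuracy": 1.0, "lytic_fraction": 0.883, ...}
"ecology":  {"n_planted": 3, "planted_recovered": 3, ...}
```

A thin CLI mirrors the library (`viroflow simulate|screen|derep|
taxonomy|lifestyle|abundance|activity|amg|ecology|run`).

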