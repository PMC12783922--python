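# Methods

This note documents the models and procedures `viroflow` implements,
the defaults it ships, and the decisions taken where the underlying
conventions are genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Taxonomic lineages and the LCA

Lineages use the eight-rank ladder realm → kingdom → phylum → class →
order → family → subfamily → genus. Subfamily is treated as an
*optional* rank: a lineage naming family and genus but no subfamily has
no gap, matching ICTV usage where subfamilies exist only in some
families. Names are compared case-sensitively after whitespace
trimming; no synonym resolution is attempted. The fully unclassified
(empty) lineage is a first-class value.

`lca(a, b)` walks the ranks top-down and keeps the shared prefix: a
rank named identically by both is kept, a rank named by neither is
skipped, and the walk stops at the first disagreement *or* at the first
rank only one lineage resolves (agreement cannot be confirmed there).
This makes LCA commutative and associative, so integrating any number
of lineages is order-independent — a property the test suite checks
over all 120 orderings of five-lineage sets.

Family-level tallies are reported twice: strictly (named family only)
and with subfamily-only classifications folded in
(`family_or_subfamily`), because published community summaries commonly
count named subfamilies as family-level classifications.

## Consensus taxonomy

Each tool's call passes through its own acceptance rule before
integration (thresholds in the README). Integration follows the
priority order vConTACT2 > BLASTn > geNomad > PhaGCN2 > VPF-Class:

1. no accepted lineage → unclassified;
2. one accepted lineage → taken as is;
3. several, every pair sharing at least its topmost mutually named
   rank → the LCA of all (conflicts at a lower rank back off to the
   deepest shared rank);
4. any pair agreeing on no rank → the highest-priority accepted
   lineage.

Case 4 covers both fully disjoint name sets and pairs that conflict at
their topmost comparable rank; the priority list's only documented role
is conflict arbitration, so it decides both. An alternative
`first-accept` mode (walk the priority list, stop at the first
accepted tool) is exposed because the hierarchical wording admits that
reading too; the default is LCA-across-all.

"Top best hit" for the BLASTn stream means highest bitscore, ties
broken by lowest e-value, then file order (`best_blastn_hit`).

## Lifestyle consensus

Per-method semantics are asymmetric by design: CheckV (provirus
boundary) and gene-annotation keyword matches can only assert
*lysogeny* — the absence of a provirus is not evidence of a lytic
lifestyle — while VIBRANT and BACPHLIP can call either way. BACPHLIP
calls lysogenic at temperate score ≥ 0.9 and lytic at virulent score
(1 − temperate) ≥ 0.9. Keyword matching is case-insensitive substring
search over annotation text (integrase, invertase, serine recombinase,
transposase, CI/Cro repressor, parA/parB); a word-boundary mode is
available for stricter matching.

The combination rule: a label with ≥ `min_agree` votes (default 2) and
strictly more votes than the other label wins by agreement; every
other situation with at least one caller falls back to the priority
CheckV > annotation > VIBRANT > BACPHLIP (this also covers the 2–2 tie
possible with four callers, which the two stated rules alone leave
undefined). A single caller decides alone; no caller leaves the vOTU
undetermined. The rule is verified against an independently coded
brute force over all 256 call combinations.

`lifestyle_summary` compares the per-sample lytic and lysogenic
proportion vectors with a Welch two-tailed t test. When both vectors
are constant the statistic is undefined and reported as NA — except
when they are elementwise identical, where t = 0, p = 1 (no evidence
of a difference is a defined answer there).

## ANI / AF and dereplication

ANI is the length-weighted identity over accepted local alignment
blocks; AF is the fraction of the *shorter* sequence those blocks
cover. The block finder tiles the shorter sequence into 500 bp windows
and aligns each window end-to-free (edlib infix mode) against the
longer sequence; a window counts as a block when its identity reaches
0.80. Unrelated sequences produce no accepted blocks (AF = 0), while
sequences near the 95% clustering threshold are covered essentially
everywhere. `N` bases match nothing, including other `N`s. On
substitution-only pairs the estimate agrees with a global no-gap
identity count to within ±0.3 percentage points (tested at 2%
divergence).

All-vs-all comparison prescreens pairs with a hash-sampled 16-mer
sketch (~1/8 of k-mers kept): pairs sharing fewer than 3 sampled
k-mers are reported as ANI = AF = 0 without alignment. Any pair near
the clustering threshold shares thousands of sampled 16-mers, so the
prescreen cannot remove true cluster edges; it reduces a 300-contig
all-vs-all from minutes to seconds.

Clustering is greedy and centroid-based: contigs sorted by length
descending (ties by id ascending); each joins the first centroid at
ANI ≥ 95 and AF ≥ 85, else founds a new cluster. Representatives are
therefore the longest members, and the outcome is independent of input
row order. Contig lengths are taken as given in the input tables
(whether upstream provirus trimming was applied is upstream's
concern).

## AMG curation

The confidence filter retains candidates with auxiliary_score ≤ 3 and
a flag set of `M` alone or `M` with `E` and/or `K` — nothing else.
The flank check mechanizes a manual inspection step: within a window
(default 3 genes, configurable) on *each existing side* of the
candidate there must be at least one viral-hallmark or viral-like
gene; candidates at contig ends are judged on the existing side only,
and a candidate with no neighbours fails (no viral context is
demonstrable).

Novelty is decided by direct candidate-vs-reference protein alignment
(Biopython local alignment, BLOSUM62, gap open/extend −11/−1): a
candidate aligning to any reference AMG at ≥ 30% identity with ≥ 60%
coverage of both sequences is *known*, else *novel*. This is the
testable semantics of "does not cluster with the reference set" without
re-implementing a cascaded clustering heuristic; coverage is
bidirectional, mirroring the coverage-mode default of the cited
clustering approach. Host redundancy uses the same aligner with
query-side coverage only (the thresholds are stated on the viral query):
100% identity at ≥ 60% query coverage ⇒ `identical`, > 40% ⇒
`homologous`, else `absent`. Before interpreting host homology, a
nucleotide contamination check asks whether the host genome carries an
exact copy of part of the vOTU: an exact shared substring at least as
long as the shortest megablast-significant hit at e ≤ 10⁻³
(Karlin–Altschul with K = 0.46, λ = 1.28; ~25 bp at typical sizes),
found by exact k-mer scan. Contaminated pairs are excluded from the
redundancy interpretation.

## Abundance and activity

TPM per sample: `rate_i = count_i / length_i` over features whose
covered fraction passes the gate (0.10 for metagenome streams, 0 for
transcript-AMG streams); `TPM_i = rate_i / Σ rate × 10⁶`; gated-out
features report 0. Gating happens *before* normalisation, so the
passing features always sum to exactly 10⁶ per sample (an invariant the
oracle tests pin); an all-zero sample yields an all-zero column rather
than a division error. Transcript counts are assumed pre-filtered to
mapping quality ≥ 30 upstream; the module records that contract rather
than re-deriving it. Activity is `TPM > 0` in any sample, and AMGs
inherit their parent vOTU's metagenomic TPM row verbatim so host-derived
reads cannot inflate gene-level abundance.

## Ecology

Shannon uses the natural log by default (a base flag exists); evenness
is H′/ln(richness), undefined at richness ≤ 1. Spearman ρ is the
Pearson correlation of mid-ranks; for n ≤ 8 the two-sided p-value is
exact, enumerating all n! permutations of the y-ranks (720 at the
design's n = 6), because the t-approximation is unreliable at such n.
The smallest achievable p at n = 6 is 2/720 ≈ 0.0028, so the screen's
p < 0.05 gate is attainable only by near-perfect monotone
associations — which is the intended strictness. Raw p-values are used
(no multiple-testing correction) to mirror the per-pair reporting
convention; a Benjamini–Hochberg option exists but is off by default.
A pair/variable combination is flagged only when virus and host both
reach |ρ| ≥ 0.80 at p < 0.05 with agreeing signs.

## The synthetic-data generator

`ScenarioConfig` defaults encode the emulated study design:

| parameter | default | rationale |
|---|---|---|
| samples | 6 (3 sites × 2 months) | the study design |
| contig length | log-uniform 10–60 kb | the reported genome-size band |
| cluster members | 1 + Poisson(0.36) | the ~1.36 contigs-per-vOTU ratio |
| within-cluster divergence | 2% substitutions | safely inside the 95/85 gate |
| lifestyle mixture | 0.822 / 0.106 / 0.072 | the reported lytic/lysogenic split |
| active fraction | 0.15 | the reported fraction of active vOTUs |
| quality tiers | 83.8 / 9.5 / 3.6 / 2.9 / 0.2% | the reported CheckV tier mix |
| per-tool taxonomy error | 0.05 sibling-family | small, family-rank confusable |
| NB dispersion | 0.3 | moderate overdispersion for count noise |
| planted associations | 3 negative vs NH₄⁺-N | the headline pair–variable finding |
| n_votus | 220 (≈ 300 contigs) | desk-scale end-to-end runs in seconds |

Counts are negative-binomial around lognormal relative abundances.
Environment associations are injected by *rank-preserving assignment*:
a planted feature's counts follow a factor-6 geometric ladder ordered
by the variable's sample ranks, so the planted Spearman correlation of
the resulting TPM is exactly ±1 by construction (the factor dominates
any between-sample variation of the TPM denominator). Inactive
features have strictly zero transcript counts, so the planted active
fraction is recovered exactly, not approximately.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: assembly fragmentation and chimerism, indels
and rearrangements between cluster members (substitution-only by
default; an indel rate is configurable but the ANI oracle then no
longer reduces to a Hamming count), compositional biases, shared gene
content between unrelated viruses, correlated errors between tools
(tool mistakes are drawn independently), and read-level noise (counts
are generated at the feature level; there is no FASTQ simulation).

## Numerical and degenerate-input conventions

Ties in contig length break by id; ties in BLASTn bitscore by e-value
then file order. Constant vectors make Spearman undefined (NA), and a
pair with an undefined correlation is never flagged. Zero feature
length is an error; an all-zero sample is a valid all-zero column.
vOTU records enforce the 10 kb floor and the CheckV tier vocabulary.
Probabilities and mixtures are validated on configuration.

## Scoring definitions

Consensus-vs-single-tool comparisons use coverage-inclusive family
accuracy: over all vOTUs whose true lineage names a family, a
classifier is correct iff it produces an accepted lineage naming that
family — no call counts as wrong. Under complete acceptance by all
five tools the LCA consensus is necessarily below any single tool
(a single erring tool erases the family rank), so the advantage of
consensus appears in the realistic regime where each tool accepts only
part of the catalogue; the generator's default report/accept rates
(0.9 / 0.8) model that regime. Dereplication is scored by
adjusted Rand index and by the fraction of truth clusters recovered
exactly.

## Known limitations

The ANI block finder uses fixed windows rather than seed-extended HSPs,
so AF is quantised at the window size for partially overlapping
sequences; the lifestyle keyword list is the stated marker set only; the
contamination check models megablast statistics with fixed
Karlin–Altschul parameters rather than computing them from the actual
scoring system; and `screen_pairs` correlates the metagenome TPM matrix
as given (which normalised-coverage variant fed the original analysis
is not derivable from its description).
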