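"""ANI/AF estimation and greedy vOTU clustering."""

from __future__ import annotations

import numpy as np
import pytest

from viroflow import (
    MissingPairError,
    PairwiseSimilarity,
    all_vs_all,
    greedy_cluster,
    pairwise_ani,
)
from viroflow.simulate import mutate_sequence, random_sequence


def hamming_identity_pct(a: str, b: str) -> float:
    """Independent oracle: global no-gap identity of equal-length sequences."""
    assert len(a) == len(b)
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float((arr_a == arr_b).mean())


class TestPairwiseANI:
    def test_identical_sequences(self, rng):
        s = random_sequence(rng, 10_000)
        sim = pairwise_ani(s, s)
        assert sim.ani_pct == 100.0
        assert sim.af_pct == 100.0

    def test_unrelated_sequences_have_zero_af(self, rng):
        a = random_sequence(rng, 10_000)
        b = random_sequence(rng, 8_000)
        sim = pairwise_ani(a, b)
        assert sim.af_pct == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_two_percent_substitutions_match_global_oracle(self, seed):
        """ANI of a 2%-mutated copy tracks the global-alignment identity."""
        rng = np.random.default_rng(seed)
        s = random_sequence(rng, 10_000)
        t = mutate_sequence(rng, s, 0.02)
        oracle = hamming_identity_pct(s, t)
        sim = pairwise_ani(s, t)
        assert sim.ani_pct == pytest.approx(oracle, abs=0.3)
        assert sim.af_pct >= 99.0

    def test_symmetric_in_argument_order(self, rng):
        a = random_sequence(rng, 9_000)
        b = mutate_sequence(rng, a, 0.03)[:8_000]
        s1 = pairwise_ani(a, b)
        s2 = pairwise_ani(b, a)
        assert s1.ani_pct == pytest.approx(s2.ani_pct)
        assert s1.af_pct == pytest.approx(s2.af_pct)

    def test_n_bases_never_match(self):
        s = "A" * 600
        t = "A" * 300 + "N" * 300
        sim = pairwise_ani(s, t, window=600, block_min_identity=0.4)
        assert sim.ani_pct == pytest.approx(50.0, abs=2.0)
        # even N-vs-N columns count as mismatches
        seq_n = "N" * 200 + "A" * 400
        both_n = pairwise_ani(seq_n, seq_n, window=600, block_min_identity=0.4)
        assert both_n.ani_pct < 100.0

    def test_empty_or_invalid_sequence_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pairwise_ani("", "ACGT")
        with pytest.raises(ValueError, match="invalid characters"):
            pairwise_ani("ACGU", "ACGT")

    def test_prescreen_reports_every_pair(self, rng):
        seqs = {f"c{i}": random_sequence(rng, 3_000) for i in range(5)}
        sims = all_vs_all(seqs)
        assert len(sims) == 10


def sim(a, b, ani, af):
    return PairwiseSimilarity(a, b, ani, af)


class TestGreedyCluster:
    def test_three_mutually_similar_contigs_form_one_votu(self):
        lengths = {"A": 30_000, "B": 20_000, "C": 15_000}
        sims = [
            sim("A", "B", 97, 95),
            sim("A", "C", 96, 90),
            sim("B", "C", 98, 99),
        ]
        votus = greedy_cluster(sims, lengths)
        assert len(votus) == 1
        assert votus[0].representative_contig == "A"
        assert sorted(votus[0].member_contigs) == ["A", "B", "C"]

    def test_chain_splits_under_centroid_rule(self):
        """A~B and B~C but not A~C: C cannot join A's cluster."""
        lengths = {"A": 30_000, "B": 20_000, "C": 15_000}
        sims = [
            sim("A", "B", 96, 90),
            sim("B", "C", 96, 90),
            sim("A", "C", 80, 90),
        ]
        votus = greedy_cluster(sims, lengths)
        parts = {v.representative_contig: set(v.member_contigs) for v in votus}
        assert parts == {"A": {"A", "B"}, "C": {"C"}}

    def test_missing_pair_is_an_error(self):
        lengths = {"A": 30_000, "B": 20_000}
        with pytest.raises(MissingPairError):
            greedy_cluster([], lengths)

    def test_length_tie_breaks_toward_smaller_id(self):
        lengths = {"B": 20_000, "A": 20_000}
        votus = greedy_cluster([sim("A", "B", 99, 99)], lengths)
        assert votus[0].representative_contig == "A"

    def test_cluster_count_invariant_to_row_order(self, rng):
        ids = [f"c{i}" for i in range(10)]
        lengths = {c: int(rng.integers(10_000, 50_000)) for c in ids}
        sims = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                related = rng.random() < 0.3
                sims.append(
                    sim(a, b, 97.0 if related else 70.0, 95.0 if related else 40.0)
                )
        ref = greedy_cluster(sims, lengths)
        perm = list(sims)
        rng.shuffle(perm)
        shuffled = greedy_cluster(perm, lengths)
        assert [v.member_contigs for v in ref] == [v.member_contigs for v in shuffled]

    def test_members_meet_thresholds_to_representative(self, rng):
        ids = [f"c{i}" for i in range(12)]
        lengths = {c: int(rng.integers(10_000, 40_000)) for c in ids}
        table = {}
        sims = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ani = float(rng.uniform(80, 100))
                af = float(rng.uniform(50, 100))
                table[frozenset((a, b))] = (ani, af)
                sims.append(sim(a, b, ani, af))
        for v in greedy_cluster(sims, lengths):
            rep = v.representative_contig
            for m in v.member_contigs:
                if m == rep:
                    continue
                ani, af = table[frozenset((m, rep))]
                assert ani >= 95 and af >= 85


def test_dereplicate_divergent_and_identical(rng):
    from viroflow import dereplicate

    base = random_sequence(rng, 12_000)
    seqs = {
        "long": base,
        "near": mutate_sequence(rng, base, 0.02)[:11_500],
        "far": random_sequence(rng, 10_500),
    }
    votus = dereplicate(seqs)
    parts = {v.representative_contig: set(v.member_contigs) for v in votus}
    assert parts == {"long": {"long", "near"}, "far": {"far"}}
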