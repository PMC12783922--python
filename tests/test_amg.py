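"""AMG confidence filtering, flank context, novelty and host homology."""

from __future__ import annotations

import numpy as np
import pytest

from viroflow import (
    AMGCandidate,
    check_flanks,
    contamination_check,
    filter_amgs,
    host_redundancy,
    novelty,
)
from viroflow.amg import FlagError, parse_flags
from viroflow.simulate import AMINO_ACIDS, mutate_sequence, random_sequence


def cand(score=2, flags="M", pos=5, neighborhood=(), seq="MKVLAWTSGERR"):
    return AMGCandidate(
        gene_id="g1",
        votu_id="v1",
        ko_id="K00001",
        auxiliary_score=score,
        amg_flags=parse_flags(flags),
        position_on_contig=pos,
        protein_seq=seq,
        neighborhood=neighborhood,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "score,flags,kept",
        [
            (3, "M", True),      # boundary score inclusive
            (1, "ME", True),
            (2, "MEK", True),
            (2, "MK", True),
            (4, "M", False),     # score too high
            (2, "MV", False),    # V outside {M, E, K}
            (2, "EK", False),    # metabolic flag M required
            (5, "MEK", False),
        ],
    )
    def test_filter_rule(self, score, flags, kept):
        retained = filter_amgs([cand(score=score, flags=flags)])
        assert (len(retained) == 1) is kept

    def test_malformed_flag_names_the_gene(self):
        with pytest.raises(FlagError, match="g9"):
            parse_flags("MZ", gene_id="g9")

    def test_filter_monotone_in_score_threshold(self, rng):
        cands = [
            cand(score=int(rng.integers(1, 6)), flags="M")
            for _ in range(50)
        ]
        strict = {id(c) for c in filter_amgs(cands, max_auxiliary_score=2)}
        relaxed = {id(c) for c in filter_amgs(cands, max_auxiliary_score=3)}
        assert strict <= relaxed


class TestFlanks:
    def test_viral_context_on_both_sides(self):
        nb = ((4, "viral-hallmark"), (7, "viral-like"), (3, "other"))
        assert check_flanks(cand(pos=5, neighborhood=nb), window=3)

    def test_no_viral_genes_anywhere(self):
        nb = ((3, "other"), (4, "other"), (6, "other"))
        assert not check_flanks(cand(pos=5, neighborhood=nb), window=3)

    def test_contig_end_evaluates_existing_side_only(self):
        # candidate at the very start of the contig: only a right flank exists
        nb = ((2, "viral-hallmark"), (3, "other"))
        assert check_flanks(cand(pos=1, neighborhood=nb), window=3)

    def test_viral_gene_outside_window_does_not_count(self):
        nb = ((1, "viral-hallmark"), (9, "viral-hallmark"))
        assert not check_flanks(cand(pos=5, neighborhood=nb), window=3)
        assert check_flanks(cand(pos=5, neighborhood=nb), window=4)

    def test_isolated_gene_fails(self):
        assert not check_flanks(cand(pos=1, neighborhood=()), window=3)


class TestNovelty:
    def test_identical_to_reference_is_known(self, rng):
        ref = random_sequence(rng, 200, AMINO_ACIDS)
        out = novelty([cand(seq=ref)], {"ref1": ref})
        assert out.loc[0, "status"] == "known"
        assert out.loc[0, "reference"] == "ref1"

    def test_unalignable_candidate_is_novel(self, rng):
        refs = {f"r{i}": random_sequence(rng, 200, AMINO_ACIDS) for i in range(5)}
        out = novelty([cand(seq=random_sequence(rng, 200, AMINO_ACIDS))], refs)
        assert out.loc[0, "status"] == "novel"

    def test_half_identity_copy_is_still_known(self, rng):
        ref = random_sequence(rng, 250, AMINO_ACIDS)
        mutant = mutate_sequence(rng, ref, 0.5, alphabet=AMINO_ACIDS)
        out = novelty([cand(seq=mutant)], {"ref1": ref})
        assert out.loc[0, "status"] == "known"


class TestHostRedundancy:
    def test_exact_host_copy_is_identical(self, rng):
        prot = random_sequence(rng, 200, AMINO_ACIDS)
        assert host_redundancy(prot, {"h1": prot}) == "identical"

    def test_seventy_percent_identity_is_homologous(self, rng):
        prot = random_sequence(rng, 300, AMINO_ACIDS)
        homolog = mutate_sequence(rng, prot, 0.3, alphabet=AMINO_ACIDS)
        assert host_redundancy(homolog, {"h1": prot}) == "homologous"

    def test_unrelated_host_proteome_is_absent(self, rng):
        prot = random_sequence(rng, 200, AMINO_ACIDS)
        proteome = {f"h{i}": random_sequence(rng, 200, AMINO_ACIDS) for i in range(5)}
        assert host_redundancy(prot, proteome) == "absent"

    def test_category_ordering_identical_implies_homologous_thresholds(self, rng):
        # an "identical" call always satisfies the homologous thresholds too
        prot = random_sequence(rng, 200, AMINO_ACIDS)
        assert host_redundancy(prot, {"h": prot}) == "identical"
        assert host_redundancy(prot, {"h": prot}, homolog_min_id=40.0) != "absent"


class TestContamination:
    def test_embedded_fragment_is_detected(self, rng):
        votu = random_sequence(rng, 12_000)
        host = random_sequence(rng, 40_000)
        frag = votu[2_000:7_000]
        host = host[:15_000] + frag + host[15_000:]
        assert contamination_check(votu, [host])

    def test_unrelated_sequences_are_clean(self, rng):
        votu = random_sequence(rng, 12_000)
        host = random_sequence(rng, 40_000)
        assert not contamination_check(votu, [host])
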