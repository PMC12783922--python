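"""Per-tool taxonomy acceptance rules and hierarchical LCA integration."""

from __future__ import annotations

import pandas as pd
import pytest

from viroflow import RankedLineage, ToolAssignment, accept, classification_summary, integrate
from viroflow.taxonomy import best_blastn_hit

BASE = dict(
    realm="Duplodnaviria",
    kingdom="Heunggongvirae",
    phylum="Uroviricota",
    class_="Caudoviricetes",
    order="Ordoviralesx",
)
PEDUO = RankedLineage(family="Peduoviridae", **BASE)
KYANO = RankedLineage(family="Kyanoviridae", **BASE)
NCLDV = RankedLineage(
    realm="Varidnaviria", kingdom="Bamfordvirae", phylum="Nucleocytoviricota"
)


def ta(tool, lineage=PEDUO, **evidence):
    return ToolAssignment("v1", tool, lineage, evidence)


@pytest.mark.parametrize(
    "assignment,accepted",
    [
        # vConTACT2: strictly more than half the proteins, bitscore >= 50
        (ta("vcontact2", protein_total=10, protein_assigned_to_family=6, min_bitscore=50), True),
        (ta("vcontact2", protein_total=10, protein_assigned_to_family=5, min_bitscore=200), False),
        (ta("vcontact2", protein_total=10, protein_assigned_to_family=8, min_bitscore=49), False),
        (ta("vcontact2", protein_total=0, protein_assigned_to_family=0, min_bitscore=60), False),
        # BLASTn: top hit, >= 90% identity, >= 75% coverage
        (ta("blastn", pct_identity=92, pct_coverage=80, hit_rank=1), True),
        (ta("blastn", pct_identity=95, pct_coverage=74, hit_rank=1), False),
        (ta("blastn", pct_identity=90, pct_coverage=75, hit_rank=2), False),
        (ta("blastn", pct_identity=90, pct_coverage=75, hit_rank=1), True),
        # PhaGCN2: strict > 0.5
        (ta("phagcn2", score=0.51), True),
        (ta("phagcn2", score=0.5), False),
        # VPF-Class: operating point inclusive
        (ta("vpfclass", membership_ratio=0.5, confidence=0.75), True),
        (ta("vpfclass", membership_ratio=0.6, confidence=0.74), False),
        (ta("vpfclass", membership_ratio=0.49, confidence=0.9), False),
        # geNomad: pre-accepted when a lineage is reported
        (ta("genomad"), True),
    ],
)
def test_acceptance_rules(assignment, accepted):
    got = accept(assignment)
    assert (got is not None) is accepted
    if accepted:
        assert got == assignment.lineage


def test_genomad_empty_lineage_is_no_call():
    assert accept(ta("genomad", lineage=RankedLineage())) is None


class TestIntegrate:
    def test_no_accepted_lineage_is_unclassified(self):
        assert integrate({}).is_empty

    def test_single_tool_passes_through(self):
        cls_only = RankedLineage(
            realm=BASE["realm"], kingdom=BASE["kingdom"],
            phylum=BASE["phylum"], class_=BASE["class_"],
        )
        assert integrate({"genomad": cls_only}) == cls_only

    def test_family_conflict_with_shared_order_gives_order(self):
        got = integrate({"vcontact2": PEDUO, "blastn": KYANO})
        assert got.deepest_rank() == "order"
        assert got.name_at("order") == BASE["order"]

    def test_disjoint_top_rank_falls_back_to_priority(self):
        got = integrate({"vcontact2": PEDUO, "phagcn2": NCLDV})
        assert got == PEDUO
        # and priority is by tool rank, not dict insertion order
        got2 = integrate({"phagcn2": NCLDV, "vcontact2": PEDUO})
        assert got2 == PEDUO

    def test_first_accept_mode_ignores_conflicts(self):
        got = integrate({"vcontact2": PEDUO, "blastn": KYANO}, mode="first-accept")
        assert got == PEDUO

    def test_integrated_lineage_is_ancestor_of_each_input_when_lca_applies(self):
        inputs = {"vcontact2": PEDUO, "blastn": KYANO, "genomad": PEDUO}
        got = integrate(inputs)
        for lin in inputs.values():
            assert got.is_ancestor_or_equal(lin)

    def test_subset_never_conflicts_with_remaining_inputs(self):
        full = {"vcontact2": PEDUO, "blastn": KYANO, "phagcn2": PEDUO}
        sub = {"blastn": KYANO, "phagcn2": PEDUO}
        got = integrate(sub)
        assert got.is_ancestor_or_equal(KYANO) or got.is_empty


def test_best_blastn_hit_orders_by_bitscore_then_evalue():
    df = pd.DataFrame(
        {
            "votu_id": ["v1", "v1", "v1"],
            "lineage": ["a", "b", "c"],
            "pct_identity": [91.0, 92.0, 93.0],
            "pct_coverage": [80.0, 80.0, 80.0],
            "hit_rank": [0, 0, 0],
            "bitscore": [500.0, 900.0, 900.0],
            "evalue": [1e-10, 1e-40, 1e-20],
        }
    )
    ranked = best_blastn_hit(df)
    top = ranked[ranked["hit_rank"] == 1]
    assert list(top["lineage"]) == ["b"]


def test_classification_summary_counts_and_subfamily_folding():
    lineages = {
        "v1": PEDUO,
        "v2": RankedLineage(subfamily="Queuovirinae", **BASE),
        "v3": RankedLineage(
            realm=BASE["realm"], kingdom=BASE["kingdom"],
            phylum=BASE["phylum"], class_=BASE["class_"],
        ),
        "v4": RankedLineage(),
    }
    df = classification_summary(lineages).set_index("rank")
    assert df.loc["class", "count"] == 3
    assert df.loc["family", "count"] == 1          # strict family
    assert df.loc["family_or_subfamily", "count"] == 2
    assert df.loc["any", "count"] == 3
    assert df.loc["family", "percent"] == pytest.approx(25.0)


def test_classification_summary_all_unclassified():
    df = classification_summary({"v1": RankedLineage(), "v2": RankedLineage()})
    assert (df["count"] == 0).all()
    assert (df["percent"] == 0.0).all()
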