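"""Lifestyle evidence calling and four-method consensus."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from viroflow import LifestyleEvidence, call_methods, consensus, lifestyle_summary


class TestCallMethods:
    def test_integrase_annotation_calls_lysogenic(self):
        ev = LifestyleEvidence("v1", marker_genes=("site-specific integrase",))
        assert call_methods(ev)["annotation"] == "lysogenic"

    def test_neutral_annotations_are_silent(self):
        ev = LifestyleEvidence("v1", marker_genes=("major capsid protein",))
        assert call_methods(ev)["annotation"] == "no-call"

    def test_word_boundary_mode_rejects_substring_hits(self):
        # "paralog" contains "para" only as a substring
        ev = LifestyleEvidence("v1", marker_genes=("conserved paralog",))
        assert call_methods(ev)["annotation"] == "lysogenic"
        assert call_methods(ev, word_boundary=True)["annotation"] == "no-call"

    @pytest.mark.parametrize(
        "score,expected",
        [(0.95, "lysogenic"), (0.9, "lysogenic"), (0.05, "lytic"), (0.5, "no-call")],
    )
    def test_bacphlip_thresholds(self, score, expected):
        ev = LifestyleEvidence("v1", bacphlip_temperate_score=score)
        assert call_methods(ev)["bacphlip"] == expected

    def test_checkv_provirus_and_absence(self):
        assert call_methods(LifestyleEvidence("v1", checkv_provirus=True))["checkv"] == "lysogenic"
        assert call_methods(LifestyleEvidence("v1", checkv_provirus=False))["checkv"] == "no-call"
        assert call_methods(LifestyleEvidence("v1"))["checkv"] == "no-call"

    def test_all_streams_absent_is_all_no_call(self):
        calls = call_methods(LifestyleEvidence("v1"))
        assert set(calls.values()) == {"no-call"}


class TestConsensus:
    def test_two_way_agreement_wins(self):
        c = consensus({"vibrant": "lytic", "bacphlip": "lytic"})
        assert (c.final, c.resolved_by) == ("lytic", "agreement")

    def test_checkv_beats_vibrant_on_conflict(self):
        c = consensus({"checkv": "lysogenic", "vibrant": "lytic"})
        assert (c.final, c.resolved_by) == ("lysogenic", "priority")

    def test_single_caller_decides(self):
        c = consensus({"vibrant": "lytic"})
        assert c.final == "lytic"

    def test_no_caller_is_undetermined(self):
        c = consensus({})
        assert (c.final, c.resolved_by) == ("undetermined", "none")

    def test_adding_a_no_call_stream_never_changes_the_result(self):
        base = {"vibrant": "lytic", "bacphlip": "lytic"}
        with_silent = dict(base, checkv="no-call", annotation="no-call")
        assert consensus(base).final == consensus(with_silent).final

    def test_two_two_tie_resolves_by_priority(self):
        c = consensus(
            {
                "checkv": "lysogenic",
                "annotation": "lysogenic",
                "vibrant": "lytic",
                "bacphlip": "lytic",
            }
        )
        assert (c.final, c.resolved_by) == ("lysogenic", "priority")

    def test_majority_beats_priority(self):
        c = consensus(
            {"checkv": "lysogenic", "vibrant": "lytic", "bacphlip": "lytic"}
        )
        assert (c.final, c.resolved_by) == ("lytic", "agreement")


class TestLifestyleSummary:
    def _presence(self, votus, samples):
        return pd.DataFrame(True, index=votus, columns=samples)

    def test_all_lytic_gives_degenerate_t(self):
        finals = {f"v{i}": "lytic" for i in range(5)}
        presence = self._presence(list(finals), ["s1", "s2", "s3"])
        df, t, p = lifestyle_summary(finals, presence)
        assert (df["lytic"] == 1.0).all()
        assert (df["lysogenic"] == 0.0).all()
        assert np.isnan(t) and np.isnan(p)

    def test_identical_proportion_vectors_give_p_one(self):
        finals = {"v1": "lytic", "v2": "lysogenic"}
        presence = self._presence(["v1", "v2"], ["s1", "s2", "s3"])
        df, t, p = lifestyle_summary(finals, presence)
        assert (df["lytic"] == 0.5).all()
        assert t == 0.0 and p == 1.0

    def test_planted_mixture_recovered(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(
            ["lytic", "lysogenic", "undetermined"], size=600, p=[0.8, 0.1, 0.1]
        )
        finals = {f"v{i}": l for i, l in enumerate(labels)}
        presence = self._presence(list(finals), [f"s{j}" for j in range(6)])
        df, t, p = lifestyle_summary(finals, presence)
        assert df["lytic"].mean() == pytest.approx(0.8, abs=0.05)
        assert df["lysogenic"].mean() == pytest.approx(0.1, abs=0.05)
        assert p < 0.05  # lytic clearly dominates lysogenic
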