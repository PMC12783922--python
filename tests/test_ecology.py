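"""Alpha diversity and small-n Spearman screening."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from viroflow import (
    VirusHostLink,
    alpha_diversity,
    screen_pairs,
    sign_counts,
    spearman,
)


class TestAlphaDiversity:
    def test_single_positive_feature(self):
        r, h, e = alpha_diversity([0.0, 7.5, 0.0])
        assert (r, h) == (1, 0.0)
        assert math.isnan(e)

    def test_uniform_community_closed_form(self):
        r, h, e = alpha_diversity([2.0, 2.0, 2.0, 2.0])
        assert r == 4
        assert h == pytest.approx(math.log(4))
        assert e == pytest.approx(1.0)

    def test_matches_textbook_formulas(self, rng):
        x = rng.uniform(0, 10, 50)
        x[rng.random(50) < 0.3] = 0.0
        r, h, e = alpha_diversity(x)
        pos = x[x > 0]
        p = pos / pos.sum()
        assert r == len(pos)
        assert h == pytest.approx(-(p * np.log(p)).sum())
        assert 0.0 <= e <= 1.0

    def test_shannon_maximal_iff_uniform(self, rng):
        uniform = [1.0] * 10
        skewed = rng.uniform(0.1, 5.0, 10)
        _, h_u, _ = alpha_diversity(uniform)
        _, h_s, _ = alpha_diversity(skewed)
        assert h_u >= h_s
        assert h_u == pytest.approx(math.log(10))


def spearman_rank_formula(x, y):
    """Independent oracle: classic 1 - 6*sum(d^2)/(n(n^2-1)), tie-free."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(((rx - ry) ** 2).sum())
    return 1 - 6 * d2 / (n * (n**2 - 1))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 55, 70])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720)  # only the two extreme orderings

    def test_constant_input_is_nan(self):
        rho, p = spearman([1, 2, 3, 4, 5, 6], [2, 2, 2, 2, 2, 2])
        assert math.isnan(rho) and math.isnan(p)

    def test_matches_rank_formula_for_all_tie_free_n6_swaps(self):
        x = np.arange(6, dtype=float)
        for i, j in itertools.combinations(range(6), 2):
            y = x.copy()
            y[i], y[j] = y[j], y[i]
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_rank_formula(x, y))

    def test_matches_rank_formula_random_small_n(self, rng):
        for n in (4, 5, 6, 7):
            x = rng.uniform(size=n)
            y = rng.uniform(size=n)
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(spearman_rank_formula(x, y))

    def test_exact_p_is_valid_under_the_null(self, rng):
        """P(p <= alpha) <= alpha for the exact permutation p."""
        alpha = 0.05
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            _, p = spearman(rng.uniform(size=6), rng.uniform(size=6))
            hits += p < alpha
        # binomial 99% upper bound around alpha
        bound = alpha + 2.6 * math.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= bound


def _matrix(rows, samples):
    return pd.DataFrame(rows, index=samples).T


class TestScreenPairs:
    SAMPLES = ["s1", "s2", "s3", "s4", "s5", "s6"]

    def _env(self):
        env = pd.DataFrame(
            {
                v: np.linspace(1, 6, 6) + i * 0.1
                for i, v in enumerate(
                    ["pH", "EC", "TN", "NH4_N", "NO3_N", "TP", "TOC", "WT"]
                )
            },
            index=self.SAMPLES,
        )
        return env

    def test_planted_negative_association_is_flagged(self):
        virus = _matrix({"v1": [64, 32, 16, 8, 4, 2]}, self.SAMPLES)
        host = _matrix({"h1": [600, 500, 400, 30, 20, 10]}, self.SAMPLES)
        links = [VirusHostLink("v1", "h1")]
        out = screen_pairs(virus, host, links, self._env(), variables=("NH4_N",))
        row = out.iloc[0]
        assert row["flagged"]
        assert row["rho_virus"] == pytest.approx(-1.0)
        sc = sign_counts(out)
        assert sc.loc[0, "negative"] == 1 and sc.loc[0, "positive"] == 0

    def test_inconsistent_pair_not_reported(self):
        virus = _matrix({"v1": [5, 5, 5, 5, 5, 5]}, self.SAMPLES)  # rho undefined
        host = _matrix({"h1": [600, 500, 400, 30, 20, 10]}, self.SAMPLES)
        out = screen_pairs(
            virus, host, [VirusHostLink("v1", "h1")], self._env(), variables=("NH4_N",)
        )
        assert not out["flagged"].any()

    def test_sample_order_invariance(self, rng):
        virus = _matrix({"v1": rng.uniform(size=6)}, self.SAMPLES)
        host = _matrix({"h1": rng.uniform(size=6)}, self.SAMPLES)
        env = self._env()
        out1 = screen_pairs(virus, host, [VirusHostLink("v1", "h1")], env)
        shuffled = env.sample(frac=1, random_state=0)
        out2 = screen_pairs(
            virus[list(reversed(self.SAMPLES))],
            host,
            [VirusHostLink("v1", "h1")],
            shuffled,
        )
        assert np.allclose(out1["rho_virus"], out2["rho_virus"], equal_nan=True)

    def test_too_few_shared_samples_is_an_error(self):
        virus = _matrix({"v1": [1, 2]}, ["s1", "s2"])
        host = _matrix({"h1": [1, 2]}, ["s1", "s2"])
        with pytest.raises(ValueError, match="at least 3"):
            screen_pairs(
                virus, host, [VirusHostLink("v1", "h1")], self._env().iloc[:2]
            )
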