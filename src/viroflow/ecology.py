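"""Alpha diversity and virus-host-environment correlation screening.

The study design behind this module is small-n ecology: six sediment
samples, a TPM matrix per community, and eight physicochemical
variables.  Spearman correlations at n = 6 get an exact permutation
p-value (all 720 rank permutations) because the t-approximation is
unreliable there; a virus-host pair is flagged for a variable only when
*both* the virus and its host correlate strongly (|rho| >= 0.80,
p < 0.05) with consistent signs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ENV_VARIABLES, VirusHostLink

RHO_CUT = 0.80
P_CUT = 0.05
MAX_EXACT_N = 8


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(tpm_column: Sequence[float]) -> tuple[int, float, float]:
    """Richness, Shannon index and Pielou evenness of one sample.

    Richness counts features with TPM > 0; Shannon H' = -sum p_i ln p_i
    over the positive features; evenness = H'/ln(richness), undefined
    (nan) when richness <= 1.  Natural log by default (see
    :func:`shannon` for the base-2 variant).
    """
    x = np.asarray(tpm_column, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance values")
    pos = x[x > 0]
    richness = int(pos.size)
    if richness == 0:
        return 0, 0.0, float("nan")
    p = pos / pos.sum()
    h = float(-(p * np.log(p)).sum())
    evenness = h / math.log(richness) if richness > 1 else float("nan")
    return richness, h, evenness


def shannon(tpm_column: Sequence[float], base: float = math.e) -> float:
    """Shannon index with a configurable log base."""
    _, h, _ = alpha_diversity(tpm_column)
    return h / math.log(base)


def alpha_diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha diversity of a features x samples TPM matrix."""
    rows = []
    for sample in matrix.columns:
        r, h, e = alpha_diversity(matrix[sample].to_numpy())
        rows.append(
            {"sample_id": sample, "richness": r, "shannon": h, "evenness": e}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman with exact small-n permutation p
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(
    x: Sequence[float], y: Sequence[float], max_exact_n: int = MAX_EXACT_N
) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value at small n.

    rho is the Pearson correlation of mid-ranks.  For n <= ``max_exact_n``
    the two-sided p enumerates all n! permutations of the y ranks
    (counting |rho_perm| >= |rho_obs|); larger n falls back to the
    t-approximation.  A constant input makes rho undefined -> (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    rxc = (rx - rx.mean()) / sx
    ryc = (ry - ry.mean()) / sy
    rho = float(rxc @ ryc) / n

    if n <= max_exact_n:
        perms = _perm_matrix(n)
        rho_null = (ryc[perms] @ rxc) / n
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        res = stats.spearmanr(x, y)
        p = float(res.pvalue)
    return rho, p


# ---------------------------------------------------------------------------
# pair screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairCorrelation:
    votu_id: str
    host_id: str
    variable: str
    rho_virus: float
    p_virus: float
    rho_host: float
    p_host: float
    consistent: bool
    flagged: bool


def screen_pairs(
    virus_tpm: pd.DataFrame,
    host_tpm: pd.DataFrame,
    links: Iterable[VirusHostLink] | pd.DataFrame,
    env: pd.DataFrame,
    variables: Sequence[str] = ENV_VARIABLES,
    rho_cut: float = RHO_CUT,
    p_cut: float = P_CUT,
) -> pd.DataFrame:
    """Correlate every linked virus-host pair with each environment variable.

    ``virus_tpm`` / ``host_tpm`` are feature x sample matrices;
    ``env`` is indexed by sample with one column per variable.  Samples
    are intersected and ordered identically before correlating, so the
    result is invariant to input sample order.  A pair/variable row is
    ``flagged`` when both correlations reach |rho| >= ``rho_cut`` with
    p < ``p_cut`` and agree in sign.
    """
    if isinstance(links, pd.DataFrame):
        pairs = list(zip(links["votu_id"], links["host_genome_id"]))
    else:
        pairs = [(l.votu_id, l.host_genome_id) for l in links]

    samples = sorted(set(virus_tpm.columns) & set(host_tpm.columns) & set(env.index))
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples to correlate")

    rows = []
    for votu_id, host_id in pairs:
        v = virus_tpm.loc[votu_id, samples].to_numpy(dtype=float)
        h = host_tpm.loc[host_id, samples].to_numpy(dtype=float)
        for var in variables:
            e = env.loc[samples, var].to_numpy(dtype=float)
            rho_v, p_v = spearman(v, e)
            rho_h, p_h = spearman(h, e)
            consistent = (
                not math.isnan(rho_v)
                and not math.isnan(rho_h)
                and np.sign(rho_v) == np.sign(rho_h)
                and np.sign(rho_v) != 0
            )
            flagged = bool(
                consistent
                and abs(rho_v) >= rho_cut
                and abs(rho_h) >= rho_cut
                and p_v < p_cut
                and p_h < p_cut
            )
            rows.append(
                PairCorrelation(
                    votu_id, host_id, var, rho_v, p_v, rho_h, p_h, consistent, flagged
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def sign_counts(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable counts of flagged pairs, split by correlation sign."""
    flagged = pair_table[pair_table["flagged"]]
    rows = []
    for var, group in flagged.groupby("variable"):
        rows.append(
            {
                "variable": var,
                "negative": int((group["rho_virus"] < 0).sum()),
                "positive": int((group["rho_virus"] > 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "negative", "positive"])
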