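"""Lytic / lysogenic lifestyle calling from four evidence streams.

Per-method calls:

* CheckV — lysogenic when a provirus boundary was detected, otherwise
  silent (an intact genome is not evidence of a lytic lifestyle).
* Gene annotation — lysogenic when any protein annotation mentions a
  lysogeny marker (integrase, invertase, serine recombinase,
  transposase, CI/Cro repressor, parA/parB), otherwise silent.
* VIBRANT — its lytic/lysogenic call taken verbatim.
* BACPHLIP — lysogenic when the temperate probability is >= 0.9, lytic
  when the virulent probability (1 - temperate) is >= 0.9, else silent.

Consensus: a label called by at least ``min_agree`` methods (default 2)
wins by agreement; otherwise conflicts are resolved by the sequential
priority CheckV > annotation > VIBRANT > BACPHLIP.  A single caller
decides alone; no caller at all leaves the vOTU undetermined.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LYTIC = "lytic"
LYSOGENIC = "lysogenic"
UNDETERMINED = "undetermined"
NO_CALL = "no-call"

#: Method priority for conflict resolution, highest first.
METHOD_PRIORITY = ("checkv", "annotation", "vibrant", "bacphlip")

#: Annotation keywords that mark a provirus / lysogeny module.
LYSOGENY_KEYWORDS = (
    "integrase",
    "invertase",
    "serine recombinase",
    "transposase",
    "ci repressor",
    "cro repressor",
    "para",
    "parb",
)

BACPHLIP_MIN_SCORE = 0.9


@dataclass(frozen=True)
class LifestyleEvidence:
    votu_id: str
    checkv_provirus: Optional[bool] = None
    marker_genes: tuple[str, ...] = ()
    vibrant_call: Optional[str] = None  # "lytic" / "lysogenic" or None
    bacphlip_temperate_score: Optional[float] = None


@dataclass(frozen=True)
class LifestyleCall:
    votu_id: str
    per_method: Mapping[str, str]
    final: str
    resolved_by: str  # "agreement", "priority" or "none"


def _matches_keyword(description: str, word_boundary: bool) -> bool:
    text = description.lower()
    for kw in LYSOGENY_KEYWORDS:
        if word_boundary:
            if re.search(rf"\b{re.escape(kw)}\b", text):
                return True
        elif kw in text:
            return True
    return False


def call_methods(
    ev: LifestyleEvidence, word_boundary: bool = False
) -> dict[str, str]:
    """Per-method lifestyle calls; silent methods report ``no-call``."""
    calls: dict[str, str] = {}

    if ev.checkv_provirus is None:
        calls["checkv"] = NO_CALL
    else:
        calls["checkv"] = LYSOGENIC if ev.checkv_provirus else NO_CALL

    if any(_matches_keyword(d, word_boundary) for d in ev.marker_genes):
        calls["annotation"] = LYSOGENIC
    else:
        calls["annotation"] = NO_CALL

    if ev.vibrant_call in (LYTIC, LYSOGENIC):
        calls["vibrant"] = ev.vibrant_call
    else:
        calls["vibrant"] = NO_CALL

    score = ev.bacphlip_temperate_score
    if score is None:
        calls["bacphlip"] = NO_CALL
    elif score >= BACPHLIP_MIN_SCORE:
        calls["bacphlip"] = LYSOGENIC
    elif (1.0 - score) >= BACPHLIP_MIN_SCORE:
        calls["bacphlip"] = LYTIC
    else:
        calls["bacphlip"] = NO_CALL

    return calls


def consensus(
    calls: Mapping[str, str], votu_id: str = "", min_agree: int = 2
) -> LifestyleCall:
    """Combine per-method calls into one final lifestyle.

    Methods mapped to ``no-call`` (or absent from ``calls``) carry no
    vote.  A label reaching ``min_agree`` votes — and strictly more votes
    than the other label — wins by agreement; every other situation with
    at least one caller falls back to the priority order.
    """
    votes = {
        m: calls.get(m, NO_CALL)
        for m in METHOD_PRIORITY
        if calls.get(m, NO_CALL) in (LYTIC, LYSOGENIC)
    }
    if not votes:
        return LifestyleCall(votu_id, dict(calls), UNDETERMINED, "none")

    n_lytic = sum(1 for v in votes.values() if v == LYTIC)
    n_lyso = sum(1 for v in votes.values() if v == LYSOGENIC)
    if n_lytic >= min_agree and n_lytic > n_lyso:
        return LifestyleCall(votu_id, dict(calls), LYTIC, "agreement")
    if n_lyso >= min_agree and n_lyso > n_lytic:
        return LifestyleCall(votu_id, dict(calls), LYSOGENIC, "agreement")

    # priority fallback: the highest-priority calling method decides
    for m in METHOD_PRIORITY:
        if m in votes:
            return LifestyleCall(votu_id, dict(calls), votes[m], "priority")
    raise AssertionError("unreachable")


def call_lifestyles(
    evidence: Iterable[LifestyleEvidence],
    min_agree: int = 2,
    word_boundary: bool = False,
) -> dict[str, LifestyleCall]:
    """Full per-vOTU lifestyle calling from evidence records."""
    out: dict[str, LifestyleCall] = {}
    for ev in evidence:
        calls = call_methods(ev, word_boundary=word_boundary)
        out[ev.votu_id] = consensus(calls, votu_id=ev.votu_id, min_agree=min_agree)
    return out


def lifestyle_summary(
    finals: Mapping[str, str],
    presence: pd.DataFrame,
) -> tuple[pd.DataFrame, float, float]:
    """Per-sample lifestyle proportions and a lytic-vs-lysogenic test.

    ``finals`` maps vOTU -> final lifestyle; ``presence`` is a boolean
    vOTU x sample frame (e.g. TPM > 0).  For each sample the proportions
    of lytic / lysogenic / undetermined vOTUs among those present are
    computed, and the per-sample lytic and lysogenic proportion vectors
    are compared with a Welch two-tailed t test.  When the statistic is
    undefined (zero variance in both vectors) the result is ``nan`` —
    except for identical vectors, which report t = 0, p = 1.
    """
    rows = []
    for sample in presence.columns:
        present = [v for v in presence.index if presence.loc[v, sample]]
        n = len(present)
        row = {"sample_id": sample, "n_present": n}
        for label in (LYTIC, LYSOGENIC, UNDETERMINED):
            k = sum(1 for v in present if finals.get(v, UNDETERMINED) == label)
            row[label] = k / n if n else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)

    a = df[LYTIC].to_numpy(dtype=float)
    b = df[LYSOGENIC].to_numpy(dtype=float)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # near-constant proportion vectors trip scipy's precision warning;
        # the degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(t):
        # zero variance in both vectors: the statistic is undefined unless
        # the vectors are identical, in which case there is no difference
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = np.nan, np.nan
    return df, float(t), float(p)
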