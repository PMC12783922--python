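"""TPM abundance matrices and transcriptional activity calls.

Counts arrive per feature (vOTU, MAG or AMG) per sample together with
the fraction of the feature covered by reads.  TPM is computed per
sample over features passing the covered-fraction gate (default 10% for
metagenome streams; transcript streams for AMGs use no gate): failing
features are excluded from the normalisation and report 0.  A feature is
transcriptionally active when its transcript TPM exceeds zero in any
sample.  Transcript counts are expected to be pre-filtered to mapping
quality >= 30 upstream; this module records that contract but does not
re-derive it.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MIN_COVERED_FRACTION = 0.10
TPM_SCALE = 1e6


def sample_names(counts: pd.DataFrame) -> list[str]:
    """Sample names encoded in ``count_<sample>`` columns."""
    return [c[len("count_") :] for c in counts.columns if c.startswith("count_")]


def tpm(
    counts: pd.DataFrame,
    min_covered_fraction: float = MIN_COVERED_FRACTION,
) -> pd.DataFrame:
    """TPM matrix (features x samples) from a per-sample count table.

    ``counts`` needs columns ``feature_id``, ``length_bp`` and, per
    sample, ``count_<sample>`` and ``covfrac_<sample>``.  Per sample,
    features with covered fraction >= the gate contribute their
    length-normalised read rate to the denominator and receive
    ``rate / sum(rates) * 1e6``; gated-out features receive 0.  A sample
    with no passing reads yields an all-zero column.
    """
    if "feature_id" not in counts.columns or "length_bp" not in counts.columns:
        raise ValueError("count table needs feature_id and length_bp columns")
    lengths = counts["length_bp"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        bad = counts.loc[lengths <= 0, "feature_id"].tolist()
        raise ValueError(f"non-positive feature length(s): {bad}")

    out = {}
    for sample in sample_names(counts):
        c = counts[f"count_{sample}"].to_numpy(dtype=float)
        if (c < 0).any():
            raise ValueError(f"negative counts in sample {sample}")
        cf_col = f"covfrac_{sample}"
        if cf_col in counts.columns:
            cf = counts[cf_col].to_numpy(dtype=float)
        else:
            cf = np.ones_like(c)
        passing = cf >= min_covered_fraction
        rate = np.where(passing, c / lengths, 0.0)
        total = rate.sum()
        out[sample] = rate / total * TPM_SCALE if total > 0 else np.zeros_like(rate)
    return pd.DataFrame(out, index=pd.Index(counts["feature_id"], name="feature_id"))


def activity(matrix: pd.DataFrame) -> pd.Series:
    """Active flag per feature: TPM > 0 in at least one sample."""
    return (matrix > 0).any(axis=1).rename("active")


def amg_metagenome_abundance(
    amg_votus: Mapping[str, str] | pd.DataFrame,
    votu_matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Assign each AMG the TPM row of its parent vOTU.

    AMG metagenomic abundance is proxied by the carrying vOTU's
    abundance so that host-derived reads over the gene body cannot
    inflate it.  ``amg_votus`` maps gene_id -> votu_id (or is a frame
    with those columns).  An AMG pointing at a vOTU absent from the
    matrix is a referential-integrity error.
    """
    if isinstance(amg_votus, pd.DataFrame):
        mapping = dict(zip(amg_votus["gene_id"], amg_votus["votu_id"]))
    else:
        mapping = dict(amg_votus)
    missing = sorted(set(mapping.values()) - set(votu_matrix.index))
    if missing:
        raise KeyError(f"AMG parent vOTU(s) not in abundance matrix: {missing}")
    rows = [votu_matrix.loc[votu] for votu in mapping.values()]
    out = pd.DataFrame(rows)
    out.index = pd.Index(list(mapping.keys()), name="gene_id")
    return out
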