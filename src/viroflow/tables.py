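"""Tab-separated table I/O with per-tool dialect validation.

Every upstream tool output consumed by the pipeline (predictor score
tables, taxonomy summaries, lifestyle evidence, DRAM-v style annotation
tables, count tables, environment tables) travels as a TSV with a named
header row.  A dialect declares the mandatory columns and their types;
reading validates and types them, writing emits them first, and reading
back a written table reproduces the rows field-for-field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd


class TableFormatError(ValueError):
    """A table is missing a mandatory column or names an unknown dialect."""


@dataclass(frozen=True)
class TableDialect:
    name: str
    columns: Mapping[str, str]  # column -> {"str", "int", "float"}
    allow_extra: bool = False


_DIALECTS: dict[str, TableDialect] = {}


def register_dialect(dialect: TableDialect) -> None:
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> TableDialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise TableFormatError(f"unknown table dialect: {name!r}") from None


def list_dialects() -> list[str]:
    return sorted(_DIALECTS)


for _d in [
    # predictor hit tables (viral-contig screening)
    TableDialect("genomad_hits", {"contig_id": "str", "length_bp": "int", "score": "float"}),
    TableDialect("virsorter2_hits", {"contig_id": "str", "length_bp": "int", "score": "float"}),
    TableDialect(
        "deepvirfinder_hits",
        {"contig_id": "str", "length_bp": "int", "score": "float", "p_value": "float"},
    ),
    TableDialect("vibrant_hits", {"contig_id": "str", "length_bp": "int"}),
    # CheckV quality / provirus table
    TableDialect(
        "checkv_quality",
        {"contig_id": "str", "length_bp": "int", "quality_tier": "str", "provirus": "str"},
    ),
    # taxonomy tool summaries (lineage serialized as rank=name;...)
    TableDialect(
        "vcontact2_tax",
        {
            "votu_id": "str",
            "lineage": "str",
            "protein_total": "int",
            "protein_assigned_to_family": "int",
            "min_bitscore": "float",
        },
    ),
    TableDialect(
        "blastn_tax",
        {
            "votu_id": "str",
            "lineage": "str",
            "pct_identity": "float",
            "pct_coverage": "float",
            "hit_rank": "int",
            "bitscore": "float",
            "evalue": "float",
        },
    ),
    TableDialect("genomad_tax", {"votu_id": "str", "lineage": "str"}, allow_extra=True),
    TableDialect("phagcn2_tax", {"votu_id": "str", "lineage": "str", "score": "float"}),
    TableDialect(
        "vpfclass_tax",
        {"votu_id": "str", "lineage": "str", "membership_ratio": "float", "confidence": "float"},
    ),
    # lifestyle evidence
    TableDialect("vibrant_lifestyle", {"votu_id": "str", "call": "str"}),
    TableDialect("bacphlip_scores", {"votu_id": "str", "temperate_score": "float"}),
    TableDialect("gene_annotations", {"votu_id": "str", "gene_id": "str", "description": "str"}),
    # DRAM-v style AMG candidate table
    TableDialect(
        "dramv_amgs",
        {
            "gene_id": "str",
            "votu_id": "str",
            "ko_id": "str",
            "auxiliary_score": "int",
            "amg_flags": "str",
            "gene_index": "int",
            "annotation": "str",
        },
    ),
    # gene neighborhood categories for flank inspection
    TableDialect(
        "gene_neighborhood",
        {"amg_gene_id": "str", "gene_index": "int", "category": "str"},
    ),
    # abundance inputs: feature_id, length, then count_<sample>/covfrac_<sample>
    TableDialect("feature_counts", {"feature_id": "str", "length_bp": "int"}, allow_extra=True),
    TableDialect("tpm_matrix", {"feature_id": "str"}, allow_extra=True),
    # links, environment, vOTU output table
    TableDialect(
        "virus_host_links",
        {"votu_id": "str", "host_genome_id": "str", "host_lineage": "str", "confidence": "float"},
    ),
    TableDialect(
        "environment",
        {
            "sample_id": "str",
            "pH": "float",
            "EC": "float",
            "TN": "float",
            "NH4_N": "float",
            "NO3_N": "float",
            "TP": "float",
            "TOC": "float",
            "WT": "float",
        },
    ),
    TableDialect(
        "votus",
        {
            "votu_id": "str",
            "representative": "str",
            "members": "str",
            "length_bp": "int",
        },
        allow_extra=True,
    ),
]:
    register_dialect(_d)


_PANDAS_DTYPES = {"str": "string", "int": "int64", "float": "float64"}


def _coerce(df: pd.DataFrame, dialect: TableDialect) -> pd.DataFrame:
    missing = [c for c in dialect.columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"table dialect {dialect.name!r}: missing mandatory column(s) "
            + ", ".join(repr(c) for c in missing)
        )
    if not dialect.allow_extra:
        df = df[list(dialect.columns)]
    out = df.copy()
    for col, kind in dialect.columns.items():
        try:
            out[col] = out[col].astype(_PANDAS_DTYPES[kind])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(
                f"table dialect {dialect.name!r}: column {col!r} is not {kind}: {exc}"
            ) from exc
    if "str" in dialect.columns.values():
        pass
    # strings come back as pandas 'string' dtype; normalise NA to empty
    for col, kind in dialect.columns.items():
        if kind == "str":
            out[col] = out[col].fillna("")
    return out


def read_table(path: str | Path, dialect: str) -> pd.DataFrame:
    """Read a TSV in the named dialect, validating mandatory columns."""
    d = get_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype="string")
    df = _coerce(df, d)
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path, dialect: str) -> None:
    """Write a TSV in the named dialect (mandatory columns first)."""
    d = get_dialect(dialect)
    missing = [c for c in d.columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"table dialect {d.name!r}: missing mandatory column(s) "
            + ", ".join(repr(c) for c in missing)
        )
    ordered = list(d.columns) + [c for c in df.columns if c not in d.columns]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[ordered].to_csv(path, sep="\t", index=False)
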