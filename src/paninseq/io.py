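"""Readers and writers for the plain-text formats used across the pipeline.

Tables are TSV throughout; intervals are BED (3 or 6 column, 0-based
half-open); gene sets are GMT. Matrix TSVs carry the feature id in the
first column and one column per sample.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .intervals import BED_COLUMNS
from .util import InputError

READ_TABLE_COLUMNS = [
    "sample_id",
    "gene_id",
    "chrom",
    "position",
    "strand",
    "umi",
    "region_flag",
]


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"umi": str})
    missing = [c for c in READ_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"read table missing required columns: {missing}")
    return df


def write_read_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_design_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Design table: columns ``sample``, ``group`` and optionally ``factor2``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "group" not in df.columns:
        raise InputError("design table requires columns 'sample' and 'group'")
    return df.set_index("sample")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: line {lineno}: expected >=3 BED fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise InputError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise InputError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = fields[5] if len(fields) > 5 else None
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end))]
            name = getattr(row, "name", None)
            score = getattr(row, "score", None)
            strand = getattr(row, "strand", None)
            if name is not None or score is not None or strand is not None:
                fields.append("." if name is None or pd.isna(name) else str(name))
            if score is not None or strand is not None:
                fields.append("." if score is None or pd.isna(score) else format(score, "g"))
            if strand is not None and not pd.isna(strand):
                fields.append(str(strand))
            fh.write("\t".join(fields) + "\n")


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
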