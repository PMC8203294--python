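"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention. Two intervals overlap iff they share at least one base;
abutting half-open intervals do not overlap.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .util import InputError

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None


def validate_interval(iv: GenomicInterval) -> None:
    if iv.start < 0:
        raise InputError(f"negative start in interval {iv}")
    if not iv.start < iv.end:
        raise InputError(f"start must be < end in interval {iv}")


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 base on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    out = []
    for row in df[cols].itertuples(index=False):
        iv = GenomicInterval(
            str(row.chrom),
            int(row.start),
            int(row.end),
            getattr(row, "name", None),
            getattr(row, "score", None),
            getattr(row, "strand", None),
        )
        validate_interval(iv)
        out.append(iv)
    return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping (not merely abutting) intervals per chromosome.

    Returns a sorted frame with columns chrom/start/end and a synthetic
    ``name`` of the form ``chrom:start-end``.
    """
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name"])
    merged_rows = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_start = cur_end = None
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            if cur_start is None:
                cur_start, cur_end = int(s), int(e)
            elif s < cur_end:  # strict: abutting intervals stay separate
                cur_end = max(cur_end, int(e))
            else:
                merged_rows.append((chrom, cur_start, cur_end))
                cur_start, cur_end = int(s), int(e)
        merged_rows.append((chrom, cur_start, cur_end))
    out = pd.DataFrame(merged_rows, columns=["chrom", "start", "end"])
    out["name"] = [f"{c}:{s}-{e}" for c, s, e in merged_rows]
    return out.reset_index(drop=True)


def overlaps_any(iv: GenomicInterval, peaks: pd.DataFrame) -> bool:
    """True iff ``iv`` overlaps at least one interval in a BED-like frame."""
    if peaks.empty:
        return False
    sub = peaks[peaks["chrom"] == iv.chrom]
    if sub.empty:
        return False
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    return bool(np.any((starts < iv.end) & (iv.start < ends)))
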