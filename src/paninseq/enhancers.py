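"""Cross-cell-line consensus enhancer calling.

Candidate differential distal peaks are promoted to functional
enhancers when they overlap the histone enhancer marks (H3K27ac,
H3K4me1) in at least a minimum number of cell lines that highly express
the gene of interest. Cell lines are classified high/low by expression
thresholds; a line contributes at most one vote per candidate no matter
how many of its peaks overlap. Overlap with marks in low-expression
lines is reported as a diagnostic only, never used to filter.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .intervals import GenomicInterval, intervals_overlap, overlaps_any  # noqa: F401
from .util import ConfigurationError, InputError


def classify_lines_by_expression(
    values: Mapping[str, float] | pd.Series,
    high_thr: float = 10.0,
    low_thr: float = 0.5,
) -> pd.DataFrame:
    """Classify cell lines by expression of the gene of interest.

    RPKM-scale values strictly above ``high_thr`` are ``high``, strictly
    below ``low_thr`` are ``low``, anything between is ``unclassified``.
    """
    values = pd.Series(values, dtype=float)
    if (values < 0).any():
        raise InputError("negative expression values")
    cls = pd.Series("unclassified", index=values.index, dtype=object)
    cls[values > high_thr] = "high"
    cls[values < low_thr] = "low"
    out = pd.DataFrame({"expression": values, "class": cls})
    out.attrs["high_thr"] = high_thr
    out.attrs["low_thr"] = low_thr
    return out


def _line_supports(
    candidate: GenomicInterval,
    marks: Mapping[str, pd.DataFrame],
    mode: str,
) -> bool:
    """Does one line's histone landscape support a candidate?

    ``union`` mode (default): overlap with either mark suffices.
    ``intersection`` mode: the candidate must overlap a peak of every
    mark present for the line.
    """
    hits = [overlaps_any(candidate, peaks) for peaks in marks.values()]
    if not hits:
        return False
    return any(hits) if mode == "union" else all(hits)


def support_counts(
    candidates: pd.DataFrame,
    landscape: Mapping[str, Mapping[str, pd.DataFrame]],
    mode: str = "union",
) -> pd.Series:
    """Number of lines whose marks support each candidate (<= 1 vote per line)."""
    if mode not in ("union", "intersection"):
        raise InputError(f"unknown overlap mode {mode!r}")
    out = []
    for row in candidates.itertuples(index=False):
        iv = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        out.append(sum(_line_supports(iv, marks, mode) for marks in landscape.values()))
    index = (candidates["name"]
             if "name" in candidates.columns and candidates["name"].notna().all()
             else candidates.index)
    return pd.Series(out, index=index, name="support")


def consensus_enhancers(
    candidates: pd.DataFrame,
    landscape: Mapping[str, Mapping[str, pd.DataFrame]],
    min_lines: int = 4,
    mode: str = "union",
) -> pd.DataFrame:
    """Retain candidates supported by marks in >= ``min_lines`` high lines.

    ``landscape`` maps line name -> mark name -> BED-like peak frame and
    must already be restricted to the high-expression lines. Returns
    the retained candidates with the supporting-line count in the
    ``score`` column.
    """
    if len(landscape) == 0:
        raise ConfigurationError("no high-expression lines provided")
    if len(landscape) < min_lines:
        raise ConfigurationError(
            f"{len(landscape)} line(s) present but min_lines={min_lines}"
        )
    support = support_counts(candidates, landscape, mode=mode)
    retained = candidates.loc[support.to_numpy() >= min_lines].copy()
    retained["score"] = support[support >= min_lines].to_numpy()
    return retained.reset_index(drop=True)


def low_line_check(
    retained: pd.DataFrame,
    landscape: Mapping[str, Mapping[str, pd.DataFrame]],
    mode: str = "union",
) -> pd.Series:
    """Diagnostic: per retained enhancer, the number of low-expression
    lines whose marks overlap it. Reported only — a called enhancer is
    never revoked on low-line evidence."""
    if retained.empty:
        return pd.Series(dtype=int, name="low_support")
    return support_counts(retained, landscape, mode=mode).rename("low_support")
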