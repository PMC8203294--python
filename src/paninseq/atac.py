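"""Chromatin-accessibility analytics.

Fragments are counted into a merged union peak set; replicate agreement
is summarized with Spearman correlation of per-peak counts; peaks are
classified as promoter or distal against a strand-aware window around
annotated transcription start sites; differential accessibility reuses
the moderated count test; and the link between expression and
accessibility changes is quantified per element class with a rank-sum
comparison of fold changes and a Fisher exact association test.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import diffexpr
from .intervals import merge_intervals
from .stats import fisher_exact_2x2
from .util import InputError


def count_fragments_in_peaks(
    fragments_by_sample: Mapping[str, pd.DataFrame],
    peaks: pd.DataFrame,
) -> pd.DataFrame:
    """Count fragments overlapping each union peak, per sample.

    Peaks are merged first so the union set is non-overlapping; a
    fragment counts toward every peak it overlaps by >= 1 base (a
    fragment spanning two merged peaks increments both). Returns a
    peaks x samples integer matrix indexed by peak name.
    """
    union = merge_intervals(peaks)
    counts = pd.DataFrame(
        0, index=union["name"], columns=list(fragments_by_sample), dtype=int
    )
    by_chrom = {chrom: sub.reset_index() for chrom, sub in union.groupby("chrom")}
    for sample, frags in fragments_by_sample.items():
        col = np.zeros(len(union), dtype=int)
        for chrom, sub in frags.groupby("chrom"):
            if chrom not in by_chrom:
                continue
            psub = by_chrom[chrom]
            starts = psub["start"].to_numpy()
            ends = psub["end"].to_numpy()
            fs = sub["start"].to_numpy()
            fe = sub["end"].to_numpy()
            # peaks are sorted and disjoint: the peaks overlapped by a
            # fragment form the contiguous slice [lo, hi)
            lo = np.searchsorted(ends, fs, side="right")
            hi = np.searchsorted(starts, fe, side="left")
            delta = np.zeros(len(psub) + 1, dtype=int)
            valid = hi > lo
            np.add.at(delta, lo[valid], 1)
            np.add.at(delta, hi[valid], -1)
            col[psub["index"].to_numpy()] += np.cumsum(delta[:-1])
        counts[sample] = col
    counts.index.name = "peak"
    return counts


def spearman_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Spearman correlation of per-peak counts."""
    if counts.shape[1] < 2:
        raise InputError("need >= 2 samples for replicate correlation")
    constant = counts.nunique(axis=0) <= 1
    if constant.any():
        warnings.warn(
            f"constant count column(s) {list(counts.columns[constant])}: "
            "correlation undefined, reported as NaN",
            stacklevel=2,
        )
    rho = counts.corr(method="spearman")
    np.fill_diagonal(rho.values, 1.0)
    rho.loc[constant, :] = np.nan
    rho.loc[:, constant] = np.nan
    for c in counts.columns[constant]:
        rho.loc[c, c] = np.nan
    return rho


def classify_peaks(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 100,
) -> pd.Series:
    """Classify each peak as ``promoter`` or ``distal``.

    A peak is a promoter iff it overlaps the strand-oriented window
    [TSS - upstream, TSS + downstream) of at least one gene; on the
    minus strand the window is mirrored in genomic coordinates to
    [TSS - downstream, TSS + upstream). Peaks on chromosomes absent
    from the annotation are distal (with a warning). ``tss`` columns:
    gene, chrom, tss, strand; the first TSS listed per gene wins.
    """
    if tss["gene"].duplicated().any():
        warnings.warn("duplicate TSS entries; first listed per gene wins", stacklevel=2)
        tss = tss.drop_duplicates(subset="gene", keep="first")
    windows: dict[str, list[tuple[int, int]]] = {}
    for row in tss.itertuples(index=False):
        if row.strand == "-":
            w = (int(row.tss) - downstream, int(row.tss) + upstream)
        else:
            w = (int(row.tss) - upstream, int(row.tss) + downstream)
        windows.setdefault(str(row.chrom), []).append(w)

    missing_chroms = set(peaks["chrom"].astype(str)) - set(windows)
    if missing_chroms:
        warnings.warn(
            f"peak chromosome(s) {sorted(missing_chroms)} absent from the TSS "
            "annotation; classified as distal",
            stacklevel=2,
        )
    labels = []
    for row in peaks.itertuples(index=False):
        cls = "distal"
        for ws, we in windows.get(str(row.chrom), ()):
            if row.start < we and ws < row.end:
                cls = "promoter"
                break
        labels.append(cls)
    index = peaks["name"] if "name" in peaks.columns and peaks["name"].notna().all() else peaks.index
    return pd.Series(labels, index=index, name="peak_class")


def diff_accessibility(
    counts: pd.DataFrame,
    design: pd.Series | pd.DataFrame,
    fdr_cutoff: float = 0.05,
    reference: str | None = None,
) -> pd.DataFrame:
    """Differential accessibility: the moderated two-group count test
    with peaks as features."""
    return diffexpr.test_two_group(counts, design, fdr_cutoff=fdr_cutoff,
                                   reference=reference)


def element_foldchange_by_deg_group(
    peak_results: pd.DataFrame,
    up_genes,
    down_genes,
    gene_to_elements: Mapping[str, list],
) -> tuple[dict[str, np.ndarray], float]:
    """Compare accessibility fold changes of elements of up- vs
    down-regulated genes.

    Each element (peak) linked to a DEG contributes its log2
    accessibility fold change to its gene's direction group; elements
    are treated independently (one value per gene-element link). The
    two distributions are compared with a two-sided Mann-Whitney U test
    (exact for small tie-free samples, normal approximation with tie
    correction otherwise).
    """
    groups: dict[str, list[float]] = {"up": [], "down": []}
    for direction, genes in (("up", up_genes), ("down", down_genes)):
        for g in genes:
            for elem in gene_to_elements.get(g, []):
                if elem in peak_results.index:
                    groups[direction].append(float(peak_results.loc[elem, "log2fc"]))
    if not groups["up"] or not groups["down"]:
        raise InputError("both DEG direction groups must map to >= 1 element")
    x, y = np.array(groups["up"]), np.array(groups["down"])
    if len(x) == 1 and len(y) == 1 and x[0] == y[0]:
        p = 1.0  # identical singletons: only one rank assignment
    else:
        p = float(sp_stats.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)
    return {"up": x, "down": y}, p


def deg_peak_association(
    deg_flags: pd.Series,
    peak_flags: pd.DataFrame,
    alternative: str = "two-sided",
) -> dict[str, dict]:
    """Association between being a DEG and having a differential peak.

    ``deg_flags``: boolean per gene. ``peak_flags``: boolean per gene,
    one column per element class (e.g. promoter / distal). For each
    class, builds the 2x2 contingency of DEG status vs differential
    peak status over the shared gene universe and computes the Fisher
    exact p. Degenerate margins give p = 1 with a warning.
    """
    if not deg_flags.index.equals(peak_flags.index):
        common = deg_flags.index.intersection(peak_flags.index)
        if len(common) == 0:
            raise InputError("DEG and peak flags share no genes")
        deg_flags = deg_flags.loc[common]
        peak_flags = peak_flags.loc[common]
    out = {}
    deg = deg_flags.astype(bool).to_numpy()
    for cls in peak_flags.columns:
        pk = peak_flags[cls].astype(bool).to_numpy()
        a = int(np.sum(deg & pk))
        b = int(np.sum(deg & ~pk))
        c = int(np.sum(~deg & pk))
        d = int(np.sum(~deg & ~pk))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            warnings.warn(f"degenerate margin for class {cls!r}; p = 1", stacklevel=2)
            p = 1.0
        else:
            p = fisher_exact_2x2(a, b, c, d, alternative=alternative)
        out[cls] = {"table": [[a, b], [c, d]], "pvalue": p}
    return out
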