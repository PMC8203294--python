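"""Single-lesion amplicon quantification.

Reads carry a unique molecular identifier (UMI, here an amplicon
barcode): PCR copies of one original molecule share the same barcode.
Quantification proceeds in three steps: keep exonic reads only, collapse
reads to molecules by an exact identity key that includes the mapping
position of the read, and scale deduplicated counts to amplicons per
million (APM). A final expression filter retains genes with APM above a
threshold in a minimum number of samples.

Position-aware collapsing means the identity key is
``(sample, gene, UMI, position)`` rather than ``(sample, gene, UMI)``:
two molecules of the same gene that happen to draw the same barcode are
still distinguished when their fragments map to different coordinates.
Collapsing is exact-match; no edit-distance merging of near-identical
barcodes is attempted.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .util import InputError

_VALID_UMI_CHARS = frozenset("ACGT")


def filter_exonic(reads: pd.DataFrame) -> pd.DataFrame:
    """Keep reads whose ``region_flag`` is ``exon``; order is preserved.

    Intronic and intergenic reads are dropped: expression quantification
    is defined over exonic sequence only.
    """
    if "region_flag" not in reads.columns:
        raise InputError("read table has no 'region_flag' column")
    if reads["region_flag"].isna().any():
        raise InputError("read table has missing region_flag values")
    return reads[reads["region_flag"] == "exon"].copy()


def collapse_umis(
    reads: pd.DataFrame,
    position_aware: bool = True,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse reads to deduplicated molecule counts (gene x sample).

    A molecule is one distinct identity key: ``(sample, gene, umi,
    position)`` when ``position_aware``, else ``(sample, gene, umi)``.
    The count for a gene/sample pair is the number of distinct keys.

    ``genes``/``samples`` optionally declare the full matrix axes so
    that pairs with no reads appear as explicit zeros (and an empty read
    table yields an all-zero matrix rather than an error).
    """
    if not reads.empty:
        umis = reads["umi"].astype(str)
        lengths = umis.str.len()
        if lengths.nunique() > 1:
            raise InputError("UMIs must have uniform length within a run")
        bad = ~umis.map(lambda u: set(u) <= _VALID_UMI_CHARS)
        if bad.any():
            raise InputError(
                f"malformed UMI characters in {int(bad.sum())} reads (expected A/C/G/T)"
            )

    key_cols = ["sample_id", "gene_id", "umi"]
    if position_aware:
        key_cols.append("position")

    if reads.empty:
        counts = pd.DataFrame()
    else:
        molecules = reads.drop_duplicates(subset=key_cols)
        counts = (
            molecules.groupby(["gene_id", "sample_id"], sort=True)
            .size()
            .unstack(fill_value=0)
        )

    gene_axis = genes if genes is not None else sorted(counts.index)
    sample_axis = samples if samples is not None else sorted(counts.columns)
    counts = counts.reindex(index=gene_axis, columns=sample_axis, fill_value=0)
    counts.index.name = "gene_id"
    counts.columns.name = "sample_id"
    return counts.astype(int)


def compute_apm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale molecule counts to amplicons per million per sample.

    ``apm[g, s] = counts[g, s] / total[s] * 1e6``; every column sums to
    one million. A sample with zero total has no defined APM and is
    reported as an error by name.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise InputError(f"zero-total sample column(s): {list(zero.index)}")
    return counts / totals * 1e6


def filter_expressed_genes(
    apm: pd.DataFrame, min_apm: float = 2.0, min_samples: int = 5
) -> list[str]:
    """Genes with APM strictly above ``min_apm`` in >= ``min_samples`` samples.

    The inequality is strict: APM exactly equal to the threshold does
    not count. Output preserves the input gene order.
    """
    if min_apm <= 0 or min_samples <= 0:
        raise InputError("thresholds must be positive")
    if min_samples > apm.shape[1]:
        warnings.warn(
            f"min_samples={min_samples} exceeds sample count {apm.shape[1]}; "
            "no gene can pass the filter",
            stacklevel=2,
        )
    passing = (apm > min_apm).sum(axis=1) >= min_samples
    return [g for g, ok in passing.items() if ok]
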