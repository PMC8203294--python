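"""Transcription-factor evidence tiering at candidate enhancer loci.

Each TF is observed through multiple ChIP-seq datasets, each from a
cell line classified high or low by expression of the gene of interest.
A dataset is "bound" when at least one of its binding events overlaps
at least one candidate locus. Per TF, the bound/unbound dataset counts
in high vs low lines form a 2x2 table; TFs are then tiered:

* ``preferential`` ("red"): enough datasets in both classes, Fisher
  exact p below alpha, and a higher bound fraction in high lines;
* ``majority`` ("blue"): too few datasets to test, but bound in more
  than half of the high-line datasets;
* ``minority`` ("black"): bound in more than 25% but at most 50% of
  the high-line datasets;
* ``excluded_not_expressed``: the TF is not expressed in the host cell
  line and is removed before any counting rule applies;
* ``unclassified``: everything else.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlaps_any
from .stats import fisher_exact_2x2
from .util import InputError

TIERS = ("preferential", "majority", "minority", "unclassified", "excluded_not_expressed")


def count_binding_datasets(
    records: pd.DataFrame,
    loci: pd.DataFrame,
    line_classes: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-TF contingency of bound/total datasets in high vs low lines.

    ``records`` columns: tf, dataset_id, cell_line, chrom, start, end
    (one row per binding event). ``loci`` is a BED-like frame of the
    candidate enhancer loci. Datasets from lines that are neither high
    nor low are excluded with a warning.
    """
    if loci.empty:
        raise InputError("no candidate loci")
    line_classes = dict(pd.Series(line_classes))
    known = records["cell_line"].map(lambda ln: line_classes.get(ln) in ("high", "low"))
    if (~known).any():
        dropped = sorted(records.loc[~known, "cell_line"].unique())
        warnings.warn(f"datasets from unclassified line(s) {dropped} excluded",
                      stacklevel=2)
        records = records[known]

    rows = []
    for (tf, dataset_id, cell_line), events in records.groupby(
        ["tf", "dataset_id", "cell_line"], sort=True
    ):
        bound = any(
            overlaps_any(GenomicInterval(str(r.chrom), int(r.start), int(r.end)), loci)
            for r in events.itertuples(index=False)
        )
        rows.append((tf, dataset_id, line_classes[cell_line], bound))
    per_dataset = pd.DataFrame(rows, columns=["tf", "dataset_id", "class", "bound"])

    out = []
    for tf, sub in per_dataset.groupby("tf", sort=True):
        hi = sub[sub["class"] == "high"]
        lo = sub[sub["class"] == "low"]
        out.append(
            {
                "tf": tf,
                "bound_high": int(hi["bound"].sum()),
                "total_high": len(hi),
                "bound_low": int(lo["bound"].sum()),
                "total_low": len(lo),
            }
        )
    return pd.DataFrame(out).set_index("tf")


def assign_tiers(
    contingencies: pd.DataFrame,
    host_expression: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
    testable_min: int = 3,
    expression_threshold: float = 1.0,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Assign one tier per TF, applying the rules in fixed order.

    (1) not expressed in the host line -> excluded; (2) testable
    (>= ``testable_min`` datasets in each class) with Fisher p < alpha
    and a larger bound fraction in high lines -> preferential; (3) not
    testable, bound fraction in high lines > 50% -> majority; (4) bound
    fraction in (25%, 50%] -> minority; (5) otherwise unclassified.
    Boundary fractions follow the strict wording: exactly 50% is
    minority, exactly 25% is unclassified.
    """
    host_expression = pd.Series(host_expression, dtype=float)
    rows = []
    for tf, row in contingencies.iterrows():
        bh, th = int(row["bound_high"]), int(row["total_high"])
        bl, tl = int(row["bound_low"]), int(row["total_low"])
        frac_high = bh / th if th else np.nan
        frac_low = bl / tl if tl else np.nan
        testable = th >= testable_min and tl >= testable_min
        fisher_p = (
            fisher_exact_2x2(bh, th - bh, bl, tl - bl, alternative=alternative)
            if testable
            else np.nan
        )
        expr = float(host_expression.get(tf, 0.0))
        if expr <= expression_threshold:
            tier = "excluded_not_expressed"
        elif th == 0:
            warnings.warn(f"TF {tf}: no high-line datasets; unclassified", stacklevel=2)
            tier = "unclassified"
        elif testable and fisher_p < alpha and frac_high > (frac_low if tl else 0.0):
            tier = "preferential"
        elif not testable and frac_high > 0.5:
            tier = "majority"
        elif 0.25 < frac_high <= 0.5:
            tier = "minority"
        else:
            tier = "unclassified"
        rows.append(
            {
                "tf": tf,
                "bound_high": bh,
                "total_high": th,
                "bound_low": bl,
                "total_low": tl,
                "fraction_high": frac_high,
                "fraction_low": frac_low,
                "testable": testable,
                "fisher_p": fisher_p,
                "host_expression": expr,
                "tier": tier,
            }
        )
    return pd.DataFrame(rows).set_index("tf")
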