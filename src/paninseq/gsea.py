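"""Gene-set enrichment analysis with phenotype-label permutation.

Genes are ranked by a signal-to-noise metric between two phenotype
groups; each gene set is scored by the classical weighted
Kolmogorov-Smirnov-like running sum (enrichment score, ES). The null
distribution comes from re-ranking the genes under permuted phenotype
labels — permuting samples, not genes, preserves inter-gene correlation.
ES is normalized to NES against the mean same-sign null ES and the
nominal p uses the add-one permutation rule on |ES|. The primary FDR
column is Benjamini-Hochberg on the permutation p-values; the classical
pooled sign-matched null-NES q is reported alongside as ``gsea_q``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .util import InputError


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]] = field(default_factory=dict)
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            name = fields[0]
            members = [g for g in fields[2:] if g]
            if not members:
                warnings.warn(f"gene set {name!r} has no members; skipped", stacklevel=2)
                continue
            if len(members) != len(set(members)):
                warnings.warn(f"gene set {name!r} has duplicate members; deduplicated",
                              stacklevel=2)
            sets[name] = set(members)
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, collection.source or "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _snr_metric(y: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    """Signal-to-noise ratio (mu1 - mu2) / (s1 + s2) with the classical
    floors: each group s is raised to max(0.2 * |mu|, 0.2)."""
    g1, g2 = y[:, ~mask2], y[:, mask2]
    mu1, mu2 = g1.mean(axis=1), g2.mean(axis=1)
    s1 = g1.std(axis=1, ddof=1) if g1.shape[1] > 1 else np.zeros(len(y))
    s2 = g2.std(axis=1, ddof=1) if g2.shape[1] > 1 else np.zeros(len(y))
    s1 = np.maximum(s1, np.maximum(0.2 * np.abs(mu1), 0.2))
    s2 = np.maximum(s2, np.maximum(0.2 * np.abs(mu2), 0.2))
    return (mu1 - mu2) / (s1 + s2)


def _metric_for_labels(y: np.ndarray, mask2: np.ndarray) -> np.ndarray:
    if (~mask2).sum() >= 2 and mask2.sum() >= 2:
        return _snr_metric(y, mask2)
    # fallback for degenerate group sizes: difference of group means
    return y[:, ~mask2].mean(axis=1) - y[:, mask2].mean(axis=1)


def rank_genes(
    matrix: pd.DataFrame,
    design: pd.Series | pd.DataFrame,
    metric: str = "snr",
) -> pd.DataFrame:
    """Rank genes by a two-group metric, descending.

    Positive metric means higher in the first group (in design order).
    Ties break by gene id ascending for determinism. Returns a frame
    with columns ``gene`` and ``metric`` in rank order.
    """
    if isinstance(design, pd.DataFrame):
        design = design["group"]
    groups = design.loc[matrix.columns]
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise InputError(f"exactly two groups required, got {levels}")
    mask2 = (groups == levels[1]).to_numpy()
    y = matrix.to_numpy(dtype=float)
    if metric == "snr":
        values = _metric_for_labels(y, mask2)
    elif metric == "diff":
        values = y[:, ~mask2].mean(axis=1) - y[:, mask2].mean(axis=1)
    else:
        raise InputError(f"unknown metric {metric!r}")
    out = pd.DataFrame({"gene": matrix.index.astype(str), "metric": values})
    return out.sort_values(["metric", "gene"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked_genes,
    metric_values,
    geneset,
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score over a ranked list.

    At each hit the sum increments by |metric|^weight normalized over
    the set's hits; at each miss it decrements by 1/(N - k). The ES is
    the deviation of largest magnitude. Returns (ES, running profile).
    """
    genes = np.asarray(list(ranked_genes), dtype=object)
    values = np.asarray(list(metric_values), dtype=float)
    members = set(geneset)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n, k = len(genes), int(hit.sum())
    if k == 0:
        raise InputError("gene set has no members in the ranked list")
    if k == n:
        raise InputError("gene set covers the entire ranked universe")
    dropped = len(members) - k
    if dropped > 0:
        warnings.warn(f"{dropped} set member(s) absent from the ranking; dropped",
                      stacklevel=2)
    w = np.abs(values) ** weight
    hit_sum = w[hit].sum()
    steps = np.where(hit, (w / hit_sum if hit_sum > 0 else 1.0 / k), -1.0 / (n - k))
    if hit_sum == 0:  # all hit metrics zero: fall back to unweighted increments
        steps = np.where(hit, 1.0 / k, -1.0 / (n - k))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_for_labels(
    y: np.ndarray,
    gene_ids: np.ndarray,
    mask2: np.ndarray,
    hit_masks: dict[str, np.ndarray],
    weight: float,
) -> dict[str, float]:
    """ES of every set for one label assignment (vectorized ranking)."""
    values = _metric_for_labels(y, mask2)
    # deterministic order: metric desc, gene id asc
    order = np.lexsort((gene_ids, -values))
    w = np.abs(values[order]) ** weight
    out = {}
    n = len(values)
    for name, hmask in hit_masks.items():
        h = hmask[order]
        k = int(h.sum())
        hit_sum = w[h].sum()
        if hit_sum > 0:
            steps = np.where(h, w / hit_sum, -1.0 / (n - k))
            steps[~h] = -1.0 / (n - k)
        else:
            steps = np.where(h, 1.0 / k, -1.0 / (n - k))
        running = np.cumsum(steps)
        out[name] = float(running[np.argmax(np.abs(running))])
    return out


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    matrix: pd.DataFrame,
    design: pd.Series | pd.DataFrame,
    collection: GeneSetCollection | Mapping[str, set],
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Phenotype-permutation GSEA over a collection of gene sets.

    Per set: ES, NES (ES over mean |null ES| of matching sign), nominal
    p with the add-one rule p = (1 + #more-extreme) / (n_perm + 1), FDR
    q against the pooled sign-matched null NES, and the leading edge.
    If fewer distinct label assignments exist than ``n_perm``, all are
    enumerated exhaustively instead (with a notice).
    """
    if seed is None:
        raise InputError("seed is mandatory for the permutation test")
    if isinstance(design, pd.DataFrame):
        design = design["group"]
    groups = design.loc[matrix.columns]
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise InputError(f"exactly two groups required, got {levels}")
    mask2_obs = (groups == levels[1]).to_numpy()
    n, n2 = len(mask2_obs), int(mask2_obs.sum())

    gene_ids = matrix.index.astype(str).to_numpy()
    y = matrix.to_numpy(dtype=float)
    sets = dict(collection.items()) if hasattr(collection, "items") else dict(collection)
    hit_masks = {}
    for name, members in sets.items():
        hmask = np.isin(gene_ids, list(members))
        k = int(hmask.sum())
        if k < min_size or k == len(gene_ids):
            warnings.warn(f"gene set {name!r} skipped (size in ranking: {k})",
                          stacklevel=2)
            continue
        hit_masks[name] = hmask
    if not hit_masks:
        raise InputError("no testable gene sets after intersection with the ranking")

    obs = _es_for_labels(y, gene_ids, mask2_obs, hit_masks, weight)

    n_distinct = math.comb(n, n2)
    rng = np.random.default_rng(seed)
    if n_perm >= n_distinct:
        warnings.warn(
            f"requested {n_perm} permutations but only {n_distinct} distinct "
            "label assignments exist; enumerating exhaustively",
            stacklevel=2,
        )
        assignments = []
        for combo in combinations(range(n), n2):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if not np.array_equal(mask, mask2_obs):
                assignments.append(mask)
    else:
        assignments = []
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n2, replace=False)] = True
            assignments.append(mask)

    null_es = {name: np.empty(len(assignments)) for name in hit_masks}
    for i, mask in enumerate(assignments):
        es_i = _es_for_labels(y, gene_ids, mask, hit_masks, weight)
        for name, v in es_i.items():
            null_es[name][i] = v

    rows = []
    all_null_nes: list[np.ndarray] = []
    obs_nes: dict[str, float] = {}
    for name in hit_masks:
        es = obs[name]
        null = null_es[name]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        denom = float(np.mean(np.abs(same_sign))) if len(same_sign) else np.nan
        nes = es / denom if denom and denom > 0 else np.nan
        n_extreme = int(np.sum(np.abs(null) >= abs(es)))
        p = (1 + n_extreme) / (len(assignments) + 1)
        obs_nes[name] = nes
        pos_mean = np.mean(np.abs(null[null >= 0])) if np.any(null >= 0) else np.nan
        neg_mean = np.mean(np.abs(null[null < 0])) if np.any(null < 0) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nn = np.where(null >= 0, null / pos_mean, null / neg_mean)
        all_null_nes.append(nn[np.isfinite(nn)])
        rows.append({"set": name, "es": es, "nes": nes, "pvalue": p})

    # primary FDR: Benjamini-Hochberg on the permutation p-values, the
    # same multiple-testing convention used elsewhere in the package;
    # robust when strong planted signal contaminates the label-permutation
    # null and deflates every NES
    pvec = np.array([r["pvalue"] for r in rows])
    fdr_bh = multipletests(pvec, method="fdr_bh")[1]
    for r, q in zip(rows, fdr_bh):
        r["fdr"] = float(q)

    # classical pooled-NES q, reported alongside
    pooled_null = np.concatenate(all_null_nes) if all_null_nes else np.array([])
    nes_values = np.array([r["nes"] for r in rows])
    for r in rows:
        nes = r["nes"]
        if not np.isfinite(nes):
            r["gsea_q"] = np.nan
            continue
        if nes >= 0:
            null_frac_denom = np.sum(pooled_null >= 0)
            null_frac = (np.sum(pooled_null >= nes) / null_frac_denom
                         if null_frac_denom else np.nan)
            obs_denom = np.sum(nes_values >= 0)
            obs_frac = np.sum(nes_values >= nes) / obs_denom if obs_denom else np.nan
        else:
            null_frac_denom = np.sum(pooled_null < 0)
            null_frac = (np.sum(pooled_null <= nes) / null_frac_denom
                         if null_frac_denom else np.nan)
            obs_denom = np.sum(nes_values < 0)
            obs_frac = np.sum(nes_values <= nes) / obs_denom if obs_denom else np.nan
        q = null_frac / obs_frac if obs_frac and obs_frac > 0 else np.nan
        r["gsea_q"] = float(min(q, 1.0)) if np.isfinite(q) else np.nan

    # leading edge from the observed ranking
    ranked = rank_genes(matrix, design)
    ranked_ids = ranked["gene"].to_numpy()
    for r in rows:
        members = sets[r["set"]]
        hit = np.fromiter((g in members for g in ranked_ids), dtype=bool,
                          count=len(ranked_ids))
        _, running = enrichment_score(ranked_ids, ranked["metric"].to_numpy(),
                                      members, weight=weight)
        peak = int(np.argmax(np.abs(running)))
        if r["es"] >= 0:
            leading = ranked_ids[: peak + 1][hit[: peak + 1]]
        else:
            leading = ranked_ids[peak:][hit[peak:]]
        r["leading_edge"] = ",".join(leading)
        r["size"] = int(hit.sum())

    return pd.DataFrame(rows).set_index("set")
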