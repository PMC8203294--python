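"""Differential testing on count matrices.

Counts (genes x samples, or peaks x samples) are normalized to counts
per million with trimmed-mean-of-M-values (TMM) scale factors. Each
feature is scored on the log2-CPM scale with a variance-moderated
Wald-type statistic: feature-wise residual variances are shrunk toward
an abundance-dependent prior (an empirical-Bayes fit of a scaled
inverse-chi-square hierarchy whose location follows the parametric
count-data trend ``var = a + b / mean``). Significance is calibrated by
label permutation rather than a t reference: the moderated statistics
of all features under permuted sample labels are pooled into one
empirical null, which adapts to the actual tail behavior of
over-dispersed counts where a parametric t reference is only
approximate. For small designs every distinct label assignment is
enumerated; larger designs use a fixed-size random sample of
assignments drawn from a deterministic generator, so identical inputs
always give identical results.

The interaction contrast of a 2x2 factorial design (does the response
to the condition differ between genotypes?) uses the same statistic
with a Freedman-Lane permutation scheme: residuals of the reduced
(additive) model are permuted and the main effects added back, which
preserves type-I control in the presence of genuine main effects.

Multiple testing is controlled per analysis with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from .util import InputError, round_half_up

PSEUDOCOUNT = 0.5  # added on the CPM scale before log2, keeps fold changes finite
MAX_PERMUTATIONS = 1000  # enumerate exhaustively below this, sample above
_PERM_SEED = 20090  # fixed: the test itself is deterministic in its inputs


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, geometric mean 1.

    For each sample against a reference column (the one whose
    upper-quartile fraction is closest to the mean), the factor is the
    weighted mean of per-feature log2 ratios (M values) after trimming
    the most extreme ``trim_m`` of M values and ``trim_a`` of average
    abundances; weights are inverse binomial variances.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise InputError("all-zero sample column; cannot normalize")
    frac = mat / lib
    uq = np.quantile(frac, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_idx]
    ref_lib = lib[ref_idx]

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        obs = mat[:, j]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() == 0:
            continue
        o, r = obs[keep], ref[keep]
        m = np.log2((o / lib[j]) / (r / ref_lib))
        a = 0.5 * np.log2((o / lib[j]) * (r / ref_lib))
        w = 1.0 / ((lib[j] - o) / (lib[j] * o) + (ref_lib - r) / (ref_lib * r))
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if sel.sum() > 0 and np.sum(w[sel]) > 0:
            log_factors[j] = np.sum(w[sel] * m[sel]) / np.sum(w[sel])
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def normalize_library(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """CPM on TMM-corrected effective library sizes.

    Returns the normalized matrix and the per-sample scale factors
    (geometric mean 1; the effective library size is column total times
    factor).
    """
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    cpm = counts / eff_lib * 1e6
    return cpm, factors


# ---------------------------------------------------------------------------
# variance moderation (empirical Bayes squeeze of feature variances)
# ---------------------------------------------------------------------------

def _fit_variance_prior(
    s2: np.ndarray, df: float, abundance: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Estimate prior df d0 and per-feature prior variances s0^2.

    The prior location follows the parametric count-data form
    ``s0^2(mu) = a + b / mu`` in mean abundance mu (shot noise plus a
    dispersion floor), fit to the unbiased log residual variances. The
    prior df comes from moment-matching the spread of log(s2) around
    the trend: under the hierarchy s2/s0^2 ~ F(df, d0), so the excess of
    var(log s2) over trigamma(df/2) identifies trigamma(d0/2). Returns
    (inf, trend) when no excess spread is observed.
    """
    n = len(s2)
    ok = s2 > 0
    if ok.sum() < 4:
        s0 = float(np.mean(s2)) if n else 0.0
        return np.inf, np.full(n, max(s0, 1e-12))
    z = np.log(s2[ok])
    # unbias: E[log s2 | s0] = log s0 + digamma(df/2) - log(df/2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    trend = np.full(n, float(np.mean(e)))
    if abundance is not None and np.ptp(abundance[ok]) > 0:
        mu = np.maximum(abundance, 1e-8)

        def model(m, log_a, log_b):
            return np.log(np.exp(log_a) + np.exp(log_b) / m)

        try:
            p0 = [float(np.median(e)), float(np.median(e))]
            popt, _ = curve_fit(model, mu[ok], e, p0=p0, maxfev=10000)
            trend = model(mu, *popt)
        except RuntimeError:
            pass  # keep the constant trend
    resid = e - trend[ok]
    target = float(np.var(resid, ddof=1)) - special.polygamma(1, df / 2.0)
    if target <= 1e-8:
        return np.inf, np.exp(trend)

    half = optimize.brentq(
        lambda h: float(special.polygamma(1, h)) - target, 1e-6, 1e6
    )
    d0 = 2.0 * half
    s0 = np.exp(trend + special.digamma(half) - np.log(half))
    return d0, s0


def _moderated_stat(
    effect: np.ndarray,
    s2: np.ndarray,
    df_resid: float,
    stderr_unit: float,
    d0: float,
    s0: np.ndarray,
) -> np.ndarray:
    """Wald-type statistic with the squeezed variance in the denominator."""
    if np.isinf(d0):
        s2_post = np.broadcast_to(s0, s2.shape)
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
    se = np.sqrt(np.maximum(s2_post, 1e-300)) * stderr_unit
    return effect / se


def _pooled_permutation_p(t_obs: np.ndarray, t_null: np.ndarray) -> np.ndarray:
    """Two-sided p-values of observed statistics against a pooled null.

    p = (1 + #{|null| >= |obs|}) / (N + 1); the add-one rule bounds p
    away from zero by the size of the null ensemble.
    """
    null_abs = np.sort(np.abs(t_null.ravel()))
    n = len(null_abs)
    idx = np.searchsorted(null_abs, np.abs(t_obs), side="left")
    return (1.0 + (n - idx)) / (n + 1.0)


def _group_assignments(n: int, n2: int, observed: np.ndarray) -> np.ndarray:
    """Label assignments for the permutation null: all distinct ways to
    choose the second group when few, otherwise a fixed-size sample.

    The observed assignment and its mirror image are excluded from the
    enumerated ensemble — they would re-insert every observed statistic
    into its own null and cap the attainable significance."""
    from math import comb

    if comb(n, n2) <= MAX_PERMUTATIONS:
        masks = []
        for combo in combinations(range(n), n2):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if np.array_equal(mask, observed) or np.array_equal(~mask, observed):
                continue
            masks.append(mask)
        return np.array(masks)
    rng = np.random.default_rng(_PERM_SEED)
    masks = np.zeros((MAX_PERMUTATIONS, n), dtype=bool)
    for i in range(MAX_PERMUTATIONS):
        masks[i, rng.choice(n, size=n2, replace=False)] = True
    return masks


def _coerce_design(design: pd.Series | pd.DataFrame) -> pd.DataFrame:
    if isinstance(design, pd.Series):
        design = design.to_frame("group")
    if "group" not in design.columns:
        raise InputError("design requires a 'group' column")
    return design


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def test_two_group(
    counts: pd.DataFrame,
    design: pd.Series | pd.DataFrame,
    fdr_cutoff: float = 0.05,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-feature two-group differential test on normalized log2 counts.

    The reported ``log2fc`` is the difference of group means of
    log2(CPM + 0.5), non-reference minus reference group. The reference
    is the lexicographically first label unless ``reference`` names one
    explicitly. ``significant`` marks FDR < ``fdr_cutoff``.
    """
    design = _coerce_design(design)
    if set(design.index) != set(counts.columns):
        raise InputError("design samples do not match matrix columns")
    groups = design.loc[counts.columns, "group"]
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise InputError(f"exactly two groups required, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise InputError(f"reference {reference!r} not among groups {levels}")
        levels = [reference] + [lv for lv in levels if lv != reference]
    mask2 = (groups == levels[1]).to_numpy()
    n1, n2 = int((~mask2).sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs >= 2 samples")

    cpm, factors = normalize_library(counts)
    y = np.log2(cpm.to_numpy(dtype=float) + PSEUDOCOUNT)
    abundance = cpm.to_numpy().mean(axis=1) * float(
        (counts.sum(axis=0) * factors).mean()
    ) / 1e6  # mean normalized count per feature

    def group_stats(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """effect and residual variance for each assignment (columns)."""
        m2 = masks.T.astype(float)  # samples x perms
        m1 = 1.0 - m2
        k2 = m2.sum(axis=0)
        k1 = m1.sum(axis=0)
        s_1, s_2 = y @ m1, y @ m2
        q_1, q_2 = (y ** 2) @ m1, (y ** 2) @ m2
        mean1, mean2 = s_1 / k1, s_2 / k2
        ss = (q_1 - k1 * mean1 ** 2) + (q_2 - k2 * mean2 ** 2)
        return mean2 - mean1, ss / (len(mask2) - 2)

    eff_obs, s2_obs = group_stats(mask2[None, :])
    eff_obs, s2_obs = eff_obs[:, 0], s2_obs[:, 0]
    df_resid = n1 + n2 - 2
    unit = np.sqrt(1.0 / n1 + 1.0 / n2)
    d0, s0 = _fit_variance_prior(s2_obs, df_resid, abundance)
    t_obs = _moderated_stat(eff_obs, s2_obs, df_resid, unit, d0, s0)

    masks = _group_assignments(len(mask2), n2, mask2)
    eff_null, s2_null = group_stats(masks)
    # group sizes differ across assignments only when n1 != n2 is allowed;
    # here every assignment keeps |group2| = n2, so the unit is shared
    t_null = _moderated_stat(eff_null, s2_null, df_resid, unit, d0, s0[:, None])
    pvals = _pooled_permutation_p(t_obs, t_null)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": eff_obs,
            "stat": t_obs,
            "pvalue": pvals,
            "fdr": fdr,
            "mean_norm": cpm.to_numpy().mean(axis=1),
            "significant": fdr < fdr_cutoff,
        },
        index=counts.index,
    )


def test_interaction(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    n_perm: int = MAX_PERMUTATIONS,
) -> pd.DataFrame:
    """Interaction contrast in a 2x2 factorial design.

    ``design`` needs columns ``group`` (e.g. genotype) and ``factor2``
    (e.g. condition). The tested effect is the difference, between
    levels of ``group``, of the ``factor2`` response — features whose
    condition response depends on genotype. The null ensemble permutes
    residuals of the reduced additive model (Freedman-Lane), so main
    effects of either factor do not inflate the interaction test.
    """
    design = _coerce_design(design)
    if "factor2" not in design.columns:
        raise InputError("interaction design requires a 'factor2' column")
    if set(design.index) != set(counts.columns):
        raise InputError("design samples do not match matrix columns")
    sub = design.loc[counts.columns]
    a_levels = sorted(set(sub["group"]))
    b_levels = sorted(set(sub["factor2"]))
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise InputError("2x2 factorial design required")
    a = (sub["group"] == a_levels[1]).to_numpy(dtype=float)
    b = (sub["factor2"] == b_levels[1]).to_numpy(dtype=float)
    for va in (0, 1):
        for vb in (0, 1):
            if int(np.sum((a == va) & (b == vb))) < 2:
                raise InputError(
                    f"factorial cell (group={a_levels[va]}, factor2={b_levels[vb]}) "
                    "has < 2 samples"
                )

    cpm, factors = normalize_library(counts)
    y = np.log2(cpm.to_numpy(dtype=float) + PSEUDOCOUNT)
    abundance = cpm.to_numpy().mean(axis=1) * float(
        (counts.sum(axis=0) * factors).mean()
    ) / 1e6
    n = len(a)
    X = np.column_stack([np.ones_like(a), a, b, a * b])
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = X @ xtx_inv  # samples x 4
    df_resid = n - 4
    unit = float(np.sqrt(xtx_inv[3, 3]))

    def interaction_stats(ymat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = ymat @ proj
        resid = ymat - beta @ X.T
        return beta[:, 3], (resid ** 2).sum(axis=1) / df_resid

    eff_obs, s2_obs = interaction_stats(y)
    d0, s0 = _fit_variance_prior(s2_obs, df_resid, abundance)
    t_obs = _moderated_stat(eff_obs, s2_obs, df_resid, unit, d0, s0)

    # Freedman-Lane: permute reduced-model residuals, add fitted back.
    # The reduced-model projection removes p0 degrees of freedom, so the
    # empirical variance of the raw residual entries is sigma^2 (n-p0)/(n-1);
    # rescaling by sqrt((n-1)/(n-p0)) restores it to sigma^2 so the
    # permutation null has the same scale as the observed statistic.
    X0 = X[:, :3]
    beta0 = y @ (X0 @ np.linalg.inv(X0.T @ X0))
    fitted0 = beta0 @ X0.T
    resid0 = (y - fitted0) * np.sqrt((n - 1.0) / (n - X0.shape[1]))
    rng = np.random.default_rng(_PERM_SEED)
    t_null_parts = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        eff_p, s2_p = interaction_stats(fitted0 + resid0[:, perm])
        t_null_parts.append(_moderated_stat(eff_p, s2_p, df_resid, unit, d0, s0))
    t_null = np.stack(t_null_parts, axis=1)
    pvals = _pooled_permutation_p(t_obs, t_null)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": eff_obs,
            "stat": t_obs,
            "pvalue": pvals,
            "fdr": fdr,
            "mean_norm": cpm.to_numpy().mean(axis=1),
            "significant": fdr < fdr_cutoff,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# set overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    shared: int
    pct_shared_of_a: int
    expected_random: float
    pvalue: float
    universe_n: int

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "shared": self.shared,
            "pct_shared_of_a": self.pct_shared_of_a,
            "expected_random": self.expected_random,
            "pvalue": self.pvalue,
            "universe_n": self.universe_n,
        }


def overlap_stats(set_a, set_b, universe_n: int) -> OverlapStats:
    """Shared count, percent of A shared, expected random overlap, and
    upper-tail hypergeometric enrichment p for two feature sets drawn
    from a universe of ``universe_n`` features.

    ``expected_random = |A| * |B| / N`` is the mean intersection size of
    two random sets of the same cardinalities; the percent is rounded
    half-up to an integer for reporting.
    """
    set_a, set_b = set(set_a), set(set_b)
    if universe_n < len(set_a | set_b):
        raise InputError("universe smaller than the union of the two sets")
    if not set_a:
        raise InputError("set A is empty")
    shared = len(set_a & set_b)
    pct = int(round_half_up(100.0 * shared / len(set_a)))
    expected = len(set_a) * len(set_b) / universe_n
    p = float(stats.hypergeom.sf(shared - 1, universe_n, len(set_a), len(set_b)))
    return OverlapStats(len(set_a), len(set_b), shared, pct, expected, min(p, 1.0), universe_n)
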