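"""Exact 2x2 association testing shared by the accessibility and TF modules."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln


def _log_hypergeom_pmf(x: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(X = x) for the number of successes in the top-left cell of a
    2x2 table with fixed margins (row1 = r1, col1 = c1, grand total = n)."""
    c2 = n - c1
    return (
        gammaln(c1 + 1)
        - gammaln(x + 1)
        - gammaln(c1 - x + 1)
        + gammaln(c2 + 1)
        - gammaln(r1 - x + 1)
        - gammaln(c2 - (r1 - x) + 1)
        - (gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    )


def fisher_exact_2x2(
    a: int,
    b: int,
    c: int,
    d: int,
    alternative: str = "two-sided",
    rel_tol: float = 1e-7,
) -> float:
    """Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    Conditions on both margins; the two-sided p-value is the sum of
    hypergeometric probabilities of all tables no more likely than the
    observed one (minimum-likelihood rule). Table probabilities are
    compared with relative tolerance ``rel_tol`` so that floating-point
    noise does not exclude tables of exactly-equal probability.

    ``alternative``: ``two-sided`` (default), ``greater`` (enrichment of
    the top-left cell), or ``less``.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        warnings.warn("empty 2x2 table; p = 1", stacklevel=2)
        return 1.0
    r1, c1 = a + b, a + c
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, n, r1, c1)
    p_obs = logp[a - lo]
    if alternative == "two-sided":
        mask = logp <= p_obs + np.log1p(rel_tol)
    elif alternative == "greater":
        mask = support >= a
    elif alternative == "less":
        mask = support <= a
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    # log-sum-exp over the selected tables
    m = np.max(logp[mask])
    p = float(np.exp(m) * np.sum(np.exp(logp[mask] - m)))
    return min(p, 1.0)
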