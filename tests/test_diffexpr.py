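"""Normalization, moderated tests, BH behavior, and overlap statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from paninseq import diffexpr
from paninseq.util import InputError


def two_group_design(counts):
    return pd.Series({s: s.rsplit("_", 1)[0] for s in counts.columns})


class TestNormalizeLibrary:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"a_1": [5, 10, 15], "a_2": [5, 10, 15]},
                              index=["g1", "g2", "g3"])
        _, factors = diffexpr.normalize_library(counts)
        np.testing.assert_allclose(factors, 1.0)

    def test_depth_doubling_corrected(self):
        counts = pd.DataFrame({"a_1": [5, 10, 15], "a_2": [10, 20, 30]},
                              index=["g1", "g2", "g3"])
        cpm, factors = diffexpr.normalize_library(counts)
        np.testing.assert_allclose(cpm["a_1"], cpm["a_2"])
        np.testing.assert_allclose(factors.prod(), 1.0, rtol=1e-9)

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 200, (5, 3)),
                              index=[f"g{i}" for i in range(5)],
                              columns=["s_1", "s_2", "s_3"])
        _, factors = diffexpr.normalize_library(counts)

        # naive direct computation of the same weighted trimmed mean
        mat = counts.to_numpy(float)
        lib = mat.sum(0)
        uq = np.quantile(mat / lib, 0.75, axis=0)
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
        logf = []
        for j in range(3):
            m, a, w = [], [], []
            for g in range(5):
                o, r = mat[g, j], mat[g, ref_j]
                if o > 0 and r > 0:
                    m.append(np.log2((o / lib[j]) / (r / lib[ref_j])))
                    a.append(0.5 * np.log2((o / lib[j]) * (r / lib[ref_j])))
                    w.append(1 / ((lib[j] - o) / (lib[j] * o)
                                  + (lib[ref_j] - r) / (lib[ref_j] * r)))
            m, a, w = map(np.array, (m, a, w))
            m_lo, m_hi = np.quantile(m, [0.3, 0.7])
            a_lo, a_hi = np.quantile(a, [0.05, 0.95])
            sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
            logf.append(np.sum(w[sel] * m[sel]) / np.sum(w[sel]) if sel.any() else 0.0)
        logf = np.array(logf) - np.mean(logf)
        np.testing.assert_allclose(factors.to_numpy(), 2.0 ** logf, rtol=1e-9)

    def test_zero_column_rejected(self):
        counts = pd.DataFrame({"a_1": [1, 2], "a_2": [0, 0]})
        with pytest.raises(InputError):
            diffexpr.normalize_library(counts)


class TestTwoGroup:
    def test_label_swap_negates_logfc_preserves_p(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(100, (100, 8)),
                              index=[f"g{i}" for i in range(100)],
                              columns=[f"A_{i}" for i in range(4)]
                              + [f"B_{i}" for i in range(4)])
        design = two_group_design(counts)
        res_ab = diffexpr.test_two_group(counts, design)
        res_ba = diffexpr.test_two_group(
            counts, design.map({"A": "B", "B": "A"})
        )
        np.testing.assert_allclose(res_ab.log2fc, -res_ba.log2fc, atol=1e-12)
        np.testing.assert_allclose(res_ab.pvalue, res_ba.pvalue, atol=1e-12)

    def test_constant_matrix_no_calls(self):
        counts = pd.DataFrame(50, index=[f"g{i}" for i in range(20)],
                              columns=[f"A_{i}" for i in range(3)]
                              + [f"B_{i}" for i in range(3)])
        res = diffexpr.test_two_group(counts, two_group_design(counts))
        assert not res.significant.any()
        assert (res.pvalue == 1.0).all()

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame(
            np.ones((5, 3), dtype=int) * 10,
            columns=["A_1", "A_2", "B_1"],
        )
        with pytest.raises(InputError):
            diffexpr.test_two_group(counts, two_group_design(counts))

    def test_pvalues_in_unit_interval(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.poisson(30, (50, 8)),
                              columns=[f"A_{i}" for i in range(4)]
                              + [f"B_{i}" for i in range(4)])
        res = diffexpr.test_two_group(counts, two_group_design(counts))
        assert ((res.pvalue > 0) & (res.pvalue <= 1)).all()


class TestInteraction:
    def make(self, rng, n_per_cell=3):
        cols = [f"{a}{b}_{i}" for a in "WK" for b in "ck" for i in range(n_per_cell)]
        counts = pd.DataFrame(rng.poisson(80, (60, len(cols))), columns=cols)
        design = pd.DataFrame(
            {"group": [c[0] for c in cols], "factor2": [c[1] for c in cols]},
            index=cols,
        )
        return counts, design

    def test_constant_matrix_no_calls(self):
        counts = pd.DataFrame(
            40, index=range(10),
            columns=[f"{a}{b}_{i}" for a in "WK" for b in "ck" for i in range(2)],
        )
        design = pd.DataFrame(
            {"group": [c[0] for c in counts.columns],
             "factor2": [c[1] for c in counts.columns]},
            index=counts.columns,
        )
        res = diffexpr.test_interaction(counts, design)
        assert not res.significant.any()

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(7)
        counts, design = self.make(rng)
        drop = [c for c in counts.columns if c.startswith("Kk")]
        with pytest.raises(InputError):
            diffexpr.test_interaction(counts.drop(columns=drop),
                                      design.drop(index=drop))

    def test_planted_genotype_specific_response_recovered(self):
        from paninseq import synthetic

        hits = 0
        for seed in (1, 2, 3):
            cfg = synthetic.SimConfig(
                n_genes=500, groups={"Wc": 5, "Wk": 5, "Kc": 5, "Kk": 5},
                seed=seed + 40,
            )
            counts, _ = synthetic.simulate_count_matrix(cfg)
            kk = [c for c in counts.columns if c.startswith("Kk")]
            counts.loc["gene042", kk] = (counts.loc["gene042", kk] * 8).astype(int)
            design = pd.DataFrame(
                {"group": [s[0] for s in counts.columns],
                 "factor2": [s[1] for s in counts.columns]},
                index=counts.columns,
            )
            res = diffexpr.test_interaction(counts, design)
            hits += bool(res.loc["gene042", "significant"])
        assert hits >= 2


class TestBenjaminiHochberg:
    def test_fdr_is_monotone_stepup_of_sorted_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        fdr = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        # permuting the input leaves per-feature values invariant
        perm = rng.permutation(40)
        fdr_perm = multipletests(p[perm], method="fdr_bh")[1]
        np.testing.assert_allclose(fdr_perm, fdr[perm])


class TestOverlapStats:
    def test_printed_percentages(self):
        a = [f"g{i}" for i in range(125)]
        b = a[:57] + [f"h{i}" for i in range(60)]
        stats = diffexpr.overlap_stats(a, b, universe_n=20_000)
        assert stats.shared == 57
        assert stats.pct_shared_of_a == 46
        a = [f"g{i}" for i in range(165)]
        b = a[:54] + [f"h{i}" for i in range(100)]
        assert diffexpr.overlap_stats(a, b, 20_000).pct_shared_of_a == 33

    def test_disjoint_sets(self):
        stats = diffexpr.overlap_stats(["a", "b"], ["c", "d"], 1000)
        assert stats.shared == 0 and stats.pct_shared_of_a == 0
        assert stats.pvalue == pytest.approx(1.0, abs=0.01)

    def test_expected_random_matches_monte_carlo(self):
        rng = np.random.default_rng(9)
        universe = np.arange(100)
        stats = diffexpr.overlap_stats(range(10), range(10, 20), 100)
        assert stats.expected_random == pytest.approx(1.0)
        draws = [
            len(set(rng.choice(universe, 10, replace=False))
                & set(rng.choice(universe, 10, replace=False)))
            for _ in range(10_000)
        ]
        assert np.mean(draws) == pytest.approx(1.0, abs=3 * np.std(draws) / 100)

    def test_hypergeometric_p_matches_enumeration_small_universe(self):
        # brute force over all intersection sizes for N <= 30
        from math import comb

        for n_a, n_b, universe, shared in [(5, 7, 20, 3), (4, 4, 12, 2), (10, 8, 30, 5)]:
            stats = diffexpr.overlap_stats(
                range(shared) if False else [f"a{i}" for i in range(n_a)],
                [f"a{i}" for i in range(shared)] + [f"b{i}" for i in range(n_b - shared)],
                universe,
            )
            expect = sum(
                comb(n_a, k) * comb(universe - n_a, n_b - k) / comb(universe, n_b)
                for k in range(shared, min(n_a, n_b) + 1)
            )
            assert stats.pvalue == pytest.approx(expect, rel=1e-9)

    def test_universe_too_small_rejected(self):
        with pytest.raises(InputError):
            diffexpr.overlap_stats(range(10), range(5), 8)


class TestPowerMonotonicity:
    def test_rejection_rate_rises_with_effect_size(self):
        from paninseq import synthetic

        rates = []
        for lfc in (0.5, 1.0, 2.0):
            hits = 0
            for seed in (1, 2, 3, 4, 5):
                cfg = synthetic.SimConfig(
                    n_genes=300, groups={"A": 6, "B": 6}, seed=seed + 60,
                    planted_logfc={"gene042": lfc},
                )
                counts, _ = synthetic.simulate_count_matrix(cfg)
                res = diffexpr.test_two_group(counts, two_group_design(counts))
                hits += bool(res.loc["gene042", "pvalue"] < 0.05)
            rates.append(hits)
        assert rates[0] <= rates[2]
        assert rates[2] >= 4
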