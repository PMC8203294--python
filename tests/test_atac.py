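"""Fragment counting, replicate correlation, peak classification,
fold-change comparison, and DEG-peak association."""

import numpy as np
import pandas as pd
import pytest

from paninseq import atac
from paninseq.util import InputError


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestFragmentCounting:
    def test_fragment_equal_to_peak_counts_once(self):
        peaks = bed([("chr1", 100, 200)])
        counts = atac.count_fragments_in_peaks({"s1": bed([("chr1", 100, 200)])}, peaks)
        assert counts.iloc[0, 0] == 1

    def test_abutting_fragment_does_not_count(self):
        peaks = bed([("chr1", 100, 200)])
        counts = atac.count_fragments_in_peaks({"s1": bed([("chr1", 200, 300)])}, peaks)
        assert counts.iloc[0, 0] == 0

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(2)
        starts = np.sort(rng.choice(10_000, 30, replace=False))
        peaks = bed([("chr1", int(s), int(s + rng.integers(50, 200))) for s in starts])
        merged = []
        for _, row in peaks.iterrows():  # merge so the oracle sees the same set
            if merged and row.start < merged[-1][2]:
                merged[-1][2] = max(merged[-1][2], row.end)
            else:
                merged.append([row.chrom, row.start, row.end])
        frags = {
            s: bed([
                ("chr1", int(p), int(p + rng.integers(20, 500)))
                for p in rng.integers(0, 11_000, 200)
            ])
            for s in ("s1", "s2")
        }
        counts = atac.count_fragments_in_peaks(frags, peaks)
        for sample, fdf in frags.items():
            for j, (chrom, ps, pe) in enumerate(merged):
                naive = sum(
                    1
                    for f in fdf.itertuples(index=False)
                    if f.chrom == chrom and f.start < pe and ps < f.end
                )
                assert counts.iloc[j][sample] == naive


class TestSpearman:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 100, 20)
        counts = pd.DataFrame({"s1": col, "s2": col})
        rho = atac.spearman_replicates(counts)
        assert rho.loc["s1", "s2"] == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        col = np.arange(20)
        counts = pd.DataFrame({"s1": col, "s2": col[::-1]})
        assert atac.spearman_replicates(counts).loc["s1", "s2"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 50, (20, 3)), columns=list("abc"))
        rho = atac.spearman_replicates(counts)
        ranks = counts.rank()
        expect = np.corrcoef(ranks["a"], ranks["b"])[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(expect)

    def test_constant_column_reported_missing(self):
        counts = pd.DataFrame({"s1": np.arange(10), "s2": np.ones(10, dtype=int)})
        with pytest.warns(UserWarning):
            rho = atac.spearman_replicates(counts)
        assert np.isnan(rho.loc["s1", "s2"])


class TestClassifyPeaks:
    def tss(self):
        return pd.DataFrame(
            {
                "gene": ["plus", "minus", "far"],
                "chrom": ["chr1", "chr1", "chr2"],
                "tss": [10_000, 50_000, 5_000],
                "strand": ["+", "-", "+"],
            }
        )

    def test_peak_spanning_tss_is_promoter(self):
        peaks = bed([("chr1", 9_900, 10_100)])
        assert atac.classify_peaks(peaks, self.tss()).iloc[0] == "promoter"

    def test_peak_far_downstream_is_distal(self):
        peaks = bed([("chr1", 20_000, 20_500)])
        assert atac.classify_peaks(peaks, self.tss()).iloc[0] == "distal"

    def test_minus_strand_window_is_mirrored(self):
        # upstream of a minus-strand gene lies at larger genomic coordinates
        upstream_peak = bed([("chr1", 50_500, 50_800)])     # within +1000 genomic
        downstream_peak = bed([("chr1", 48_500, 48_900)])   # -1100 genomic: outside
        tss = self.tss()
        assert atac.classify_peaks(upstream_peak, tss).iloc[0] == "promoter"
        assert atac.classify_peaks(downstream_peak, tss).iloc[0] == "distal"
        # just inside the 100 bp gene-downstream side (genomic left of TSS)
        inside = bed([("chr1", 49_950, 50_050)])
        assert atac.classify_peaks(inside, tss).iloc[0] == "promoter"

    def test_unknown_chromosome_distal_with_warning(self):
        peaks = bed([("chrZ", 0, 100)])
        with pytest.warns(UserWarning, match="chrZ"):
            out = atac.classify_peaks(peaks, self.tss())
        assert out.iloc[0] == "distal"


class TestElementFoldChange:
    def make_results(self, values):
        return pd.DataFrame({"log2fc": values},
                            index=[f"p{i}" for i in range(len(values))])

    def test_identical_singletons_p_one(self):
        res = self.make_results([1.0, 1.0])
        groups, p = atac.element_foldchange_by_deg_group(
            res, ["gU"], ["gD"], {"gU": ["p0"], "gD": ["p1"]}
        )
        assert p == 1.0

    def test_separated_groups_significant(self):
        res = self.make_results([2.0, 2.1, 1.9, 2.2, -2.0, -1.8, -2.2, -2.1])
        up = [f"u{i}" for i in range(4)]
        down = [f"d{i}" for i in range(4)]
        mapping = {g: [f"p{i}"] for i, g in enumerate(up + down)}
        groups, p = atac.element_foldchange_by_deg_group(res, up, down, mapping)
        assert p < 0.05
        assert groups["up"].mean() > groups["down"].mean()

    def test_exact_p_matches_enumeration_4v4(self):
        from itertools import combinations

        values = [3.0, 2.0, 1.5, 1.2, 1.0, 0.5, 0.2, -1.0]
        res = self.make_results(values)
        up = [f"u{i}" for i in range(4)]
        down = [f"d{i}" for i in range(4)]
        mapping = {g: [f"p{i}"] for i, g in enumerate(up + down)}
        _, p = atac.element_foldchange_by_deg_group(res, up, down, mapping)

        # enumeration oracle over all rank assignments
        x, y = values[:4], values[4:]
        pooled = sorted(values)
        obs_u = sum(pooled.index(v) + 1 for v in x)  # rank sum of group 1 (no ties)
        stats = []
        for combo in combinations(range(8), 4):
            stats.append(sum(i + 1 for i in combo))
        mean_u = np.mean(stats)
        extreme = sum(1 for s in stats if abs(s - mean_u) >= abs(obs_u - mean_u) - 1e-9)
        assert p == pytest.approx(extreme / len(stats), rel=1e-9)

    def test_empty_group_rejected(self):
        res = self.make_results([1.0])
        with pytest.raises(InputError):
            atac.element_foldchange_by_deg_group(res, ["gU"], ["gD"], {"gU": ["p0"]})


class TestDegPeakAssociation:
    def flags(self, pairs):
        genes = [f"g{i}" for i in range(len(pairs))]
        deg = pd.Series([a for a, _ in pairs], index=genes)
        pk = pd.DataFrame({"distal": [b for _, b in pairs]}, index=genes)
        return deg, pk

    def test_independence_table_p_one(self):
        deg, pk = self.flags(
            [(True, True)] * 10 + [(True, False)] * 10
            + [(False, True)] * 10 + [(False, False)] * 10
        )
        out = atac.deg_peak_association(deg, pk)
        assert out["distal"]["pvalue"] == pytest.approx(1.0)

    def test_perfect_association_tiny_p(self):
        deg, pk = self.flags([(True, True)] * 20 + [(False, False)] * 20)
        out = atac.deg_peak_association(deg, pk)
        assert out["distal"]["pvalue"] < 1e-9
        assert out["distal"]["table"] == [[20, 0], [0, 20]]

    def test_degenerate_margin_p_one_with_warning(self):
        deg, pk = self.flags([(False, True)] * 5 + [(False, False)] * 5)
        with pytest.warns(UserWarning):
            out = atac.deg_peak_association(deg, pk)
        assert out["distal"]["pvalue"] == 1.0


class TestDiffAccessibilityRecovery:
    def test_planted_differential_peak_recovered(self):
        from paninseq import synthetic

        cfg = synthetic.LandscapeConfig(seed=6)
        cand, _, _, _, truth = synthetic.simulate_regulatory_landscape(cfg)
        samples = [c for c in cand.columns if c.startswith(("WT_", "KO_"))]
        counts = cand.set_index("name")[samples]
        design = pd.Series({s: s.split("_")[0] for s in samples})
        res = atac.diff_accessibility(counts, design, reference="WT")
        planted = [iv.name for iv in truth.true_enhancers]
        assert res.loc[planted, "significant"].all()
        assert (res.loc[planted, "log2fc"] > 0).all()
        decoys = [n for n in counts.index if n not in planted]
        assert res.loc[decoys, "significant"].mean() < 0.2
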