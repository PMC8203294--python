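# Methods

This note documents the models, algorithms, defaults, and design
choices behind each module, and what the synthetic data do and do not
establish about behavior on real data.

## UMI quantification

Reads arrive as a TSV with one row per aligned read: sample, gene,
chromosome, 0-based leftmost mapping position, strand, UMI, and a
region flag (exon / intron / intergenic). Quantification uses exonic
reads only; intronic and intergenic reads are discarded by the exon
filter.

Molecule identity is the exact tuple `(sample, gene, UMI, position)`.
Including the mapping position in barcode identity separates molecules
of the same gene that happen to share a barcode, which matters when the
barcode space is small relative to per-gene molecule counts. Collapse
is exact-match: no edit-distance merging of near-identical UMIs is
attempted, so a UMI sequencing error creates a spurious molecule. This
is a deliberate trade: the collapse rule stays trivially verifiable (a
distinct-tuple count) and the error rate of modern short reads keeps
the inflation small; the synthetic generator exposes
`umi_error_rate` to quantify the effect. Strand is not part of the
key; position is the exact coordinate, unbinned.

APM (amplicons per million) is `count / column_total * 1e6`; each
sample column sums to one million by construction, and an all-zero
column is an error naming the sample. The expression filter retains a
gene when strictly more than `min_apm` (default 2) APM is observed in
at least `min_samples` (default 5) samples; the inequality is strict by
a literal reading of the filter rule.

## Differential testing

Counts are normalized to CPM on TMM effective library sizes. The TMM
factor of a sample against a reference column (the one whose
upper-quartile count fraction is closest to the mean) is the weighted
mean of per-feature log2 ratios after trimming 30% of M values and 5%
of A values, with inverse approximate-binomial-variance weights;
factors are scaled to geometric mean 1.

Each feature is scored on `log2(CPM + 0.5)` (the 0.5 pseudocount keeps
fold changes finite at zero counts) with a Wald-type statistic whose
denominator uses an empirical-Bayes moderated variance: feature
residual variances are shrunk toward a prior whose location follows the
parametric count-data trend `s0²(μ) = a + b/μ` in mean normalized count
μ (shot noise plus a dispersion floor), with the prior degrees of
freedom estimated by moment-matching the spread of log variances
around the trend.

Significance does not use a t reference. The distribution of log-count
means is platykurtic at intermediate abundance and heavy-tailed at the
extremes, so a t reference is a few tenths of a percentage point off at
α = 0.05 — real but avoidable. Instead the moderated statistics of all
features under permuted group labels are pooled into one empirical
null, and `p = (1 + #{|t*| ≥ |t|}) / (N + 1)`. For designs with at
most 1000 distinct label assignments every assignment except the
observed one and its mirror is enumerated, making the test fully
deterministic; larger designs draw 1000 assignments from a fixed
internal generator (the test is a pure function of its inputs either
way). The observed assignment is excluded from the enumerated ensemble
because including it re-inserts each observed statistic into its own
null and caps the attainable significance when many features carry
signal. Pooling across features trades exact per-stratum calibration
for aggregate calibration and p-value resolution of order
1/(features × permutations).

The interaction test fits `~ group * condition` per feature on
log2-CPM and tests the product coefficient. Its permutation null uses
the Freedman–Lane scheme: residuals of the reduced additive model are
permuted (one shared permutation per round, preserving inter-feature
correlation) and the fitted main effects added back, so genuine main
effects do not inflate the interaction test. The raw reduced-model
residuals have empirical variance σ²(n−p₀)/(n−1); they are rescaled by
√((n−1)/(n−p₀)) so the null ensemble has the same scale as the
observed statistic.

The two-group contrast direction is non-reference minus reference,
reference being the lexicographically first group label unless set
explicitly; this makes label renaming behave predictably (swapping the
two labels negates every log fold change and leaves p unchanged).
Benjamini–Hochberg is applied per analysis; genes and peaks are
adjusted separately.

DEG-overlap statistics: shared count, percent of list A shared (rounded
half-up to an integer, matching how such percentages are convention-
ally printed), expected random overlap |A|·|B|/N, and an upper-tail
hypergeometric p. The universe size N is an explicit argument —
overlap numbers are meaningless without it, and no default is imposed.

## Gene-set enrichment

Ranking uses the classical signal-to-noise metric
(μ₁−μ₂)/(σ₁+σ₂), each group σ floored at max(0.2·|μ|, 0.2); positive
metric means higher in the first (lexicographic) group. Ties break by
gene id so rankings are deterministic. If a group has fewer than two
samples the metric falls back to the difference of means.

The enrichment score is the classical weighted running sum: hits add
`|metric|^w / Σ_hits |metric|^w` (weight w = 1 by default), misses
subtract `1/(N−k)`; ES is the extremum of largest magnitude. The null
comes from re-ranking under permuted phenotype labels; when fewer
distinct label assignments exist than requested permutations, all are
enumerated (with a notice). Nominal p uses the add-one rule on |ES|
against the permutation ensemble, so the smallest reportable p is
1/(n_perm+1). NES divides ES by the mean |null ES| of matching sign.

Two FDR columns are reported. The primary `fdr` is Benjamini–Hochberg
on the permutation p-values — the same convention used everywhere else
in the package, and robust when a strong coordinated signal
contaminates the label-permutation null (contamination deflates every
NES and makes the pooled-NES q unstable with few sets). The classical
GSEA q (observed NES against the pooled sign-matched null NES) is kept
as `gsea_q` for comparability. With the default 1000 permutations the
p floor (≈0.001) is small enough for FDR < 0.1 calls over collections
of Hallmark-like size.

## ATAC analytics

Union peaks are merged (strictly overlapping intervals only — abutting
half-open intervals stay separate) before counting; a fragment counts
toward every merged peak it overlaps by at least one base. All
coordinates are 0-based half-open throughout the package, and overlap
always means ≥ 1 shared base.

Promoter/distal classification uses a strand-oriented window of
−1000/+100 bp around the TSS (a common annotation default; the window
is configurable and recorded in output metadata). On the minus strand
the window is mirrored in genomic coordinates. A peak overlapping the
window of any gene is a promoter; peaks on chromosomes absent from the
annotation are distal with a warning.

Differential accessibility is the same moderated permutation test with
peaks as features. For the fold-change comparison between elements of
up- and down-regulated genes, elements are treated independently (one
value per gene–element link); the two distributions are compared with
a two-sided Mann–Whitney U (exact for small tie-free samples, normal
approximation with tie correction otherwise). The DEG–peak association
is a Fisher exact test per element class on the 2×2 table of DEG
status against carrying a differential peak; degenerate margins give
p = 1 with a warning rather than an error.

## Consensus enhancers and TF tiering

Cell lines are classed by expression of the gene of interest with
strict thresholds: > 10 high, < 0.5 low, in between unclassified. A
candidate is a consensus enhancer when it overlaps the histone-mark
peaks of at least `min_lines` (default 4) high lines; "H3K27ac/H3K4me1"
is read as the union of the two marks within a line (either suffices) —
an intersection mode is available behind a flag. A line contributes at
most one vote regardless of how many of its peaks overlap. Low-line
overlap counts are reported as a diagnostic and never filter the call,
because the low-line observation is descriptive, not a criterion.

For TF tiering a dataset is bound when any of its events overlaps any
locus. Tier rules apply in fixed order: (1) host-expression exclusion
(normalized abundance ≤ 1, configurable — the exclusion criterion is
stated qualitatively in the field, so the cutoff is explicit here);
(2) preferential if at least `testable_min` = 3 datasets exist in each
class, two-sided Fisher p < α = 0.05, and the bound fraction is higher
in high lines; (3) majority if not testable and > 50% of high-line
datasets are bound; (4) minority for fractions in (25%, 50%] — exactly
50% is minority and exactly 25% is unclassified, by the strict reading
of "more than"; (5) otherwise unclassified. The Fisher routine uses
minimum-likelihood two-sided summation with relative tolerance 1e−7
when comparing table probabilities, and is shared with the DEG–peak
association test.

## Staining scores

H-score = 3·%strong + 2·%moderate + 1·%weak ∈ [0, 300]; percentage
inputs may sum to at most 100 plus a 0.5 tolerance for rounded inputs.
OD = log10(255/gray) for gray ∈ (0, 255]. Positivity rates round
half-up (Python's banker's rounding would print 12.5% as 12, not the
conventional 13).

## Synthetic data: what it emulates, and what it does not

The generators define the package's study conditions:

* `simulate_umi_reads` plants per-gene molecule counts (negative
  binomial around a log-normal baseline, library ~1e5 molecules per
  sample), assigns each molecule a UMI (8 bp) and a uniform position
  within its gene's 2-kb exonic block, guarantees distinct
  (UMI, position) keys per molecule, emits 1 + Poisson(mean−1) PCR
  copies per molecule (default mean 4 reads/molecule), applies
  per-base UMI substitutions (default 1e−3), and appends 5% intronic/
  intergenic reads to exercise the exon filter. With the error rate at
  zero, deduplicated counts equal the planted molecule table exactly.
* `simulate_count_matrix` draws negative-binomial counts with
  var = μ + φμ² (default φ = 0.1, a typical biological dispersion),
  log-normal baseline across genes (σ = 1), expected column totals of
  1e5, and planted log2 fold changes applied to non-reference groups.
* `simulate_regulatory_landscape` mirrors the emulated study design:
  7 high and 5 low pseudo-cell-lines, 5 true enhancers among 20 decoys
  on one chromosome, histone coverage of each true enhancer in a
  configurable number of high lines (decoys in at most 2, below the
  consensus threshold of 4), no coverage of true enhancers in low
  lines, TF rosters with preferential binders (bound in all high-line
  datasets, none low, by default) versus background binders (bound at
  rate 0.3 in both), host expression for all roster TFs, and
  accessibility counts for 3 + 3 samples with a planted log2 fold
  change of 2 at true enhancers.

Every generator writes a truth sidecar (JSON) so tests recover planted
structure instead of re-deriving it, and all randomness flows through a
single mandatory seed.

What passing tests show: the pipeline's operations are correct against
independent oracles, statistically calibrated under the generating
distributions, and able to recover planted structure under those
conditions. What they do not show: robustness to features of real data
the generators omit — positional bias and saturation within amplicons,
fragment-size structure of real ATAC libraries, mapping artifacts,
batch effects, correlated gene modules beyond the planted sets, and
lesion-to-lesion variability beyond a single negative-binomial
dispersion (no published distributional description exists for that
variability, so the defaults are free parameters of this package, not
estimates of any study).

## Numerical choices and degenerate inputs

* Permutation ensembles: at most 1000 assignments; enumeration below
  that (deterministic), seeded sampling above.
* A constant count matrix yields p = 1 everywhere and no calls.
* Constant columns in correlation are reported as missing with a
  warning, not an error.
* Zero-member gene sets are skipped with a warning at GMT parse; sets
  that cover the whole ranked universe (or none of it) are errors.
* Fisher tables with an empty margin give p = 1 with a warning.
* Problem sizes in the test suite (2000 features, 6 vs 6 or 2×2×3
  samples, 20 simulation seeds; 10⁴-row UMI tables; all 2×2 tables
  with total ≤ 40) were chosen to give tight Monte-Carlo bands while
  keeping the full suite a few minutes on one CPU.

## Known limitations

* The moderated statistic's p-values are aggregate-calibrated by the
  pooled permutation null; per-stratum calibration can deviate
  slightly for extreme-abundance features.
* UMI collapse has no error correction; counts inflate by roughly
  `umi_length × error_rate` per read relative to truth.
* The GSEA implementation follows the classical algorithm but makes no
  claim of bitwise equality with any released tool (ranking metric,
  permutation scheme, and FDR conventions are documented above and
  configurable).
* Interval operations assume modest peak-set sizes (thousands);
  consensus calling is O(candidates × lines × peaks).
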