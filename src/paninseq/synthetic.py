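"""Synthetic inputs with planted ground truth.

Every downstream stage of the pipeline is exercised against data whose
truth is known by construction: UMI-tagged read tables with PCR
duplication and planted per-gene molecule counts, negative-binomial
count matrices with planted group log fold changes, and a regulatory
landscape with planted enhancers, histone-mark coverage, and
preferential TF binding. Each generator returns its outputs together
with a :class:`TruthRecord` holding the exact plants, so tests recover
truth rather than re-derive it.

All randomness flows through one mandatory integer seed; the same seed
reproduces byte-identical outputs.

Negative-binomial counts use the mean/dispersion parameterization
``var = mu + phi * mu^2`` (phi = dispersion), the standard convention
for over-dispersed sequencing counts; planted effects are log2 fold
changes on the group mean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .util import ConfigurationError

_UMI_ALPHABET = np.array(list("ACGT"))
GENE_SPAN = 2000  # exonic coordinate range per simulated gene (bases)


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Conditions for read- and count-level simulations.

    ``groups`` maps group label to sample count; the first label is the
    reference and ``planted_logfc`` (gene -> log2 effect) shifts the
    mean of every non-reference group. ``pcr_duplication_mean`` is the
    expected number of reads per molecule (>= 1), ``umi_error_rate`` the
    per-base substitution probability on read UMIs, and
    ``nonexonic_read_fraction`` the fraction of extra intronic or
    intergenic reads appended to exercise the exon filter.
    """

    n_genes: int
    groups: Mapping[str, int]
    seed: int
    planted_logfc: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 0.1
    mean_library_size: int = 100_000
    umi_length: int = 8
    pcr_duplication_mean: float = 4.0
    umi_error_rate: float = 0.001
    nonexonic_read_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.groups or any(n < 1 for n in self.groups.values()):
            raise ConfigurationError("every group needs >= 1 sample")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if not 0.0 <= self.umi_error_rate <= 1.0:
            raise ConfigurationError("umi_error_rate must be in [0, 1]")
        if not 0.0 <= self.nonexonic_read_fraction <= 1.0:
            raise ConfigurationError("nonexonic_read_fraction must be in [0, 1]")
        if self.pcr_duplication_mean < 1.0:
            raise ConfigurationError("pcr_duplication_mean must be >= 1")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size must be positive")
        if self.umi_length <= 0:
            raise ConfigurationError("umi_length must be positive")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups.items() for i in range(n)]

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{str(i + 1).zfill(width)}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class LandscapeConfig:
    """Conditions for the regulatory-landscape simulation.

    Defaults mirror the study design this generator emulates: seven
    high-expression and five low-expression pseudo-cell-lines, five true
    enhancers each covered by histone marks in a configurable number of
    high lines, a consensus threshold of four lines, and a TF roster
    split into preferential binders (bound in most high-line datasets,
    rarely in low-line datasets) and background binders (bound at the
    same modest rate in both).
    """

    seed: int
    n_high_lines: int = 7
    n_low_lines: int = 5
    n_true_enhancers: int = 5
    n_decoy_peaks: int = 20
    enhancer_support_lines: int = 7
    decoy_max_support: int = 2
    consensus_min_lines: int = 4
    tf_roster: Mapping[str, str] = field(
        default_factory=lambda: {
            "EP300": "preferential",
            "NR3C1": "preferential",
            "CTCF": "background",
            "MAX": "background",
            "MYC": "background",
            "REST": "background",
        }
    )
    datasets_per_tf_high: int = 7
    datasets_per_tf_low: int = 5
    preferential_bind_rate_high: float = 1.0
    preferential_bind_rate_low: float = 0.0
    background_bind_rate: float = 0.3
    unexpressed_tfs: tuple[str, ...] = ()
    n_samples_per_group: int = 3
    accessibility_logfc: float = 2.0
    peak_mean_count: float = 200.0
    dispersion: float = 0.05
    peak_width: int = 500

    def __post_init__(self) -> None:
        if self.n_high_lines < self.consensus_min_lines:
            raise ConfigurationError(
                f"{self.n_high_lines} high lines but consensus threshold "
                f"{self.consensus_min_lines}"
            )
        if self.enhancer_support_lines > self.n_high_lines:
            raise ConfigurationError("enhancer_support_lines exceeds n_high_lines")
        if self.decoy_max_support >= self.consensus_min_lines:
            raise ConfigurationError(
                "decoy_max_support must stay below the consensus threshold"
            )
        if not self.tf_roster:
            raise ConfigurationError("tf_roster must not be empty")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        for tf, cls in self.tf_roster.items():
            if cls not in ("preferential", "background"):
                raise ConfigurationError(f"TF {tf}: unknown class {cls!r}")


@dataclass
class TruthRecord:
    """Exact plants of one simulation run, serializable to JSON."""

    true_molecules: pd.DataFrame | None = None  # genes x samples
    true_de_genes: dict[str, float] = field(default_factory=dict)
    true_enhancers: list[GenomicInterval] = field(default_factory=list)
    true_tf_classes: dict[str, str] = field(default_factory=dict)
    true_line_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "true_molecules": (
                None
                if self.true_molecules is None
                else {
                    "genes": list(self.true_molecules.index),
                    "samples": list(self.true_molecules.columns),
                    "counts": self.true_molecules.to_numpy().tolist(),
                }
            ),
            "true_de_genes": self.true_de_genes,
            "true_enhancers": [
                [iv.chrom, iv.start, iv.end, iv.name] for iv in self.true_enhancers
            ],
            "true_tf_classes": self.true_tf_classes,
            "true_line_classes": self.true_line_classes,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        tm = payload.get("true_molecules")
        true_molecules = (
            None
            if tm is None
            else pd.DataFrame(tm["counts"], index=tm["genes"], columns=tm["samples"])
        )
        return cls(
            true_molecules=true_molecules,
            true_de_genes=payload.get("true_de_genes", {}),
            true_enhancers=[
                GenomicInterval(c, s, e, n)
                for c, s, e, n in payload.get("true_enhancers", [])
            ],
            true_tf_classes=payload.get("true_tf_classes", {}),
            true_line_classes=payload.get("true_line_classes", {}),
        )


# ---------------------------------------------------------------------------
# negative-binomial machinery
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _gene_means(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene, per-sample expected molecule counts.

    Baseline abundances are log-normal across genes (sigma = 1),
    normalized so the expected column total is ``mean_library_size``;
    planted log2 fold changes multiply the mean in non-reference groups.
    """
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    base = base / base.sum() * config.mean_library_size
    genes = config.gene_names
    ref = next(iter(config.groups))
    cols = {}
    for group, n in config.groups.items():
        mu = base.copy()
        if group != ref:
            for gene, lfc in config.planted_logfc.items():
                if gene in genes:
                    mu[genes.index(gene)] *= 2.0 ** lfc
        for i in range(n):
            cols[f"{group}_{i + 1}"] = mu
    return pd.DataFrame(cols, index=genes)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_count_matrix(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Negative-binomial gene x sample counts with planted fold changes."""
    rng = np.random.default_rng(config.seed)
    means = _gene_means(config, rng)
    counts = pd.DataFrame(
        _nb_draw(rng, means.to_numpy(), config.dispersion),
        index=means.index,
        columns=means.columns,
    )
    counts.index.name = "gene_id"
    truth = TruthRecord(true_de_genes=dict(config.planted_logfc))
    return counts, truth


def _random_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    idx = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(_UMI_ALPHABET[row]) for row in idx])


def _apply_umi_errors(
    rng: np.random.Generator, umis: np.ndarray, error_rate: float
) -> np.ndarray:
    if error_rate == 0 or len(umis) == 0:
        return umis
    length = len(umis[0])
    chars = np.array([list(u) for u in umis])
    hit = rng.random(chars.shape) < error_rate
    if hit.any():
        # substitute with one of the three other bases, uniformly
        offsets = rng.integers(1, 4, size=int(hit.sum()))
        base_idx = np.searchsorted(_UMI_ALPHABET, chars[hit])
        chars[hit] = _UMI_ALPHABET[(base_idx + offsets) % 4]
    return np.array(["".join(row) for row in chars])


def simulate_umi_reads(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """UMI-tagged read table with PCR duplication and planted molecules.

    Each gene occupies its own exonic coordinate block on a simulated
    chromosome; every true molecule gets a UMI and a uniform mapping
    position within its gene's block, distinct from every other molecule
    of the same gene and sample so that exact-key deduplication can
    recover the planted counts. PCR emits 1 + Poisson(mean - 1) reads
    per molecule; UMI base substitutions are applied per read. A
    configurable fraction of extra intronic/intergenic reads is
    appended (not part of the molecular truth).
    """
    rng = np.random.default_rng(config.seed)
    means = _gene_means(config, rng)
    molecules = pd.DataFrame(
        _nb_draw(rng, means.to_numpy(), config.dispersion),
        index=means.index,
        columns=means.columns,
    )
    molecules.index.name = "gene_id"

    genes = config.gene_names
    strands = {g: ("+" if i % 2 == 0 else "-") for i, g in enumerate(genes)}
    offsets = {g: i * GENE_SPAN for i, g in enumerate(genes)}

    frames = []
    for sample in molecules.columns:
        for gi, gene in enumerate(genes):
            m = int(molecules.iat[gi, molecules.columns.get_loc(sample)])
            if m == 0:
                continue
            umis = _random_umis(rng, m, config.umi_length)
            positions = offsets[gene] + rng.integers(0, GENE_SPAN, size=m)
            # enforce distinct (umi, position) identity keys per molecule
            seen = set()
            for j in range(m):
                while (umis[j], positions[j]) in seen:
                    umis[j] = _random_umis(rng, 1, config.umi_length)[0]
                    positions[j] = offsets[gene] + rng.integers(0, GENE_SPAN)
                seen.add((umis[j], int(positions[j])))
            n_reads = 1 + rng.poisson(config.pcr_duplication_mean - 1.0, size=m)
            rep = np.repeat(np.arange(m), n_reads)
            read_umis = _apply_umi_errors(rng, umis[rep], config.umi_error_rate)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "chrom": "chrS",
                        "position": positions[rep],
                        "strand": strands[gene],
                        "umi": read_umis,
                        "region_flag": "exon",
                    }
                )
            )

    reads = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "sample_id", "gene_id", "chrom", "position",
                "strand", "umi", "region_flag",
            ]
        )
    )

    n_noise = int(round(len(reads) * config.nonexonic_read_fraction))
    if n_noise > 0:
        noise_genes = rng.choice(genes, size=n_noise)
        noise = pd.DataFrame(
            {
                "sample_id": rng.choice(molecules.columns.to_numpy(), size=n_noise),
                "gene_id": noise_genes,
                "chrom": "chrS",
                "position": [
                    offsets[g] + int(rng.integers(0, GENE_SPAN)) for g in noise_genes
                ],
                "strand": [strands[g] for g in noise_genes],
                "umi": _random_umis(rng, n_noise, config.umi_length),
                "region_flag": rng.choice(["intron", "intergenic"], size=n_noise),
            }
        )
        reads = pd.concat([reads, noise], ignore_index=True)

    truth = TruthRecord(
        true_molecules=molecules, true_de_genes=dict(config.planted_logfc)
    )
    return reads, truth


def simulate_regulatory_landscape(
    config: LandscapeConfig,
) -> tuple[
    pd.DataFrame,
    dict[str, dict[str, pd.DataFrame]],
    pd.DataFrame,
    pd.DataFrame,
    TruthRecord,
]:
    """Peak landscape with planted enhancers, histone marks, and TF events.

    Returns (candidates, histone landscape, TF event table, host
    expression table, truth). ``candidates`` is a BED-like frame of
    true enhancers plus decoys, with per-sample fragment counts as
    extra columns: true enhancers carry a planted accessibility
    increase (``accessibility_logfc``) in the KO group. The histone
    landscape maps line -> mark -> peak frame; each true enhancer is
    covered by marks in exactly ``enhancer_support_lines`` high lines
    and in no low line, decoys in at most ``decoy_max_support`` lines.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr9"
    gap = 10 * config.peak_width
    high_lines = [f"high_{i + 1}" for i in range(config.n_high_lines)]
    low_lines = [f"low_{i + 1}" for i in range(config.n_low_lines)]

    n_cand = config.n_true_enhancers + config.n_decoy_peaks
    starts = np.arange(n_cand) * gap + gap
    order = rng.permutation(n_cand)
    enhancer_slots = set(order[: config.n_true_enhancers].tolist())
    rows, names, is_true = [], [], []
    for i in range(n_cand):
        s = int(starts[i])
        truth_flag = i in enhancer_slots
        name = (
            f"enh_{sum(is_true) + 1}" if truth_flag else f"decoy_{i + 1}"
        )
        rows.append((chrom, s, s + config.peak_width, name))
        names.append(name)
        is_true.append(truth_flag)
    candidates = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    # histone-mark coverage per line
    landscape: dict[str, dict[str, pd.DataFrame]] = {
        ln: {"H3K27ac": [], "H3K4me1": []} for ln in high_lines + low_lines
    }
    for i, row in candidates.iterrows():
        if is_true[i]:
            support = rng.choice(
                config.n_high_lines, size=config.enhancer_support_lines, replace=False
            )
        else:
            k = int(rng.integers(0, config.decoy_max_support + 1))
            support = rng.choice(config.n_high_lines, size=k, replace=False)
        for li in support:
            marks = ["H3K27ac", "H3K4me1"] if rng.random() < 0.5 else [
                rng.choice(["H3K27ac", "H3K4me1"])
            ]
            for mark in marks:
                jitter = int(rng.integers(-config.peak_width // 4, config.peak_width // 4))
                landscape[high_lines[li]][mark].append(
                    (chrom, max(0, row.start + jitter), row.end + jitter)
                )
    # low lines get background peaks away from every candidate
    far = int(starts[-1]) + 20 * gap
    for ln in low_lines:
        for mark in ("H3K27ac", "H3K4me1"):
            n_bg = int(rng.integers(3, 8))
            for j in range(n_bg):
                s = far + int(rng.integers(0, 100)) * gap + j * gap
                landscape[ln][mark].append((chrom, s, s + config.peak_width))
    landscape_df = {
        ln: {
            mark: pd.DataFrame(peaks, columns=["chrom", "start", "end"])
            for mark, peaks in marks.items()
        }
        for ln, marks in landscape.items()
    }

    # TF binding events: one event inside a random true enhancer when a
    # dataset is "bound", plus one background event far away for realism
    enh_rows = candidates[np.array(is_true)]
    tf_rows = []
    for tf, cls in config.tf_roster.items():
        for line_set, n_datasets, rate in (
            (high_lines, config.datasets_per_tf_high, None),
            (low_lines, config.datasets_per_tf_low, None),
        ):
            is_high = line_set is high_lines
            if cls == "preferential":
                rate = (
                    config.preferential_bind_rate_high
                    if is_high
                    else config.preferential_bind_rate_low
                )
            else:
                rate = config.background_bind_rate
            for d in range(n_datasets):
                line = line_set[d % len(line_set)]
                dataset_id = f"{tf}_{line}_ds{d + 1}"
                bg = far + int(rng.integers(0, 1000)) * 100
                tf_rows.append((tf, dataset_id, line, chrom, bg, bg + 200))
                if rng.random() < rate and len(enh_rows) > 0:
                    target = enh_rows.iloc[int(rng.integers(0, len(enh_rows)))]
                    es = int(target.start + rng.integers(0, config.peak_width - 200))
                    tf_rows.append((tf, dataset_id, line, chrom, es, es + 200))
    tf_events = pd.DataFrame(
        tf_rows, columns=["tf", "dataset_id", "cell_line", "chrom", "start", "end"]
    )

    host_expr = pd.DataFrame(
        {
            "tf": list(config.tf_roster),
            "expression": [
                0.0 if tf in config.unexpressed_tfs else 5.0
                for tf in config.tf_roster
            ],
        }
    ).set_index("tf")

    # per-sample accessibility counts at the candidates
    samples = [f"WT_{i + 1}" for i in range(config.n_samples_per_group)] + [
        f"KO_{i + 1}" for i in range(config.n_samples_per_group)
    ]
    mu = np.full((n_cand, len(samples)), config.peak_mean_count)
    ko_cols = np.arange(config.n_samples_per_group, 2 * config.n_samples_per_group)
    mu[np.array(is_true)[:, None] & np.isin(np.arange(len(samples)), ko_cols)[None, :]] *= (
        2.0 ** config.accessibility_logfc
    )
    count_mat = _nb_draw(rng, mu, config.dispersion)
    for j, s in enumerate(samples):
        candidates[s] = count_mat[:, j]

    truth = TruthRecord(
        true_enhancers=[
            GenomicInterval(str(r.chrom), int(r.start), int(r.end), r.name)
            for r in enh_rows.itertuples(index=False)
        ],
        true_tf_classes=dict(config.tf_roster),
        true_line_classes={
            **{ln: "high" for ln in high_lines},
            **{ln: "low" for ln in low_lines},
        },
    )
    return candidates, landscape_df, tf_events, host_expr, truth


def config_from_mapping(cls, mapping: Mapping, seed: int | None = None):
    """Build a config dataclass from a plain mapping (e.g. parsed YAML),
    optionally overriding the seed."""
    data = dict(mapping)
    if seed is not None:
        data["seed"] = seed
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    if "tf_roster" in data and data["tf_roster"] is not None:
        data["tf_roster"] = dict(data["tf_roster"])
    if "unexpressed_tfs" in data and data["unexpressed_tfs"] is not None:
        data["unexpressed_tfs"] = tuple(data["unexpressed_tfs"])
    return cls(**data)
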