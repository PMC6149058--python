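"""Seeded generators for toy genomes, peaks, counts and class-count tables.

Every pipeline stage is testable without real data: the generators emit the
exact in-memory objects (and, via :mod:`peakrep.pipeline`, the exact file
formats) the analysis consumes, together with the ground truth they planted.

Randomness discipline: each generator draws from its own named substream of
the configured seed (``seed`` + CRC32 of the generator name), so adding or
reordering generators never perturbs another generator's output, and
identical configs reproduce identical outputs byte for byte.

Enrichment semantics: a class multiplier m is the *planted fold enrichment*.
Classes with m != 1 receive sampling probability exactly m * g_c and only
the unenriched classes are rescaled to fill the remainder, so the fold a
downstream representation test estimates equals m in expectation (a global
proportional-to-m*g renormalisation would shrink every planted fold by the
normalising constant, most severely for large classes).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import (
    DEFAULT_PRIORITY,
    INTERGENIC,
    GenomeClassPartition,
    RepeatCatalog,
    build_partition,
)
from .intervals import GenomicInterval
from .peaks import Peak, PeakSet
from .differential import RegionCounts

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_genome",
    "simulate_peaks",
    "simulate_region_counts",
    "simulate_class_counts",
]

# Class bp fractions of the toy genome.  The residual (intergenic) is
# ~31% — the genome-wide intergenic share the occupancy baseline reports —
# with introns the largest annotated class, as in mammalian annotation.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "promoter": 0.050,
    "TTS": 0.050,
    "exon": 0.040,
    "5UTR": 0.015,
    "3UTR": 0.040,
    "CpG_island": 0.020,
    "small_RNA": 0.010,
    "tRNA": 0.003,
    "rRNA": 0.002,
    "intron": 0.460,
}

# Instance counts per repeat category; proportions follow the RepeatMasker
# catalog shape (SINE-heavy, LINE ~19% of all repeats).
DEFAULT_REPEAT_COUNTS: dict[str, int] = {
    "SINE": 600,
    "LINE": 380,
    "LTR": 350,
    "simple_repeat": 300,
    "low_complexity": 200,
    "DNA": 120,
    "satellite": 30,
    "other": 20,
}

# Transcript class proportions for the class-count table (shared between
# conditions unless shifted).
DEFAULT_CLASS_COUNT_PROPS: dict[str, float] = {
    "LINE": 0.05,
    "SINE": 0.20,
    "low_complexity": 0.05,
    "intergenic": 0.30,
    "protein_coding": 0.40,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the study-scale defaults.

    ``class_enrichment`` and ``class_count_shifts`` map a label to its
    planted fold; ``fold_map`` maps a region index to its true count fold
    (regions absent from the map are null, fold 1).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    repeat_category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_COUNTS)
    )
    n_peaks: int = 2000
    peak_width: int = 500
    class_enrichment: Mapping[str, float] = field(default_factory=dict)
    depth_a: int = 20_000_000
    depth_b: int = 20_000_000
    base_rate: float = 80.0
    n_regions: int = 10_000
    region_width: int = 1100
    fold_map: Mapping[int, float] = field(default_factory=dict)
    block_size: int = 1000
    class_count_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNT_PROPS)
    )
    class_count_shifts: Mapping[str, float] = field(default_factory=dict)
    class_count_total: int = 100_000

    def __post_init__(self) -> None:
        if sum(self.class_fractions.values()) > 1 + 1e-12:
            raise ValueError("class fractions must sum to <= 1 (residual is intergenic)")
        if any(m <= 0 for m in self.class_enrichment.values()):
            raise ValueError("enrichment multipliers must be positive")
        if self.class_count_total <= 0:
            raise ValueError("class_count_total must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    class_fractions: dict[str, float] = field(default_factory=dict)
    repeat_counts: dict[str, int] = field(default_factory=dict)
    peak_classes: dict[str, str] = field(default_factory=dict)
    peak_class_probs: dict[str, float] = field(default_factory=dict)
    enriched_classes: dict[str, float] = field(default_factory=dict)
    region_folds: dict[int, float] = field(default_factory=dict)
    shifted_classes: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, name: str) -> np.random.Generator:
    """Named substream: independent of every other generator's draws."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def make_genome(config: SimConfig) -> tuple[GenomeClassPartition, RepeatCatalog, GroundTruth]:
    """Build a partitioned toy genome and repeat catalog.

    Class bp is laid out as shuffled fixed-size blocks separated by
    intergenic gaps along a concatenated coordinate, then cut at chromosome
    boundaries — realized fractions land within block-size rounding of the
    targets (well inside 2% absolute).  Repeat instances are placed
    uniformly, exactly the configured count per category.
    """
    G = config.n_chroms * config.chrom_length
    targets = {c: int(round(f * G)) for c, f in config.class_fractions.items()}
    if sum(targets.values()) > G:
        raise ValueError("requested class bp exceeds genome size")

    rng = _rng(config, "genome")
    blocks: list[tuple[str, int]] = []
    for cls_label, bp in targets.items():
        n_full, rem = divmod(bp, config.block_size)
        blocks.extend((cls_label, config.block_size) for _ in range(n_full))
        if rem:
            blocks.append((cls_label, rem))
    rng.shuffle(blocks)

    gap_budget = G - sum(size for _, size in blocks)
    n_gaps = len(blocks) + 1
    gaps = rng.multinomial(gap_budget, np.full(n_gaps, 1.0 / n_gaps))

    genome_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chrom_names = list(genome_sizes)
    class_sets: dict[str, list[GenomicInterval]] = {c: [] for c in targets}

    def emit(cls_label: str, g_start: int, g_end: int) -> None:
        # split a concatenated-coordinate span at chromosome boundaries
        while g_start < g_end:
            ci = g_start // config.chrom_length
            c_off = ci * config.chrom_length
            seg_end = min(g_end, c_off + config.chrom_length)
            class_sets[cls_label].append(
                GenomicInterval(chrom_names[ci], g_start - c_off, seg_end - c_off)
            )
            g_start = seg_end

    pos = int(gaps[0])
    for (cls_label, size), gap in zip(blocks, gaps[1:]):
        emit(cls_label, pos, pos + size)
        pos += size + int(gap)

    partition = build_partition(class_sets, priority=DEFAULT_PRIORITY, genome_sizes=genome_sizes)

    rng_rep = _rng(config, "repeats")
    instances: list[tuple[GenomicInterval, str]] = []
    for cat in sorted(config.repeat_category_counts):
        K = config.repeat_category_counts[cat]
        lengths = rng_rep.integers(100, 600, size=K)
        chroms = rng_rep.integers(0, config.n_chroms, size=K)
        for length, ci in zip(lengths, chroms):
            start = int(rng_rep.integers(0, config.chrom_length - length))
            instances.append((GenomicInterval(chrom_names[ci], start, start + int(length)), cat))
    catalog = RepeatCatalog(instances)

    truth = GroundTruth(
        class_fractions=dict(partition.fractions),
        repeat_counts=dict(config.repeat_category_counts),
    )
    return partition, catalog, truth


def _pinned_probs(base: dict[str, float], pinned: Mapping[str, float]) -> dict[str, float]:
    """Probabilities with pinned classes at fold*base and the rest rescaled."""
    pinned_mass = sum(base[c] * m for c, m in pinned.items())
    if pinned_mass >= 1:
        raise ValueError("planted enrichment exceeds the available probability mass")
    free = [c for c in base if c not in pinned]
    free_mass = sum(base[c] for c in free)
    scale = (1.0 - pinned_mass) / free_mass if free_mass > 0 else 0.0
    probs = {c: base[c] * pinned[c] for c in pinned}
    probs.update({c: base[c] * scale for c in free})
    return probs


def simulate_peaks(
    partition: GenomeClassPartition, catalog: RepeatCatalog, config: SimConfig
) -> tuple[PeakSet, GroundTruth]:
    """Place peaks with class-specific planted enrichment.

    Each peak's class is drawn from the pinned-probability scheme (planted
    fold = multiplier), then the peak is placed wholly inside a
    length-weighted random region of that class, so the recorded true class
    always equals the partition's own max-overlap assignment.
    """
    rng = _rng(config, "peaks")
    base = {c: partition.fractions[c] for c in partition.class_intervals}
    probs = _pinned_probs(base, config.class_enrichment)
    labels = sorted(probs)
    pvec = np.array([probs[c] for c in labels])
    pvec = pvec / pvec.sum()

    # flattened per-class region lists with length weights
    regions: dict[str, list[tuple[str, int, int]]] = {}
    weights: dict[str, np.ndarray] = {}
    for cls_label in labels:
        flat = [
            (chrom, s, e)
            for chrom, pairs in partition.class_intervals[cls_label].items()
            for s, e in pairs
        ]
        regions[cls_label] = flat
        w = np.array([e - s for _, s, e in flat], dtype=float)
        weights[cls_label] = w / w.sum() if w.sum() else w

    peaks: list[Peak] = []
    truth = GroundTruth(
        enriched_classes=dict(config.class_enrichment),
        peak_class_probs=dict(zip(labels, pvec.tolist())),
    )
    if config.n_peaks == 0:
        return PeakSet([], label="simulated"), truth
    draws = rng.choice(len(labels), size=config.n_peaks, p=pvec)
    for i, li in enumerate(draws):
        cls_label = labels[li]
        flat = regions[cls_label]
        ri = rng.choice(len(flat), p=weights[cls_label])
        chrom, s, e = flat[ri]
        width = min(config.peak_width, e - s)
        start = int(rng.integers(s, e - width + 1))
        pid = f"peak_{i}"
        peaks.append(Peak(GenomicInterval(chrom, start, start + width), pid))
        truth.peak_classes[pid] = cls_label
    return PeakSet(peaks, label="simulated"), truth


def simulate_region_counts(config: SimConfig) -> tuple[list[RegionCounts], GroundTruth]:
    """Poisson region counts at two depths with known per-region folds.

    count_b ~ Poisson(base_rate); count_a ~ Poisson(base_rate * fold * r)
    with r = depth_a/depth_b, so fold is the true depth-normalized fold
    change.  Regions absent from ``fold_map`` are null (fold 1).
    """
    if config.base_rate <= 0:
        raise ValueError("base_rate must be positive")
    rng = _rng(config, "regions")
    r = config.depth_a / config.depth_b
    folds = np.ones(config.n_regions)
    for idx, f in config.fold_map.items():
        folds[idx] = f
    count_b = rng.poisson(config.base_rate, size=config.n_regions)
    count_a = rng.poisson(config.base_rate * folds * r)
    regions = [
        RegionCounts(
            GenomicInterval("chrSim", i * config.region_width, (i + 1) * config.region_width),
            int(a),
            int(b),
        )
        for i, (a, b) in enumerate(zip(count_a, count_b))
    ]
    truth = GroundTruth(region_folds={i: float(f) for i, f in enumerate(folds)})
    return regions, truth


def simulate_class_counts(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Multinomial 2xC transcript class-count table with known shifts.

    Condition 2 draws from the base proportions; condition 1 pins shifted
    classes at shift*base (planted fold) and rescales the rest.  Totals are
    ``class_count_total`` per condition (minimum 1 enforced).
    """
    rng = _rng(config, "class_counts")
    base = dict(config.class_count_proportions)
    s = sum(base.values())
    base = {c: v / s for c, v in base.items()}
    probs1 = _pinned_probs(base, config.class_count_shifts)
    labels = sorted(base)
    total = max(1, config.class_count_total)
    counts1 = rng.multinomial(total, [probs1[c] for c in labels])
    counts2 = rng.multinomial(total, [base[c] for c in labels])
    table = pd.DataFrame(
        {"condition_1": counts1, "condition_2": counts2}, index=pd.Index(labels, name="class")
    )
    truth = GroundTruth(shifted_classes=dict(config.class_count_shifts))
    return table, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Same study conditions under a different seed."""
    return replace(config, seed=seed)
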