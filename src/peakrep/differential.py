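"""Depth-normalized differential enrichment between two conditions.

For each candidate region with read counts (count_a, count_b) at total
depths (depth_a, depth_b), direction A>B scales the background count to
condition A's depth, lambda = max(count_b, pseudocount) * depth_a/depth_b,
and tests the observed count_a against Poisson(lambda) with the upper-tail
(cumulative) probability P(X >= k).  A region is called when both the
depth-normalized fold change is >= ``min_fold`` and p < ``max_p`` — the
classic HOMER-style differential-peak rule (defaults: 2-fold, p < 1e-4, no
multiple-testing correction).  The reciprocal direction swaps the roles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import poisson

from .genome import GenomeClassPartition, RepeatCatalog
from .intervals import GenomicInterval
from .peaks import ClassTally, Peak, PeakSet, tally_classes

__all__ = [
    "RegionCounts",
    "DepthPair",
    "DifferentialRegion",
    "cumulative_poisson_p",
    "call_differential",
    "differential_class_summary",
    "read_region_counts",
    "aggregate_direction_counts",
]

A_OVER_B = "A_over_B"
B_OVER_A = "B_over_A"


@dataclass(frozen=True)
class RegionCounts:
    """Read counts of one candidate region in two conditions."""

    region: GenomicInterval
    count_a: int
    count_b: int

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("counts must be non-negative integers")


@dataclass(frozen=True)
class DepthPair:
    """Total mapped reads per condition; r = depth_a / depth_b."""

    depth_a: int
    depth_b: int

    def __post_init__(self) -> None:
        if self.depth_a <= 0 or self.depth_b <= 0:
            raise ValueError("depths must be positive")

    @property
    def r(self) -> float:
        return self.depth_a / self.depth_b


@dataclass(frozen=True)
class DifferentialRegion:
    region: GenomicInterval
    direction: str  # A_over_B or B_over_A
    fold_change: float
    p: float
    lam: float  # Poisson expectation under the null (depth-scaled background)
    count_target: int
    count_background: int


def cumulative_poisson_p(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(lam).

    Computed via the survival function, numerically stable for lam up to
    ~1e6.  ``k = 0`` returns 1 exactly (the whole sample space).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0 (apply a pseudocount to zero backgrounds)")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if k == 0:
        return 1.0
    return float(poisson.sf(k - 1, lam))


def call_differential(
    regions: list[RegionCounts],
    depths: DepthPair,
    min_fold: float = 2.0,
    max_p: float = 1e-4,
    pseudocount: float = 0.5,
) -> list[DifferentialRegion]:
    """Call direction-specific differential regions in both directions.

    Direction A>B: lambda = max(count_b, pseudocount) * r with
    r = depth_a/depth_b; the test statistic is k = count_a; the fold change
    FC = (count_a/depth_a) / (max(count_b, pseudocount)/depth_b) = k/lambda.
    Reported iff FC >= min_fold and p < max_p.  B>A is the reciprocal with
    1/r.  With min_fold >= 1 the two direction lists are disjoint by
    construction.  An empty input yields an empty result.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    calls: list[DifferentialRegion] = []
    r = depths.r
    for rc in regions:
        for direction, k, bg, ratio in (
            (A_OVER_B, rc.count_a, rc.count_b, r),
            (B_OVER_A, rc.count_b, rc.count_a, 1.0 / r),
        ):
            lam = max(bg, pseudocount) * ratio
            fc = k / lam
            if fc < min_fold:
                continue
            p = cumulative_poisson_p(k, lam)
            if p < max_p:
                calls.append(
                    DifferentialRegion(
                        region=rc.region,
                        direction=direction,
                        fold_change=fc,
                        p=p,
                        lam=lam,
                        count_target=k,
                        count_background=bg,
                    )
                )
    return calls


def differential_class_summary(
    calls: list[DifferentialRegion],
    partition: GenomeClassPartition,
    catalog: RepeatCatalog | None = None,
    rule: str = "max_overlap",
) -> dict[str, ClassTally]:
    """Per-direction class/repeat tallies of differential calls.

    Returns ``{"A_over_B": tally, "B_over_A": tally}``; with condition A the
    baseline-vs-target labelling of the study, A>B corresponds to regions
    that lost the mark and B>A to regions that gained it.
    """
    out: dict[str, ClassTally] = {}
    for direction in (A_OVER_B, B_OVER_A):
        sub = [c for c in calls if c.direction == direction]
        ps = PeakSet(
            [Peak(c.region, f"{direction}_{i}") for i, c in enumerate(sub)],
            label=direction,
        )
        out[direction] = tally_classes(ps, partition, catalog=catalog, rule=rule)
    return out


def aggregate_direction_counts(
    decreased: dict[str, int], increased: dict[str, int], categories: list[str] | None = None
) -> int:
    """Sum per-category differential-region counts over both directions.

    Reporting-layer arithmetic: restricts to *categories* when given (e.g.
    the repeat + non-genic classes), otherwise sums everything.
    """
    if categories is None:
        return sum(decreased.values()) + sum(increased.values())
    return sum(decreased.get(c, 0) for c in categories) + sum(
        increased.get(c, 0) for c in categories
    )


def read_region_counts(path: str | Path) -> list[RegionCounts]:
    """Read a region-count TSV (chrom, start, end, count_a, count_b)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "count_a", "count_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        RegionCounts(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            int(row.count_a),
            int(row.count_b),
        )
        for row in df.itertuples()
    ]


def differential_frame(calls: list[DifferentialRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.region.chrom,
                "start": c.region.start,
                "end": c.region.end,
                "direction": c.direction,
                "fold_change": c.fold_change,
                "lambda": c.lam,
                "p": c.p,
                "count_target": c.count_target,
                "count_background": c.count_background,
            }
            for c in calls
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "direction",
            "fold_change",
            "lambda",
            "p",
            "count_target",
            "count_background",
        ],
    )
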