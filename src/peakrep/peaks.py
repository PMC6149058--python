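"""Peak set I/O, class/repeat assignment, and class tallies.

Peaks are consumed as intervals (BED or HOMER peak-text dialect) — peak
calling itself happens upstream.  Each peak receives exactly one sequence
class (max-overlap against the genome partition by default, midpoint rule
optional) and at most one repeat category (max-overlap against the repeat
catalog), so tallies are mutually exclusive and sum to the peak total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .genome import GenomeClassPartition, ParseError, RepeatCatalog
from .intervals import GenomicInterval

__all__ = ["Peak", "PeakSet", "ClassTally", "read_peaks", "assign_class", "assign_repeat", "tally_classes"]


@dataclass
class Peak:
    interval: GenomicInterval
    id: str
    score: float | None = None
    assigned_class: str | None = None
    assigned_repeat: str | None = None


@dataclass
class PeakSet:
    peaks: list[Peak]
    label: str = ""
    source_depth: int | None = None

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise ValueError(f"duplicate peak id {dup!r} in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ClassTally:
    """Mutually exclusive per-class and per-repeat-category peak counts."""

    by_class: dict[str, int] = field(default_factory=dict)
    by_repeat: dict[str, int] = field(default_factory=dict)
    n_with_repeat: int = 0
    total: int = 0


def read_peaks(path: str | Path, dialect: str = "bed", label: str | None = None) -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    ``bed``: BED3+ with optional name (col 4) and score (col 5); coordinates
    0-based half-open.  ``homer``: HOMER peak text — '#'-prefixed comment
    lines, then ``PeakID chr start end strand ...`` with 1-based inclusive
    coordinates, converted to 0-based half-open on load.

    Missing ids are auto-generated as ``peak_<i>``; duplicate explicit ids
    raise.  An empty file yields an empty set.
    """
    if dialect not in {"bed", "homer"}:
        raise ValueError(f"unknown peak dialect {dialect!r}; use 'bed' or 'homer'")
    peaks: list[Peak] = []
    with open(path) as fh:
        i = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "bed" and line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    if len(fields) < 3:
                        raise ValueError("expected >=3 tab-separated fields")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    pid = fields[3] if len(fields) >= 4 and fields[3] not in {"", "."} else f"peak_{i}"
                    score = float(fields[4]) if len(fields) >= 5 and fields[4] not in {"", "."} else None
                    strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
                else:
                    if len(fields) < 5:
                        raise ValueError("expected >=5 columns (PeakID chr start end strand)")
                    pid = fields[0] if fields[0] not in {"", "."} else f"peak_{i}"
                    chrom = fields[1]
                    start, end = int(fields[2]) - 1, int(fields[3])  # 1-based incl -> 0-based half-open
                    strand = fields[4] if fields[4] in {"+", "-"} else "."
                    score = float(fields[5]) if len(fields) >= 6 and fields[5] not in {"", "."} else None
                peaks.append(Peak(GenomicInterval(chrom, start, end, strand), pid, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            i += 1
    return PeakSet(peaks, label=label if label is not None else Path(path).stem)


def assign_class(
    peak: Peak, partition: GenomeClassPartition, rule: str = "max_overlap"
) -> str:
    """Assign one sequence class to *peak*.

    ``max_overlap``: the class with most overlapping bp wins; ties broken by
    the partition's priority order (intergenic last).  ``midpoint``: the
    class containing ``floor((start + end) / 2)``.
    """
    iv = peak.interval
    if iv.chrom not in partition.genome_sizes:
        raise KeyError(f"peak {peak.id}: chromosome {iv.chrom!r} absent from partition")
    if rule == "midpoint":
        return partition.class_at(iv.chrom, min(iv.midpoint, partition.genome_sizes[iv.chrom] - 1))
    if rule != "max_overlap":
        raise ValueError(f"unknown assignment rule {rule!r}; use 'max_overlap' or 'midpoint'")
    overlaps = partition.overlap_by_class(iv.chrom, iv.start, iv.end)
    if not overlaps:
        raise ValueError(f"peak {peak.id} does not overlap the annotated genome")
    order = {c: i for i, c in enumerate(partition.priority)}
    order.setdefault("intergenic", len(order))
    return max(overlaps, key=lambda c: (overlaps[c], -order.get(c, len(order))))


def assign_repeat(peak: Peak, catalog: RepeatCatalog) -> str | None:
    """Repeat category of the instance with greatest bp overlap, or None.

    Ties (equal overlap bp) are broken by category name order.
    """
    iv = peak.interval
    best: tuple[int, str] | None = None
    for hit in catalog.tree_for(iv.chrom).overlap(iv.start, iv.end):
        bp = min(iv.end, hit.end) - max(iv.start, hit.begin)
        cat = hit.data
        if best is None or bp > best[0] or (bp == best[0] and cat < best[1]):
            best = (bp, cat)
    return best[1] if best else None


def tally_classes(
    peakset: PeakSet,
    partition: GenomeClassPartition,
    catalog: RepeatCatalog | None = None,
    rule: str = "max_overlap",
) -> ClassTally:
    """Annotate every peak and tally class / repeat-category composition.

    Every peak contributes to exactly one class count; repeat tallies run
    over peaks with a non-None repeat assignment.  Duplicate or overlapping
    peaks are all counted (no deduplication).
    """
    tally = ClassTally(total=len(peakset.peaks))
    for peak in peakset.peaks:
        peak.assigned_class = assign_class(peak, partition, rule=rule)
        tally.by_class[peak.assigned_class] = tally.by_class.get(peak.assigned_class, 0) + 1
        if catalog is not None:
            peak.assigned_repeat = assign_repeat(peak, catalog)
            if peak.assigned_repeat is not None:
                tally.n_with_repeat += 1
                tally.by_repeat[peak.assigned_repeat] = (
                    tally.by_repeat.get(peak.assigned_repeat, 0) + 1
                )
    return tally


def annotated_peaks_frame(peakset: PeakSet) -> pd.DataFrame:
    """Annotated peaks as a table (id, chrom, start, end, class, repeat_category)."""
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "class": p.assigned_class,
                "repeat_category": p.assigned_repeat,
            }
            for p in peakset.peaks
        ],
        columns=["id", "chrom", "start", "end", "class", "repeat_category"],
    )
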