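"""Genome class partition and repeat catalog.

The genome is modelled as a disjoint partition of every annotated base into
one *sequence class* (promoter, exon, intron, ..., intergenic).  Input class
interval sets may overlap each other; overlaps are resolved by an explicit
priority list (earlier class wins) and intergenic is the residual — every
base not claimed by any supplied class.  The partition supplies the
genome-occupancy baseline g_c = occupancy_bp(c) / G used as the expectation
in class representation tests.

The repeat catalog holds RepeatMasker-style repeat instances, each with a
normalized category label (LINE, SINE, LTR, low_complexity, simple_repeat,
DNA, satellite, other).  It supplies the hypergeometric universe: N repeats
in total, K per category.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    GenomicInterval,
    intersect_pairs,
    merge_pairs,
    overlap_bp,
    subtract_pairs,
    total_bp,
)

__all__ = [
    "INTERGENIC",
    "DEFAULT_PRIORITY",
    "REPEAT_CATEGORIES",
    "GenomeClassPartition",
    "RepeatCatalog",
    "load_class_intervals",
    "load_chrom_sizes",
    "load_repeatmasker",
    "build_partition",
    "class_occupancy_report",
]

INTERGENIC = "intergenic"

#: Annotation hierarchy used to resolve bases claimed by several classes;
#: earlier entries win.  Intergenic is always the residual and never listed.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "promoter",
    "TTS",
    "exon",
    "5UTR",
    "3UTR",
    "CpG_island",
    "small_RNA",
    "tRNA",
    "rRNA",
    "intron",
)

#: Normalized repeat category labels.
REPEAT_CATEGORIES: tuple[str, ...] = (
    "LINE",
    "SINE",
    "LTR",
    "low_complexity",
    "simple_repeat",
    "DNA",
    "satellite",
    "other",
)

# UCSC rmsk repClass values -> normalized category.  Anything else maps to
# "other"; a trailing "?" (uncertain classification) is stripped first.
_RMSK_CLASS_MAP = {
    "line": "LINE",
    "sine": "SINE",
    "ltr": "LTR",
    "low_complexity": "low_complexity",
    "simple_repeat": "simple_repeat",
    "dna": "DNA",
    "satellite": "satellite",
}


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


def normalize_repeat_category(label: str) -> str:
    key = label.strip().rstrip("?").lower()
    return _RMSK_CLASS_MAP.get(key, "other" if key not in REPEAT_CATEGORIES else key)


@dataclass
class GenomeClassPartition:
    """Disjoint assignment of every annotated base to one sequence class.

    Attributes
    ----------
    class_intervals
        class -> merged disjoint ``(start, end)`` pairs per chromosome.
    occupancy_bp
        class -> total base pairs assigned to that class.
    total_bp
        Total annotated genome size G (sum of chromosome lengths).
    fractions
        class -> g_c = occupancy_bp / G.
    """

    class_intervals: dict[str, dict[str, list[tuple[int, int]]]]
    occupancy_bp: dict[str, int]
    total_bp: int
    fractions: dict[str, float]
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    genome_sizes: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_occupancy(
        cls, occupancy_bp: dict[str, int], total_bp: int | None = None
    ) -> "GenomeClassPartition":
        """Build an occupancy-only partition from per-class bp totals.

        Interval lists are left empty; useful when only published occupancy
        numbers are available.  If *total_bp* exceeds the supplied classes'
        sum, the remainder is assigned to intergenic (unless intergenic was
        supplied explicitly, in which case an unlabelled residual is not
        permitted and the totals must agree).
        """
        occ = dict(occupancy_bp)
        supplied = sum(occ.values())
        if total_bp is None:
            total_bp = supplied
        if supplied > total_bp:
            raise ValueError("class occupancies exceed the stated genome size")
        residual = total_bp - supplied
        if residual:
            if INTERGENIC in occ:
                occ["_unannotated"] = occ.get("_unannotated", 0) + residual
            else:
                occ[INTERGENIC] = residual
        fractions = {c: bp / total_bp for c, bp in occ.items()}
        return cls(
            class_intervals={c: {} for c in occ},
            occupancy_bp=occ,
            total_bp=total_bp,
            fractions=fractions,
        )

    def classes(self) -> list[str]:
        return list(self.class_intervals)

    def chrom_segments(self, chrom: str) -> list[tuple[int, int, str]]:
        """Sorted ``(start, end, class)`` segments covering *chrom*."""
        segs: list[tuple[int, int, str]] = []
        for cls_label, per_chrom in self.class_intervals.items():
            for s, e in per_chrom.get(chrom, []):
                segs.append((s, e, cls_label))
        segs.sort()
        return segs

    def class_at(self, chrom: str, pos: int) -> str:
        """Sequence class claiming base *pos* on *chrom*."""
        if chrom not in self.genome_sizes:
            raise KeyError(f"chromosome {chrom!r} absent from partition")
        if not 0 <= pos < self.genome_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} [0, {self.genome_sizes[chrom]})")
        for cls_label, per_chrom in self.class_intervals.items():
            for s, e in per_chrom.get(chrom, []):
                if s <= pos < e:
                    return cls_label
        raise AssertionError("partition does not cover the genome")  # pragma: no cover

    def overlap_by_class(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """Overlapping bp of ``[start, end)`` with each class (zero rows kept out)."""
        if chrom not in self.genome_sizes:
            raise KeyError(f"chromosome {chrom!r} absent from partition")
        out: dict[str, int] = {}
        for cls_label, per_chrom in self.class_intervals.items():
            bp = overlap_bp(start, end, per_chrom.get(chrom, []))
            if bp:
                out[cls_label] = bp
        return out


@dataclass
class RepeatCatalog:
    """Repeat instances with normalized category labels.

    ``category_counts`` maps category -> K (number of instances) and
    ``total_repeats`` is N; these are the hypergeometric population
    parameters for repeat representation testing.
    """

    instances: list[tuple[GenomicInterval, str]]
    category_counts: dict[str, int] = field(init=False)
    total_repeats: int = field(init=False)

    def __post_init__(self) -> None:
        counts = Counter(cat for _, cat in self.instances)
        self.category_counts = dict(counts)
        self.total_repeats = len(self.instances)
        self._trees: dict[str, IntervalTree] | None = None

    def tree_for(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
            for iv, cat in self.instances:
                trees[iv.chrom].addi(iv.start, iv.end, cat)
            self._trees = dict(trees)
        return self._trees.get(chrom, IntervalTree())


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coord(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what} {value!r}") from None


def load_class_intervals(path: str | Path, class_label: str | None = None) -> list[GenomicInterval]:
    """Read a BED3+ file into a sorted interval list.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Coordinates are taken as 0-based half-open (BED native).  *class_label*
    is accepted for call-site readability; intervals themselves carry no
    class (the partition builder attaches classes).
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        start = _parse_coord(fields[1], path, lineno, "start")
        end = _parse_coord(fields[2], path, lineno, "end")
        if start >= end or start < 0:
            raise ParseError(
                f"{path}:{lineno}: invalid coordinates {start}-{end} (need 0 <= start < end)"
            )
        strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else "."
        intervals.append(GenomicInterval(fields[0], start, end, strand))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read two-column ``chrom<TAB>length`` text."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
        sizes[fields[0]] = _parse_coord(fields[1], path, lineno, "length")
    return sizes


# Column offsets of the UCSC rmsk table dump (with leading `bin` column):
# bin swScore milliDiv milliDel milliIns genoName genoStart genoEnd genoLeft
# strand repName repClass repFamily ...
_RMSK_WITH_BIN = dict(chrom=5, start=6, end=7, strand=9, rep_class=11)
_RMSK_NO_BIN = dict(chrom=4, start=5, end=6, strand=8, rep_class=10)


def load_repeatmasker(path: str | Path, dialect: str | None = None) -> RepeatCatalog:
    """Load a repeat catalog from a UCSC rmsk table dump or a 4-column BED.

    Dialects
    --------
    ``rmsk``
        UCSC table dump (tab-separated; genoStart 0-based; `repClass`
        column).  Dumps with or without the leading `bin` column are
        accepted.
    ``bed``
        BED with the category label in column 4.

    When *dialect* is None it is sniffed from the first data line.
    Categories are normalized (e.g. ``Low_complexity`` -> ``low_complexity``);
    repClass values outside the known set map to ``other``.
    """
    rows = list(_data_lines(path))
    if dialect is None:
        dialect = _sniff_repeat_dialect(rows, path)
    if dialect not in {"rmsk", "bed"}:
        raise ValueError(
            f"unknown repeat-catalog dialect {dialect!r}; accepted dialects: 'rmsk' "
            "(UCSC rmsk table dump) or 'bed' (BED with category in column 4)"
        )
    instances: list[tuple[GenomicInterval, str]] = []
    for lineno, line in rows:
        fields = line.split("\t")
        if dialect == "bed":
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED repeat rows need 4 columns")
            chrom, cat = fields[0], fields[3]
            start = _parse_coord(fields[1], path, lineno, "start")
            end = _parse_coord(fields[2], path, lineno, "end")
            strand = "."
        else:
            cols = _RMSK_WITH_BIN if len(fields) >= 17 else _RMSK_NO_BIN
            if len(fields) <= cols["rep_class"]:
                raise ParseError(f"{path}:{lineno}: too few columns for rmsk dialect")
            chrom = fields[cols["chrom"]]
            start = _parse_coord(fields[cols["start"]], path, lineno, "genoStart")
            end = _parse_coord(fields[cols["end"]], path, lineno, "genoEnd")
            strand = fields[cols["strand"]] if fields[cols["strand"]] in {"+", "-"} else "."
            cat = fields[cols["rep_class"]]
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid coordinates {start}-{end}")
        instances.append((GenomicInterval(chrom, start, end, strand), normalize_repeat_category(cat)))
    return RepeatCatalog(instances)


def _sniff_repeat_dialect(rows, path) -> str:
    if not rows:
        return "bed"
    _, first = rows[0]
    fields = first.split("\t")

    def is_int(x: str) -> bool:
        try:
            int(x)
            return True
        except ValueError:
            return False

    if len(fields) >= 11:
        for cols in (_RMSK_WITH_BIN, _RMSK_NO_BIN):
            if len(fields) > cols["rep_class"] and is_int(fields[cols["start"]]) and is_int(
                fields[cols["end"]]
            ):
                return "rmsk"
    if len(fields) >= 4 and is_int(fields[1]) and is_int(fields[2]):
        return "bed"
    raise ValueError(
        f"{path}: cannot determine repeat-catalog dialect; accepted dialects: 'rmsk' "
        "(UCSC table dump) or 'bed' (category in column 4)"
    )


def build_partition(
    class_sets: dict[str, list[GenomicInterval]],
    priority: tuple[str, ...] | list[str] = DEFAULT_PRIORITY,
    genome_sizes: dict[str, int] | None = None,
) -> GenomeClassPartition:
    """Resolve possibly-overlapping class interval sets into a disjoint partition.

    Every base of every chromosome in *genome_sizes* is assigned to exactly
    one class: where supplied classes overlap, the earlier class in
    *priority* wins; intergenic is the residual.

    Raises
    ------
    ValueError
        If a class is missing from *priority*, an interval's chromosome is
        absent from *genome_sizes*, or an interval exceeds its chromosome
        length.
    """
    if genome_sizes is None:
        raise ValueError("genome_sizes is required (chrom -> length)")
    priority = tuple(priority)
    for cls_label in class_sets:
        if cls_label == INTERGENIC:
            raise ValueError("intergenic is the residual class; do not supply it")
        if cls_label not in priority:
            raise ValueError(f"class {cls_label!r} missing from priority list")

    # per-chrom merged pairs per class, validated against genome_sizes
    merged: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for cls_label, ivs in class_sets.items():
        per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for iv in ivs:
            if iv.chrom not in genome_sizes:
                raise ValueError(f"chromosome {iv.chrom!r} absent from genome sizes")
            if iv.end > genome_sizes[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {genome_sizes[iv.chrom]}"
                )
            per_chrom[iv.chrom].append((iv.start, iv.end))
        merged[cls_label] = {c: merge_pairs(p) for c, p in per_chrom.items()}

    assigned: dict[str, dict[str, list[tuple[int, int]]]] = {
        cls_label: {} for cls_label in priority if cls_label in class_sets
    }
    assigned[INTERGENIC] = {}
    for chrom, length in genome_sizes.items():
        remaining = [(0, length)]
        for cls_label in priority:
            if cls_label not in class_sets:
                continue
            claimed = intersect_pairs(merged[cls_label].get(chrom, []), remaining)
            if claimed:
                assigned[cls_label][chrom] = claimed
                remaining = subtract_pairs(remaining, claimed)
        if remaining:
            assigned[INTERGENIC][chrom] = remaining

    occupancy = {
        cls_label: sum(total_bp(p) for p in per_chrom.values())
        for cls_label, per_chrom in assigned.items()
    }
    G = sum(genome_sizes.values())
    fractions = {cls_label: bp / G for cls_label, bp in occupancy.items()}
    return GenomeClassPartition(
        class_intervals=assigned,
        occupancy_bp=occupancy,
        total_bp=G,
        fractions=fractions,
        priority=priority,
        genome_sizes=dict(genome_sizes),
    )


def class_occupancy_report(partition: GenomeClassPartition) -> pd.DataFrame:
    """Per-class occupancy table: class, occupancy_bp, genome_bp, fraction, percent.

    ``percent`` is the fraction rendered at full precision; format with two
    decimals for display (e.g. an intergenic fraction of
    813929088/2631564759 prints as 30.93).
    """
    rows = [
        {
            "class": cls_label,
            "occupancy_bp": bp,
            "genome_bp": partition.total_bp,
            "fraction": bp / partition.total_bp,
            "percent": 100.0 * bp / partition.total_bp,
        }
        for cls_label, bp in partition.occupancy_bp.items()
    ]
    df = pd.DataFrame(rows, columns=["class", "occupancy_bp", "genome_bp", "fraction", "percent"])
    if not df.empty:
        assert abs(df["fraction"].sum() - 1.0) < 1e-9
    return df
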