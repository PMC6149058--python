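"""Genomic interval primitives and merged-interval set arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
Interval-set operations work on plain ``(start, end)`` integer pairs per
chromosome; lists returned by :func:`merge_pairs` are sorted, non-overlapping
and non-adjacent, which every other routine here relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "merge_pairs",
    "intersect_pairs",
    "subtract_pairs",
    "total_bp",
    "overlap_bp",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open coordinate span on a named sequence.

    Parameters
    ----------
    chrom
        Sequence (chromosome/contig) name; must be non-empty.
    start, end
        0-based half-open coordinates with ``0 <= start < end``.
    strand
        One of ``+``, ``-`` or ``.`` (unstranded). Strand is carried but
        ignored by all occupancy and overlap computations.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {sorted(_STRANDS)}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlapping base pairs with *other* (0 if on different sequences)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended ``(start, end)`` pairs."""
    if not pairs:
        return []
    pairs = sorted(pairs)
    out = [pairs[0]]
    for s, e in pairs[1:]:
        ls, le = out[-1]
        if s <= le:  # overlap or adjacency
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def intersect_pairs(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two merged pair lists (two-pointer sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_pairs(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Bases in *a* not covered by *b*; both inputs must be merged lists."""
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_bp(pairs: list[tuple[int, int]]) -> int:
    """Total bases covered by a merged pair list."""
    return sum(e - s for s, e in pairs)


def overlap_bp(start: int, end: int, pairs: list[tuple[int, int]]) -> int:
    """Bases of ``[start, end)`` covered by a merged pair list."""
    return sum(
        max(0, min(end, e) - max(start, s)) for s, e in pairs if s < end and e > start
    )
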